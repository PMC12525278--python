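"""Reading and writing the pipeline's plain-file formats.

Variants travel as a tab-separated annotation table (one row per variant,
columns named after the AnnotatedVariant fields) optionally paired with a
VCF 4.x carrying the loci; the gene panel is a one-symbol-per-line text file;
scored output is CSV with the eleven component columns, the total and the
display-scale color bin; morphometry records and group comparisons are tidy
CSV.
"""

from __future__ import annotations

import json

import pandas as pd

from .rubric import CRITERIA, KDAScoreCard
from .variants import AnnotatedVariant, GenePanel

_BOOL_FIELDS = (
    "mutationtaster_call",
    "polyphen2_call",
    "sift_call",
    "fathmm_mkl_call",
    "spliceai_flag",
    "brain_expression",
)
_FLOAT_FIELDS = ("maf_nfe", "maf_any_population_max", "gerp_score", "missense_z", "pli")

_NA_STRINGS = {"", ".", "na", "nan", "none", "nf", "not_found"}


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in _NA_STRINGS:
        return None
    if s in ("1", "true", "yes", "d", "deleterious"):
        return True
    if s in ("0", "false", "no", "b", "benign", "tolerated"):
        return False
    raise ValueError(f"cannot parse boolean annotation {value!r}")


def _parse_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in _NA_STRINGS:
        return None
    return float(s)


def read_annotation_table(path) -> list[AnnotatedVariant]:
    """Read a UTF-8 tab-separated annotation table into variants.

    Required columns: ``gene_symbol``; all other AnnotatedVariant fields are
    optional and default sensibly. ``NF`` / ``.`` / empty cells mean "not
    found" (frequencies) or "no call" (predictors).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_symbol" not in df.columns:
        raise ValueError("annotation table must have a 'gene_symbol' column")
    variants = []
    for _, row in df.iterrows():
        kw: dict = {"gene_symbol": str(row["gene_symbol"]).strip()}
        for col in ("protein_change", "cdna_change", "inheritance", "acmg_class", "consequence"):
            if col in df.columns and not pd.isna(row[col]):
                kw[col] = str(row[col]).strip()
        if "caller_count" in df.columns and not pd.isna(row["caller_count"]):
            kw["caller_count"] = int(float(row["caller_count"]))
        if "cadd_phred" in df.columns and not pd.isna(row["cadd_phred"]):
            kw["cadd_phred"] = float(row["cadd_phred"])
        for col in _FLOAT_FIELDS:
            if col in df.columns:
                kw[col] = _parse_float(row[col])
        for col in _BOOL_FIELDS:
            if col in df.columns:
                kw[col] = _parse_bool(row[col])
        if "pathway_tags" in df.columns and not pd.isna(row["pathway_tags"]):
            tags = str(row["pathway_tags"]).strip()
            kw["pathway_tags"] = frozenset(t for t in tags.replace("/", ",").split(",") if t)
        variants.append(AnnotatedVariant(**kw))
    return variants


def write_annotation_table(path, variants: list[AnnotatedVariant]) -> None:
    rows = []
    for v in variants:
        d = dict(v.__dict__)
        d["pathway_tags"] = "/".join(sorted(v.pathway_tags))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_panel(path) -> GenePanel:
    """One HGNC symbol per line; blank lines and '#' comments ignored."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    if not symbols:
        raise ValueError(f"gene panel {path} is empty")
    return GenePanel.from_iterable(symbols)


def read_vcf_loci(path) -> pd.DataFrame:
    """Loci (CHROM, POS, REF, ALT, and the GENE info tag when present) from a
    VCF 4.x file."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
                "gene_symbol": rec.INFO.get("GENE"),
            }
        )
    return pd.DataFrame(rows)


def scores_to_frame(cards: list[KDAScoreCard]) -> pd.DataFrame:
    """Scored table with the component columns in the published order."""
    rows = []
    for card in cards:
        v = card.variant
        row = {
            "gene_symbol": v.gene_symbol,
            "protein_change": v.protein_change,
            "cdna_change": v.cdna_change,
            "inheritance": v.inheritance,
            "acmg_class": v.acmg_class,
            "cadd_phred": v.cadd_phred,
            "maf_nfe": v.maf_nfe,
            "pathway_tags": "/".join(sorted(v.pathway_tags)),
        }
        for c in CRITERIA:
            row[f"score_{c}"] = card.components[c]
        row["total"] = card.total
        row["color_bin"] = card.color
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(path, cards: list[KDAScoreCard]) -> None:
    scores_to_frame(cards).to_csv(path, index=False)


def write_json_report(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


__all__ = [
    "read_annotation_table",
    "write_annotation_table",
    "read_gene_panel",
    "read_vcf_loci",
    "scores_to_frame",
    "write_scores",
    "write_json_report",
]
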