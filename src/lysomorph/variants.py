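"""Annotated WES variants: domain types, filtering and benign/polymorphic exclusion.

The pipeline consumes variants that already carry web-resource annotations
(gnomAD frequencies, CADD, ACMG class from a clinical classifier, per-tool
deleteriousness calls, conservation, gene constraint, tissue expression).
Filtering reproduces the screening stage of the exome workflow: caller
concordance, non-Finnish-European rarity, CADD deleteriousness, membership in
a curated Parkinson's-disease gene panel, and a final exclusion of
benign/likely-benign variants that are polymorphic (>1%) in any population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: closed vocabulary of ACMG classes (benign .. pathogenic)
ACMG_CLASSES = ("B", "LB", "VUS", "LP", "P")

#: ordinal severity used for ranking; higher = more severe
ACMG_SEVERITY = {c: i for i, c in enumerate(ACMG_CLASSES)}

INHERITANCE = ("M", "F", "de_novo", "unknown")

CONSEQUENCES = ("missense", "synonymous", "intronic", "lof", "other")

#: closed vocabulary of pathway tags (lysosome, autophagy, Golgi, mitochondria,
#: endoplasmic reticulum, MAPK signalling, vesicular trafficking, neuronal)
PATHWAY_TAGS = ("LY", "ATP", "GLG", "MIT", "ER", "MAPK", "VT", "NR")


@dataclass
class AnnotatedVariant:
    """One variant's raw annotations.

    ``maf_nfe`` / ``maf_any_population_max`` are allele-frequency fractions in
    [0, 1]; ``None`` encodes "not found" in the population database (a rarity
    signal, not a missing annotation). Predictor calls are ``True`` (called
    deleterious), ``False`` (called benign/tolerated) or ``None`` (no call).
    """

    gene_symbol: str
    protein_change: str = ""
    cdna_change: str = ""
    inheritance: str = "unknown"
    caller_count: int = 0
    maf_nfe: float | None = None
    maf_any_population_max: float | None = None
    cadd_phred: float = 0.0
    acmg_class: str = "VUS"
    consequence: str = "missense"
    mutationtaster_call: bool | None = None
    polyphen2_call: bool | None = None
    sift_call: bool | None = None
    fathmm_mkl_call: bool | None = None
    spliceai_flag: bool | None = None
    gerp_score: float | None = None
    missense_z: float | None = None
    pli: float | None = None
    brain_expression: bool | None = None
    pathway_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.gene_symbol or not isinstance(self.gene_symbol, str):
            raise ValueError("gene_symbol must be a non-empty string")
        if not isinstance(self.caller_count, int) or self.caller_count < 0:
            raise ValueError(f"caller_count must be a non-negative integer, got {self.caller_count!r}")
        if self.acmg_class not in ACMG_CLASSES:
            raise ValueError(f"acmg_class must be one of {ACMG_CLASSES}, got {self.acmg_class!r}")
        if self.inheritance not in INHERITANCE:
            raise ValueError(f"inheritance must be one of {INHERITANCE}, got {self.inheritance!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence must be one of {CONSEQUENCES}, got {self.consequence!r}")
        if self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        self.pathway_tags = frozenset(self.pathway_tags)
        unknown = self.pathway_tags - set(PATHWAY_TAGS)
        if unknown:
            raise ValueError(f"unknown pathway tags: {sorted(unknown)}")

    @property
    def label(self) -> str:
        return f"{self.gene_symbol}:{self.protein_change or self.cdna_change}"

    def maf_problems(self) -> list[str]:
        """Range problems in the frequency fields (malformed records are
        rejected during filtering, not at construction)."""
        problems = []
        for name in ("maf_nfe", "maf_any_population_max"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v!r} outside [0, 1]")
        return problems


@dataclass(frozen=True)
class GenePanel:
    """A curated set of HGNC gene symbols (stored upper-cased)."""

    symbols: frozenset

    def __post_init__(self):
        if any((not s) or (not isinstance(s, str)) for s in self.symbols):
            raise ValueError("panel symbols must be non-empty strings")
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in self.symbols))

    @classmethod
    def from_iterable(cls, symbols) -> "GenePanel":
        return cls(frozenset(symbols))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class FilterThresholds:
    """Screening bounds. All three numeric bounds are strict, as in the source
    workflow: callers > 2, non-Finnish-European MAF < 0.01, CADD > 15."""

    caller_min: int = 2
    maf_max: float = 0.01
    cadd_min: float = 15.0


def filter_variants(
    variants: list[AnnotatedVariant],
    panel: GenePanel | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[AnnotatedVariant]:
    """Apply the screening filters, preserving input order.

    A variant survives iff caller_count > caller_min, maf_nfe < maf_max (a
    frequency not found in the population database counts as rare), cadd_phred
    > cadd_min and, when a panel is given, its gene symbol is on the panel
    (case-insensitive). Synonymous and intronic records are subject to the
    same CADD bound (they are evaluated, not discarded outright). Malformed
    frequency fields reject the record with a logged reason. Idempotent.
    """
    kept = []
    for v in variants:
        problems = v.maf_problems()
        if problems:
            logger.warning("rejecting %s: %s", v.label, "; ".join(problems))
            continue
        if v.caller_count <= thresholds.caller_min:
            continue
        if v.maf_nfe is not None and v.maf_nfe >= thresholds.maf_max:
            continue
        if v.cadd_phred <= thresholds.cadd_min:
            continue
        if panel is not None and v.gene_symbol not in panel:
            continue
        kept.append(v)
    return kept


def exclude_benign_polymorphic(
    variants: list[AnnotatedVariant], polymorphic_threshold: float = 0.01
) -> list[AnnotatedVariant]:
    """Drop benign / likely-benign variants that are polymorphic (>1% allele
    frequency) in at least one population.

    Both conditions must hold; a benign variant that is rare everywhere (e.g.
    GLA p.Asp313Tyr at 4.46e-3) survives, as does any VUS/LP/P variant
    regardless of frequency. A missing population maximum counts as not
    polymorphic.
    """
    kept = []
    for v in variants:
        if (
            v.acmg_class in ("B", "LB")
            and v.maf_any_population_max is not None
            and v.maf_any_population_max > polymorphic_threshold
        ):
            logger.info("excluding %s: %s with max population AF %.3g", v.label, v.acmg_class, v.maf_any_population_max)
            continue
        kept.append(v)
    return kept


__all__ = [
    "ACMG_CLASSES",
    "ACMG_SEVERITY",
    "PATHWAY_TAGS",
    "AnnotatedVariant",
    "GenePanel",
    "FilterThresholds",
    "filter_variants",
    "exclude_benign_polymorphic",
    "replace",
]
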