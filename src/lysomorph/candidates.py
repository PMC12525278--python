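"""Built-in reference fixture: the candidate variants reported in the
three-patient early-onset Parkinson's disease exome study (two trios and one
singleton), with the raw annotations that the default rubric maps onto the
published component scores. Used as a regression anchor by the tests and
embedded verbatim into synthetic variant tables."""

from __future__ import annotations

from .variants import AnnotatedVariant


def _v(**kw) -> AnnotatedVariant:
    kw.setdefault("caller_count", 3)
    kw.setdefault("consequence", "missense")
    kw.setdefault("brain_expression", True)
    kw.setdefault("missense_z", 1.0)
    kw.setdefault("pli", 0.1)
    return AnnotatedVariant(**kw)


#: patient label -> list of AnnotatedVariant, in reported order
CANDIDATES_BY_PATIENT: dict[str, list[AnnotatedVariant]] = {
    "PD-302": [
        _v(gene_symbol="FBXO7", protein_change="p.(Ala248Thr)", cdna_change="c.742G>A",
           inheritance="M", acmg_class="VUS", cadd_phred=24.5, maf_nfe=3.97e-6,
           maf_any_population_max=3.97e-6, mutationtaster_call=True, polyphen2_call=True,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=5.2,
           pathway_tags={"LY", "ATP"}),
        _v(gene_symbol="LRRK2", protein_change="p.(Phe1436Leu)", cdna_change="c.4306T>C",
           inheritance="M", acmg_class="VUS", cadd_phred=24.1, maf_nfe=None,
           maf_any_population_max=None, mutationtaster_call=True, polyphen2_call=True,
           sift_call=False, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=5.0,
           pathway_tags={"LY", "VT", "NR"}),
        _v(gene_symbol="GLA", protein_change="p.Asp313Tyr", cdna_change="c.937G>T",
           inheritance="M", acmg_class="B", cadd_phred=18.3, maf_nfe=4.46e-3,
           maf_any_population_max=4.46e-3, mutationtaster_call=True, polyphen2_call=True,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=0.5,
           pathway_tags={"LY", "ATP"}),
    ],
    "PD-227": [
        _v(gene_symbol="ABL2", protein_change="p.(Arg180Cys)", cdna_change="c.538C>T",
           inheritance="unknown", acmg_class="LP", cadd_phred=34.0, maf_nfe=8.79e-6,
           maf_any_population_max=8.79e-6, mutationtaster_call=True, polyphen2_call=True,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=0.8,
           pathway_tags={"NR"}),
        _v(gene_symbol="GLA", protein_change="p.Asp313Tyr", cdna_change="c.937G>T",
           inheritance="M", acmg_class="B", cadd_phred=18.3, maf_nfe=4.46e-3,
           maf_any_population_max=4.46e-3, mutationtaster_call=True, polyphen2_call=True,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=0.5,
           pathway_tags={"LY", "ATP"}),
        _v(gene_symbol="BORCS8", protein_change="p.(Arg85His)", cdna_change="c.254G>A",
           inheritance="unknown", acmg_class="VUS", cadd_phred=22.8, maf_nfe=1.35e-5,
           maf_any_population_max=1.35e-5, mutationtaster_call=True, polyphen2_call=False,
           sift_call=False, fathmm_mkl_call=False, spliceai_flag=False, gerp_score=4.8,
           pathway_tags={"LY", "MAPK"}),
    ],
    "PD-216": [
        _v(gene_symbol="VPS33B", protein_change="p.(Arg398Cys)", cdna_change="c.1192C>T",
           inheritance="M", acmg_class="VUS", cadd_phred=33.0, maf_nfe=None,
           maf_any_population_max=None, mutationtaster_call=True, polyphen2_call=True,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=5.5,
           pathway_tags={"LY", "GLG", "ATP"}),
        _v(gene_symbol="GLB1", protein_change="p.Arg419Gln", cdna_change="c.1256G>A",
           inheritance="F", acmg_class="LP", cadd_phred=35.0, maf_nfe=7.06e-6,
           maf_any_population_max=7.06e-6, mutationtaster_call=True, polyphen2_call=False,
           sift_call=False, fathmm_mkl_call=True, spliceai_flag=True, gerp_score=5.1,
           pathway_tags={"LY", "ATP", "NR"}),
        _v(gene_symbol="DAPK1", protein_change="p.(Arg666Gln)", cdna_change="c.1997G>A",
           inheritance="M", acmg_class="VUS", cadd_phred=25.4, maf_nfe=6.22e-5,
           maf_any_population_max=6.22e-5, mutationtaster_call=True, polyphen2_call=False,
           sift_call=True, fathmm_mkl_call=True, spliceai_flag=False, gerp_score=4.6,
           pathway_tags={"LY", "ATP"}),
    ],
}

#: the eight distinct candidate variants (GLA p.Asp313Tyr appears in two
#: patients; kept once, keyed by gene + protein change)
REFERENCE_VARIANTS: dict[str, AnnotatedVariant] = {
    v.label: v
    for patient in ("PD-302", "PD-227", "PD-216")
    for v in CANDIDATES_BY_PATIENT[patient]
}

#: published total scores for the eight distinct variants
REFERENCE_TOTALS: dict[str, int] = {
    "FBXO7:p.(Ala248Thr)": 12,
    "LRRK2:p.(Phe1436Leu)": 11,
    "GLA:p.Asp313Tyr": 8,
    "ABL2:p.(Arg180Cys)": 12,
    "BORCS8:p.(Arg85His)": 8,
    "VPS33B:p.(Arg398Cys)": 13,
    "GLB1:p.Arg419Gln": 12,
    "DAPK1:p.(Arg666Gln)": 10,
}

#: published per-criterion component scores, in rubric.CRITERIA order
REFERENCE_COMPONENTS: dict[str, tuple[int, ...]] = {
    "FBXO7:p.(Ala248Thr)":  (2, 1, 3, 1, 1, 1, 1, 0, 1, 0, 1),
    "LRRK2:p.(Phe1436Leu)": (2, 1, 3, 1, 1, 0, 1, 0, 1, 0, 1),
    "GLA:p.Asp313Tyr":      (1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 1),
    "ABL2:p.(Arg180Cys)":   (3, 2, 2, 1, 1, 1, 1, 0, 0, 0, 1),
    "BORCS8:p.(Arg85His)":  (2, 1, 2, 1, 0, 0, 0, 0, 1, 0, 1),
    "VPS33B:p.(Arg398Cys)": (2, 2, 3, 1, 1, 1, 1, 0, 1, 0, 1),
    "GLB1:p.Arg419Gln":     (3, 2, 2, 1, 0, 0, 1, 1, 1, 0, 1),
    "DAPK1:p.(Arg666Gln)":  (2, 1, 2, 1, 0, 1, 1, 0, 1, 0, 1),
}

__all__ = [
    "CANDIDATES_BY_PATIENT",
    "REFERENCE_VARIANTS",
    "REFERENCE_TOTALS",
    "REFERENCE_COMPONENTS",
]
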