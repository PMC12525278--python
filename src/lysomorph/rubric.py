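"""Knowledge-driven (KDA) prioritization score.

Each filtered variant receives eleven integer component scores — ACMG class,
CADD tier, population-rarity tier, five pathogenicity-predictor calls
(MutationTaster, PolyPhen-2, SIFT, FATHMM-MKL, SpliceAI), conservation
(GERP++), gene constraint (missense Z / pLI) and expression in brain — whose
sum is the total used for ranking. The exact appendix cut-points of the
original scheme are not published; the default rubric here is reconstructed
to be consistent with every row of the published three-patient candidate
table, and every cut-point is configurable and serializable to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .variants import ACMG_SEVERITY, AnnotatedVariant

#: the eleven scored criteria, in the column order of the scored table
CRITERIA = (
    "acmg",
    "cadd",
    "frequency",
    "mutationtaster",
    "polyphen2",
    "sift",
    "fathmm_mkl",
    "spliceai",
    "gerp",
    "constraint",
    "brain_expression",
)

_PREDICTOR_FIELDS = {
    "mutationtaster": "mutationtaster_call",
    "polyphen2": "polyphen2_call",
    "sift": "sift_call",
    "fathmm_mkl": "fathmm_mkl_call",
    "spliceai": "spliceai_flag",
}


@dataclass
class KDARubric:
    """Threshold tables mapping raw annotations to integer component scores.

    ``cadd_tiers`` and ``frequency_tiers`` are ordered ``[threshold, score]``
    pairs scanned top-down: the first tier whose threshold is crossed wins
    (strictly-greater for CADD, strictly-less for frequency), else
    ``*_base_score``. A frequency of ``None`` (not found in the population
    database) scores the rarest tier.
    """

    acmg_scores: dict = field(
        default_factory=lambda: {"B": 1, "LB": 1, "VUS": 2, "LP": 3, "P": 3}
    )
    cadd_tiers: list = field(default_factory=lambda: [[30.0, 2], [15.0, 1]])
    cadd_base_score: int = 0
    frequency_tiers: list = field(default_factory=lambda: [[5e-6, 3], [1e-3, 2]])
    frequency_base_score: int = 1
    frequency_not_found_score: int = 3
    predictor_score: int = 1
    gerp_min: float = 2.0
    missense_z_min: float = 3.09
    pli_min: float = 0.9
    missing_score: int = 0

    def score(self, variant: AnnotatedVariant, criterion: str) -> int:
        """Integer component score of one criterion; missing raw annotations
        map to ``missing_score``."""
        if criterion == "acmg":
            return int(self.acmg_scores.get(variant.acmg_class, self.missing_score))
        if criterion == "cadd":
            for threshold, score in sorted(self.cadd_tiers, reverse=True):
                if variant.cadd_phred > threshold:
                    return int(score)
            return self.cadd_base_score
        if criterion == "frequency":
            if variant.maf_nfe is None:
                return self.frequency_not_found_score
            for threshold, score in sorted(self.frequency_tiers):
                if variant.maf_nfe < threshold:
                    return int(score)
            return self.frequency_base_score
        if criterion in _PREDICTOR_FIELDS:
            call = getattr(variant, _PREDICTOR_FIELDS[criterion])
            if call is None:
                return self.missing_score
            return self.predictor_score if call else 0
        if criterion == "gerp":
            if variant.gerp_score is None:
                return self.missing_score
            return 1 if variant.gerp_score >= self.gerp_min else 0
        if criterion == "constraint":
            z, pli = variant.missense_z, variant.pli
            if z is None and pli is None:
                return self.missing_score
            hit = (z is not None and z >= self.missense_z_min) or (
                pli is not None and pli >= self.pli_min
            )
            return 1 if hit else 0
        if criterion == "brain_expression":
            if variant.brain_expression is None:
                return self.missing_score
            return 1 if variant.brain_expression else 0
        raise KeyError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")

    def component_range(self, criterion: str) -> tuple[int, int]:
        """Declared (min, max) of a criterion's scores."""
        if criterion == "acmg":
            vals = list(self.acmg_scores.values()) + [self.missing_score]
        elif criterion == "cadd":
            vals = [s for _, s in self.cadd_tiers] + [self.cadd_base_score]
        elif criterion == "frequency":
            vals = [s for _, s in self.frequency_tiers] + [
                self.frequency_base_score,
                self.frequency_not_found_score,
            ]
        elif criterion in _PREDICTOR_FIELDS or criterion in (
            "gerp",
            "constraint",
            "brain_expression",
        ):
            vals = [0, self.predictor_score if criterion in _PREDICTOR_FIELDS else 1,
                    self.missing_score]
        else:
            raise KeyError(f"unknown criterion {criterion!r}")
        return min(vals), max(vals)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KDARubric":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KDARubric":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


DEFAULT_RUBRIC = KDARubric()

#: the total ranges from green (3) to deep red (15) on the display scale
COLOR_SCALE_MIN = 3
COLOR_SCALE_MAX = 15
N_COLOR_BINS = COLOR_SCALE_MAX - COLOR_SCALE_MIN + 1  # 13 discrete, evenly spaced bins


def color_bin(total: int) -> int:
    """Ordinal bin on the green-to-deep-red display scale.

    Returns an index in 0..12: totals <= 3 fall in the lowest (green) bin,
    totals >= 15 in the deepest-red bin; interior bins are one score point
    wide (monotone non-decreasing in the total).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    return int(min(max(total, COLOR_SCALE_MIN), COLOR_SCALE_MAX) - COLOR_SCALE_MIN)


def score_component(
    variant: AnnotatedVariant, criterion: str, rubric: KDARubric = DEFAULT_RUBRIC
) -> int:
    """Score a single criterion of one variant."""
    return rubric.score(variant, criterion)


@dataclass
class KDAScoreCard:
    """Eleven component scores, their total, and the display-scale bin."""

    variant: AnnotatedVariant
    components: dict
    total: int
    color: int

    def __post_init__(self):
        if tuple(self.components) != CRITERIA:
            raise ValueError("components must cover exactly the eleven criteria, in order")
        if self.total != sum(self.components.values()):
            raise ValueError("total must equal the sum of the components")


def score_variant(
    variant: AnnotatedVariant, rubric: KDARubric = DEFAULT_RUBRIC
) -> KDAScoreCard:
    """Score one variant over all eleven criteria."""
    components = {c: rubric.score(variant, c) for c in CRITERIA}
    total = sum(components.values())
    return KDAScoreCard(variant=variant, components=components, total=total, color=color_bin(total))


DEFAULT_RANK_KEYS = ("lysosomal", "acmg", "total")


def _rank_key(card: KDAScoreCard, keys) -> tuple:
    parts = []
    for k in keys:
        if k == "lysosomal":
            parts.append(1 if "LY" in card.variant.pathway_tags else 0)
        elif k == "acmg":
            parts.append(ACMG_SEVERITY[card.variant.acmg_class])
        elif k == "total":
            parts.append(card.total)
        else:
            raise KeyError(f"unknown rank key {k!r}")
    return tuple(parts)


def rank_variants(
    cards: list[KDAScoreCard], keys=DEFAULT_RANK_KEYS
) -> list[KDAScoreCard]:
    """Stable descending sort by (lysosomal-pathway membership, ACMG severity,
    total); ties preserve input order. Key order is configurable."""
    return sorted(cards, key=lambda c: _rank_key(c, keys), reverse=True)


__all__ = [
    "CRITERIA",
    "KDARubric",
    "DEFAULT_RUBRIC",
    "KDAScoreCard",
    "score_component",
    "score_variant",
    "rank_variants",
    "color_bin",
    "N_COLOR_BINS",
]
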