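"""Generator presets: one per study group (CT control plus four
patient-derived fibroblast lines).

Each preset carries the distribution parameters the synthetic-image and
variant-table generators sample from. Targets are the published group means:
lysosome diameter (nm), lysosomal-network porosity (%), LysoSensor relative
intensity, enzyme/trans-Golgi Manders M1, p62 aggregate density (per um^2)
and Golgi morphology (fragmented-cell prevalence, nucleus distance, fragment
count). Where a group's value was not reported (e.g. Golgi metrics outside
CT/PD-216), the control values are reused.

``dispersion_px`` (the Thomas-process offspring scatter that controls network
porosity) is calibrated once against the porosity targets and frozen here;
it is the only preset parameter set by calibration rather than read directly
from the published group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

PRESET_VERSION = 1


@dataclass(frozen=True)
class GeneratorPreset:
    group: str

    # lysosome geometry (shared by sizing and network images)
    diameter_mean_nm: float = 482.9
    diameter_sd_nm: float = 111.2
    diameter_min_nm: float = 100.0
    n_lysosomes: int = 30
    n_network_lysosomes: int = 120
    n_parents: int = 3
    dispersion_px: float = 10.0          # Thomas-process offspring sigma (px)
    lysosome_pixel_nm: float = 40.0
    lysosome_field_px: int = 512
    rim_sigma_px: float = 1.0
    lysosome_amp: float = 160.0
    porosity_target: float = 12.83

    # colocalization (enzyme vs trans-Golgi)
    coloc_fraction_mean: float = 0.36
    coloc_fraction_sd: float = 0.12
    coloc_pixel_nm: float = 80.0
    coloc_field_px: int = 256

    # Golgi morphology
    golgi_fragmented_prob: float = 0.1467
    golgi_frag_count_lambda: float = 1.5   # fragmented: count = 6 + Poisson(lambda)
    golgi_unfrag_count_lambda: float = 2.2  # unfragmented: count = 1 + Poisson(lambda), capped at 5
    golgi_disp_frag_mean_um: float = 8.0
    golgi_disp_frag_sd_um: float = 3.0
    golgi_disp_unfrag_mean_um: float = 5.98
    golgi_disp_unfrag_sd_um: float = 2.9
    nucleus_axes_um: tuple = (7.2, 5.6)
    golgi_pixel_nm: float = 160.0
    golgi_field_px: int = 384
    golgi_blob_sigma_px: float = 1.6
    golgi_amp: float = 150.0

    # p62 aggregates
    p62_rate_per_um2: float = 0.022
    p62_pixel_nm: float = 160.0
    p62_field_px: int = 320
    cell_area_um2: float = 1500.0
    p62_amp: float = 130.0

    # LysoSensor
    lysosensor_mean: float = 0.99
    lysosensor_sd: float = 0.08
    lysosensor_base_amp: float = 120.0
    lysosensor_pixel_nm: float = 80.0
    lysosensor_field_px: int = 192
    lysosensor_n_puncta: int = 20

    # optics / noise
    psf_sigma_px: float = 1.2
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    bit_depth: int = 8

    # study design
    n_cells: int = 30
    n_replicates: int = 3

    version: int = PRESET_VERSION

    #: published group means recovered by the morphometry operators
    targets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("diameter_mean_nm", "diameter_sd_nm", "dispersion_px",
                     "lysosome_pixel_nm", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coloc_fraction_mean", "golgi_fragmented_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _targets(diameter, porosity, lysosensor, coloc, p62, frag_pct, golgi_dist, golgi_n):
    return {
        "lysosome_diameter_nm": diameter,
        "porosity_pct": porosity,
        "lysosensor_relative": lysosensor,
        "manders_m1": coloc,
        "p62_density_per_um2": p62,
        "golgi_fragmented_pct": frag_pct,
        "golgi_distance_um": golgi_dist,
        "golgi_fragments": golgi_n,
    }


PRESETS: dict[str, GeneratorPreset] = {
    "CT": GeneratorPreset(
        group="CT",
        diameter_mean_nm=482.9, diameter_sd_nm=111.2,
        dispersion_px=76.0, n_network_lysosomes=160, porosity_target=12.83,
        coloc_fraction_mean=0.36, coloc_fraction_sd=0.12,
        golgi_fragmented_prob=0.1467,
        p62_rate_per_um2=0.022,
        lysosensor_mean=0.99, lysosensor_sd=0.08,
        targets=_targets(482.9, 12.83, 0.99, 0.36, 0.022, 14.67, 5.98, 4.12),
    ),
    "PD-302": GeneratorPreset(
        group="PD-302",
        diameter_mean_nm=645.8, diameter_sd_nm=116.7,
        dispersion_px=112.0, n_network_lysosomes=100, porosity_target=48.57,
        coloc_fraction_mean=0.45, coloc_fraction_sd=0.15,
        golgi_fragmented_prob=0.1467,
        p62_rate_per_um2=0.006,
        lysosensor_mean=0.91, lysosensor_sd=0.13,
        targets=_targets(645.8, 48.57, 0.91, 0.45, 0.006, 14.67, 5.98, 4.12),
    ),
    "PD-216": GeneratorPreset(
        group="PD-216",
        diameter_mean_nm=749.1, diameter_sd_nm=175.2,
        dispersion_px=186.0, n_network_lysosomes=80, porosity_target=64.59,
        coloc_fraction_mean=0.36, coloc_fraction_sd=0.12,
        golgi_fragmented_prob=0.8252,
        golgi_frag_count_lambda=7.5,
        golgi_disp_frag_mean_um=12.01, golgi_disp_frag_sd_um=5.0,
        p62_rate_per_um2=0.012,
        lysosensor_mean=0.98, lysosensor_sd=0.11,
        targets=_targets(749.1, 64.59, 0.98, 0.36, 0.012, 82.52, 12.01, 12.25),
    ),
    "PD-212": GeneratorPreset(
        group="PD-212",
        diameter_mean_nm=588.2, diameter_sd_nm=134.7,
        dispersion_px=118.0, n_network_lysosomes=100, porosity_target=55.50,
        coloc_fraction_mean=0.36, coloc_fraction_sd=0.12,
        golgi_fragmented_prob=0.1467,
        p62_rate_per_um2=0.013,
        lysosensor_mean=1.08, lysosensor_sd=0.11,
        targets=_targets(588.2, 55.50, 1.08, 0.36, 0.013, 14.67, 5.98, 4.12),
    ),
    "PD-088": GeneratorPreset(
        group="PD-088",
        diameter_mean_nm=443.0, diameter_sd_nm=111.7,
        dispersion_px=75.0, n_network_lysosomes=160, porosity_target=18.29,
        coloc_fraction_mean=0.36, coloc_fraction_sd=0.12,
        golgi_fragmented_prob=0.1467,
        p62_rate_per_um2=0.022,
        lysosensor_mean=1.03, lysosensor_sd=0.11,
        targets=_targets(443.0, 18.29, 1.03, 0.36, 0.022, 14.67, 5.98, 4.12),
    ),
}


def preset_from_paper(group_name: str) -> GeneratorPreset:
    """The versioned preset whose targets are the published group statistics."""
    try:
        return PRESETS[group_name]
    except KeyError:
        raise KeyError(
            f"unknown group {group_name!r}; known groups: {sorted(PRESETS)}"
        ) from None


__all__ = ["GeneratorPreset", "PRESETS", "preset_from_paper", "PRESET_VERSION"]
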