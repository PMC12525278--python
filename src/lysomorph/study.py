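"""Simulated-study drivers: generate preset-conditioned images, run the
morphometry operators on them, and return tidy per-cell / per-object tables.

The study design mirrors the source experiments: 3 independent replicates per
group, >=80 lysosomes per replicate for sizing, >=100 cells per replicate for
Golgi classification, and ~30 cells per replicate for colocalization, p62 and
LysoSensor readouts. Each replicate draws its own image seeds from the study
seed, so replicates are independent but the whole study is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import morphometry as mm
from .presets import GeneratorPreset, preset_from_paper
from .synth import (
    make_coloc_image,
    make_golgi_image,
    make_lysosome_image,
    make_lysosensor_image,
    make_p62_image,
)

_SEED_CAP = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


def diameter_study(
    preset: GeneratorPreset,
    seed: int,
    n_replicates: int = 3,
    min_objects_per_replicate: int = 80,
    max_images: int = 8,
) -> pd.DataFrame:
    """Measure lysosome diameters on sizing images until each replicate holds
    at least the required number of resolved objects."""
    rows = []
    rep_seeds = _child_seeds(seed, n_replicates)
    for rep, rep_seed in enumerate(rep_seeds):
        img_seeds = _child_seeds(int(rep_seed), max_images)
        count = 0
        for img_seed in img_seeds:
            if count >= min_objects_per_replicate:
                break
            image, _ = make_lysosome_image(preset, int(img_seed), kind="size")
            for lab, nm, resolved in mm.measure_lysosome_diameters(image):
                if resolved:
                    rows.append({"group": preset.group, "replicate": rep,
                                 "measure": "lysosome_diameter_nm", "value": nm})
                    count += 1
    return pd.DataFrame(rows)


def porosity_study(
    preset: GeneratorPreset, seed: int, n_replicates: int = 3, cells_per_replicate: int = 3
) -> pd.DataFrame:
    """Per-tile network porosity over clustered-network images."""
    rows = []
    rep_seeds = _child_seeds(seed, n_replicates)
    for rep, rep_seed in enumerate(rep_seeds):
        for img_seed in _child_seeds(int(rep_seed), cells_per_replicate):
            image, _ = make_lysosome_image(preset, int(img_seed), kind="network")
            try:
                tiles = mm.measure_porosity(image)
            except ValueError:
                continue
            for t in tiles:
                rows.append({"group": preset.group, "replicate": rep,
                             "measure": "porosity_pct", "value": float(t)})
    return pd.DataFrame(rows)


def golgi_study(
    preset: GeneratorPreset, seed: int, n_replicates: int = 3, cells_per_replicate: int = 100
) -> pd.DataFrame:
    """Classify Golgi morphology cell by cell; one row per cell with the
    fragment count, nucleus distance and classification."""
    rows = []
    rep_seeds = _child_seeds(seed, n_replicates)
    for rep, rep_seed in enumerate(rep_seeds):
        for img_seed in _child_seeds(int(rep_seed), cells_per_replicate):
            image, truth = make_golgi_image(preset, int(img_seed))
            g = mm.measure_golgi(image)
            rows.append({
                "group": preset.group, "replicate": rep,
                "classification": g.classification,
                "fragment_count": g.fragment_count,
                "nucleus_distance_um": g.nucleus_distance_um,
                "true_fragmented": truth.data["fragmented"],
            })
    return pd.DataFrame(rows)


def fragmented_percentage(golgi_frame: pd.DataFrame) -> float:
    return 100.0 * (golgi_frame["classification"] == "fragmented_or_beehive").mean()


def coloc_study(
    preset: GeneratorPreset, seed: int, n_replicates: int = 3, cells_per_replicate: int = 30,
    ref_role: str = "GALA", other_role: str = "TGN46",
) -> pd.DataFrame:
    """Per-cell Manders M1 of the enzyme channel inside the trans-Golgi mask."""
    rows = []
    rep_seeds = _child_seeds(seed, n_replicates)
    for rep, rep_seed in enumerate(rep_seeds):
        for img_seed in _child_seeds(int(rep_seed), cells_per_replicate):
            image, truth = make_coloc_image(preset, int(img_seed))
            m1 = mm.measure_manders(image, ref_role, other_role)
            rows.append({"group": preset.group, "replicate": rep,
                         "measure": "manders_m1", "value": m1,
                         "planted": truth.data["planted_fraction"]})
    return pd.DataFrame(rows)


def p62_study(
    preset: GeneratorPreset, seed: int, n_replicates: int = 3, cells_per_replicate: int = 20
) -> pd.DataFrame:
    rows = []
    rep_seeds = _child_seeds(seed, n_replicates)
    for rep, rep_seed in enumerate(rep_seeds):
        for img_seed in _child_seeds(int(rep_seed), cells_per_replicate):
            image, truth = make_p62_image(preset, int(img_seed))
            cell_mask = mm.segment_channel(image, "CELL", min_object_px=64).binary()
            density = mm.p62_aggregate_density(
                image.plane("P62"), cell_mask, image.pixel_size_nm
            )
            rows.append({"group": preset.group, "replicate": rep,
                         "measure": "p62_density_per_um2", "value": density,
                         "planted": truth.data["density_per_um2"]})
    return pd.DataFrame(rows)


def lysosensor_study(
    groups: list[str], seed: int, n_replicates: int = 3, cells_per_replicate: int = 20,
    control_group: str = "CT",
) -> pd.DataFrame:
    """Per-cell LysoSensor intensities for several groups, normalized to the
    control group's per-replicate mean."""
    if control_group not in groups:
        groups = [control_group] + [g for g in groups if g != control_group]
    raw: dict[str, list[list[float]]] = {}
    group_seeds = _child_seeds(seed, len(groups))
    for g, gseed in zip(groups, group_seeds):
        preset = preset_from_paper(g)
        reps = []
        for rep_seed in _child_seeds(int(gseed), n_replicates):
            cells = []
            for img_seed in _child_seeds(int(rep_seed), cells_per_replicate):
                image, _ = make_lysosensor_image(preset, int(img_seed))
                cells.append(mm.cell_mean_intensity(image))
            reps.append(cells)
        raw[g] = reps
    relative = mm.lysosensor_relative_intensity(raw, control_group=control_group)
    rows = []
    for g, reps in relative.items():
        for rep, cells in enumerate(reps):
            for v in cells:
                rows.append({"group": g, "replicate": rep,
                             "measure": "lysosensor_relative", "value": float(v)})
    return pd.DataFrame(rows)


__all__ = [
    "diameter_study",
    "porosity_study",
    "golgi_study",
    "fragmented_percentage",
    "coloc_study",
    "p62_study",
    "lysosensor_study",
]
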