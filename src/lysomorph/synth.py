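"""Ground-truthed synthetic data: annotated variant tables and multichannel
fluorescence cell images whose statistics match the study-group presets.

Images are rendered noise-free at float precision (ground truth is recorded
at this stage), then passed through a simple optical model: Gaussian PSF
blur, Poisson photon noise, additive Gaussian read noise, and 8-bit
quantization. Lysosomes are rendered as annuli — the membrane marker stains
the rim, which is what makes the two-peak intensity-profile diameter
definition meaningful; the rendered rim radius is compensated for the small
inward peak shift that isotropic blur induces on a curved rim, so that the
post-blur peak-to-peak distance equals the drawn ground-truth diameter.

Everything is deterministic per (preset, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import CellImage
from .presets import GeneratorPreset
from .rubric import CRITERIA, DEFAULT_RUBRIC, KDARubric
from .variants import AnnotatedVariant
from .candidates import REFERENCE_VARIANTS

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Pre-noise truth of one generated image or table (immutable per seed)."""

    kind: str
    seed: int | None
    preset: str | None
    data: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def apply_optics(channels: dict, preset: GeneratorPreset, rng: np.random.Generator) -> dict:
    """PSF blur, Poisson + read noise, clip and quantize to the bit depth."""
    out = {}
    maxval = 2**preset.bit_depth - 1
    for role, arr in channels.items():
        blurred = gaussian_filter(np.asarray(arr, dtype=float), preset.psf_sigma_px)
        if preset.poisson_gain > 0:
            noisy = rng.poisson(np.clip(blurred, 0, None) * preset.poisson_gain) / preset.poisson_gain
        else:
            noisy = blurred
        noisy = noisy + rng.normal(0.0, preset.read_noise_sd, size=blurred.shape)
        out[role] = np.clip(np.round(noisy), 0, maxval).astype(np.uint8)
    return out


def _noise_free(channels: dict, preset: GeneratorPreset) -> dict:
    maxval = 2**preset.bit_depth - 1
    return {r: np.clip(a, 0, maxval) for r, a in channels.items()}


def apply_noise(channels: dict, preset: GeneratorPreset, rng: np.random.Generator) -> dict:
    """Poisson + read noise + quantization on already-blurred channels."""
    out = {}
    maxval = 2**preset.bit_depth - 1
    for role, arr in channels.items():
        arr = np.asarray(arr, dtype=float)
        if preset.poisson_gain > 0:
            noisy = rng.poisson(np.clip(arr, 0, None) * preset.poisson_gain) / preset.poisson_gain
        else:
            noisy = arr
        noisy = noisy + rng.normal(0.0, preset.read_noise_sd, size=arr.shape)
        out[role] = np.clip(np.round(noisy), 0, maxval).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _add_ring(img: np.ndarray, cy: float, cx: float, radius_px: float,
              rim_sigma_px: float, amp: float) -> None:
    """Additively render a radial-Gaussian annulus peaked at ``radius_px``."""
    win = int(np.ceil(radius_px + 4 * rim_sigma_px)) + 2
    ny, nx = img.shape
    r0, r1 = max(0, int(cy) - win), min(ny, int(cy) + win + 1)
    c0, c1 = max(0, int(cx) - win), min(nx, int(cx) + win + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cy, xx - cx)
    img[r0:r1, c0:c1] += amp * np.exp(-((d - radius_px) ** 2) / (2 * rim_sigma_px**2))


def _add_blob(img: np.ndarray, cy: float, cx: float, sigma_px: float, amp: float) -> None:
    win = int(np.ceil(4 * sigma_px)) + 2
    ny, nx = img.shape
    r0, r1 = max(0, int(cy) - win), min(ny, int(cy) + win + 1)
    c0, c1 = max(0, int(cx) - win), min(nx, int(cx) + win + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    img[r0:r1, c0:c1] += amp * np.exp(-d2 / (2 * sigma_px**2))


def _draw_diameters(preset: GeneratorPreset, rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated-normal lysosome diameters (nm), resampled above the floor."""
    out = np.empty(n)
    for i in range(n):
        d = rng.normal(preset.diameter_mean_nm, preset.diameter_sd_nm)
        while d <= preset.diameter_min_nm:
            d = rng.normal(preset.diameter_mean_nm, preset.diameter_sd_nm)
        out[i] = d
    return out


def _rim_compensation(radius_px: float, rim_sigma_px: float, psf_sigma_px: float) -> float:
    """Rendered rim radius whose post-blur intensity peak sits at ``radius_px``.

    Isotropic blur of a curved rim pulls the radial peak inward by about
    sigma_eff^2 / (2 r); rendering at the compensated radius cancels this.
    """
    sigma_eff2 = rim_sigma_px**2 + psf_sigma_px**2
    return radius_px + 0.5 * sigma_eff2 / max(radius_px, 1.0)


# ---------------------------------------------------------------------------
# lysosome images (sizing and network variants)
# ---------------------------------------------------------------------------

def make_lysosome_image(
    preset: GeneratorPreset,
    seed: int,
    kind: str = "size",
    n_objects: int | None = None,
    noise: bool = True,
) -> tuple[CellImage, GroundTruth]:
    """Render a LAMP1 field of annular lysosomes.

    ``kind="size"`` places objects with clear separation (each object's rim
    profile is individually measurable); ``kind="network"`` places them with a
    Thomas parent/offspring process whose ``dispersion_px`` controls network
    porosity (overlap allowed). Truth records per-object diameters (nm) and
    centers (px).
    """
    rng = np.random.default_rng(seed)
    n = preset.n_lysosomes if n_objects is None else n_objects
    size = preset.lysosome_field_px
    img = np.zeros((size, size))
    diameters = _draw_diameters(preset, rng, n)
    radii_px = diameters / 2.0 / preset.lysosome_pixel_nm
    centers: list[tuple[float, float]] = []
    placed_d: list[float] = []
    cell_r = 0.46 * size
    center = np.array([size / 2.0, size / 2.0])

    if kind == "size":
        for d_nm, r_px in zip(diameters, radii_px):
            ok = False
            for _ in range(200):
                pos = center + (rng.random(2) - 0.5) * 2 * cell_r / np.sqrt(2)
                if np.hypot(*(pos - center)) > cell_r - r_px - 6:
                    continue
                if all(
                    np.hypot(pos[0] - cy, pos[1] - cx) > r_px + pr + 8
                    for (cy, cx), pr in zip(centers, placed_d)
                ):
                    ok = True
                    break
            if not ok:
                logger.info("could not place lysosome (d=%.0f nm); reducing count", d_nm)
                continue
            centers.append((float(pos[0]), float(pos[1])))
            placed_d.append(r_px)
            _add_ring(img, pos[0], pos[1],
                      _rim_compensation(r_px, preset.rim_sigma_px, preset.psf_sigma_px if noise else 0.0),
                      preset.rim_sigma_px, preset.lysosome_amp)
    elif kind == "network":
        if n_objects is None:
            n = preset.n_network_lysosomes
            diameters = _draw_diameters(preset, rng, n)
            radii_px = diameters / 2.0 / preset.lysosome_pixel_nm
        parents = [
            center + rng.normal(0, 0.25 * preset.dispersion_px, size=2)
            for _ in range(preset.n_parents)
        ]
        for d_nm, r_px in zip(diameters, radii_px):
            parent = parents[rng.integers(len(parents))]
            ok = False
            for _ in range(200):
                theta = rng.uniform(0, 2 * np.pi)
                rad = preset.dispersion_px * np.sqrt(rng.random())
                pos = parent + rad * np.array([np.sin(theta), np.cos(theta)])
                if np.hypot(*(pos - center)) <= cell_r - r_px:
                    ok = True
                    break
            if not ok:
                logger.info("could not place lysosome (d=%.0f nm); reducing count", d_nm)
                continue
            centers.append((float(pos[0]), float(pos[1])))
            placed_d.append(r_px)
            _add_ring(img, pos[0], pos[1],
                      _rim_compensation(r_px, preset.rim_sigma_px, preset.psf_sigma_px if noise else 0.0),
                      preset.rim_sigma_px, preset.lysosome_amp)
    else:
        raise ValueError(f"unknown lysosome image kind {kind!r}")

    placed_diam = [2 * r * preset.lysosome_pixel_nm for r in placed_d]
    channels = {"LAMP1": img}
    channels = apply_optics(channels, preset, rng) if noise else _noise_free(channels, preset)
    truth = GroundTruth(
        kind=f"lysosome_{kind}", seed=seed, preset=preset.group,
        data={"diameters_nm": placed_diam, "centers_px": centers,
              "n_requested": n, "n_placed": len(centers)},
    )
    return CellImage(channels=channels, pixel_size_nm=preset.lysosome_pixel_nm,
                     bit_depth=preset.bit_depth), truth


# ---------------------------------------------------------------------------
# Golgi images
# ---------------------------------------------------------------------------

def _ellipse_radius(theta: float, a: float, b: float, rot: float) -> float:
    t = theta - rot
    return a * b / np.hypot(b * np.cos(t), a * np.sin(t))


def make_golgi_image(preset: GeneratorPreset, seed: int, noise: bool = True
                     ) -> tuple[CellImage, GroundTruth]:
    """Render DAPI (nucleus ellipse) + TGN46 (Golgi fragment blobs) for one
    cell, planting the fragmentation class label.

    A cell is drawn fragmented with probability ``golgi_fragmented_prob``.
    Fragmented cells receive ``6 + Poisson(golgi_frag_count_lambda)``
    fragments and a farthest-fragment displacement from the per-class normal;
    unfragmented cells receive at most 5 fragments with displacement truncated
    safely below the classifier's distance bound (2x nucleus equivalent
    radius).
    """
    rng = np.random.default_rng(seed)
    size = preset.golgi_field_px
    px_um = preset.golgi_pixel_nm / 1000.0
    dapi = np.zeros((size, size))
    tgn = np.zeros((size, size))
    cy, cx = size / 2.0, size / 2.0
    a_px = preset.nucleus_axes_um[0] / px_um
    b_px = preset.nucleus_axes_um[1] / px_um
    rot = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    yr = (yy - cy) * np.cos(rot) + (xx - cx) * np.sin(rot)
    xr = -(yy - cy) * np.sin(rot) + (xx - cx) * np.cos(rot)
    dapi[(yr / a_px) ** 2 + (xr / b_px) ** 2 <= 1.0] = 180.0
    r_eq_um = np.sqrt(a_px * b_px) * px_um  # ellipse equivalent radius

    fragmented = bool(rng.random() < preset.golgi_fragmented_prob)
    if fragmented:
        n_frag = 6 + int(rng.poisson(preset.golgi_frag_count_lambda))
        disp = rng.normal(preset.golgi_disp_frag_mean_um, preset.golgi_disp_frag_sd_um)
        disp = float(np.clip(disp, 0.5, 28.0))
    else:
        n_frag = min(5, 1 + int(rng.poisson(preset.golgi_unfrag_count_lambda)))
        upper = 0.9 * 2.0 * r_eq_um
        disp = rng.normal(preset.golgi_disp_unfrag_mean_um, preset.golgi_disp_unfrag_sd_um)
        while not (0.3 < disp < upper):
            disp = rng.normal(preset.golgi_disp_unfrag_mean_um, preset.golgi_disp_unfrag_sd_um)
        disp = float(disp)

    centers: list[tuple[float, float]] = []

    def _place(dist_um: float) -> tuple[float, float] | None:
        for _ in range(150):
            theta = rng.uniform(0, 2 * np.pi)
            r_n = _ellipse_radius(theta, a_px, b_px, rot)
            rr = r_n + dist_um / px_um
            pos = (cy + rr * np.sin(theta), cx + rr * np.cos(theta))
            if not (6 <= pos[0] < size - 6 and 6 <= pos[1] < size - 6):
                continue
            if all(np.hypot(pos[0] - y0, pos[1] - x0) > 9 for y0, x0 in centers):
                return pos
        return None

    pos = _place(disp)
    if pos is None:  # pathological preset; keep the cell usable
        pos = (cy + (a_px + disp / px_um), cx)
    centers.append(pos)
    placed = 1
    for _ in range(n_frag - 1):
        d_i = rng.uniform(0.3, max(0.4, disp - 0.3))
        p = _place(d_i)
        if p is None:
            logger.info("could not place Golgi fragment; reducing count")
            continue
        centers.append(p)
        placed += 1
    for y0, x0 in centers:
        _add_blob(tgn, y0, x0, preset.golgi_blob_sigma_px, preset.golgi_amp)

    channels = {"DAPI": dapi, "TGN46": tgn}
    channels = apply_optics(channels, preset, rng) if noise else _noise_free(channels, preset)
    truth = GroundTruth(
        kind="golgi", seed=seed, preset=preset.group,
        data={"fragmented": fragmented, "fragment_count": placed,
              "nucleus_distance_um": disp, "nucleus_r_eq_um": float(r_eq_um)},
    )
    return CellImage(channels=channels, pixel_size_nm=preset.golgi_pixel_nm,
                     bit_depth=preset.bit_depth), truth


# ---------------------------------------------------------------------------
# colocalization images
# ---------------------------------------------------------------------------

def make_coloc_image(preset: GeneratorPreset, seed: int, noise: bool = True
                     ) -> tuple[CellImage, GroundTruth]:
    """Render TGN46 (trans-Golgi cluster) + GALA (enzyme) channels.

    The per-cell planted fraction of enzyme intensity inside the Golgi mask
    is drawn around ``coloc_fraction_mean`` and planted exactly: the inside
    (Golgi-co-resident blobs) and outside (peripheral puncta) patterns are
    rendered at optical resolution, the Golgi mask is binarized the same way
    the colocalization operator does it (Otsu with a noise floor), and the
    mixing weight is solved so the pre-noise fraction inside the mask equals
    the draw.
    """
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(seed)
    size = preset.coloc_field_px
    tgn = np.zeros((size, size))
    gcy = size / 2.0 + rng.uniform(-10, 10)
    gcx = size / 2.0 + rng.uniform(-10, 10)
    blob_centers = []
    for _ in range(6):
        by = gcy + rng.normal(0, 8)
        bx = gcx + rng.normal(0, 8)
        blob_centers.append((by, bx))
        _add_blob(tgn, by, bx, 4.0, 140.0)

    f = float(np.clip(rng.normal(preset.coloc_fraction_mean, preset.coloc_fraction_sd),
                      0.02, 0.98))
    p_in = np.zeros((size, size))
    for by, bx in blob_centers:
        _add_blob(p_in, by + rng.normal(0, 1.0), bx + rng.normal(0, 1.0), 2.2, 1.0)
    p_out = np.zeros((size, size))
    n_out = 0
    while n_out < 14:
        py, px_ = rng.uniform(8, size - 8, size=2)
        if np.hypot(py - gcy, px_ - gcx) > 60:
            _add_blob(p_out, py, px_, 1.8, 1.0)
            n_out += 1

    # work at optical resolution so the planted fraction survives the PSF
    sigma = preset.psf_sigma_px if noise else 0.0
    if sigma > 0:
        tgn_b = gaussian_filter(tgn, sigma)
        p_in_b = gaussian_filter(p_in, sigma)
        p_out_b = gaussian_filter(p_out, sigma)
    else:
        tgn_b, p_in_b, p_out_b = tgn, p_in, p_out
    mask = tgn_b > max(threshold_otsu(tgn_b), 0.25 * tgn_b.max())
    a = p_in_b[mask].sum() / p_in_b.sum()
    b = p_out_b[mask].sum() / p_out_b.sum()
    w = float(np.clip((f - b) / (a - b), 0.0, 1.0))
    enzyme = w * p_in_b / p_in_b.sum() + (1 - w) * p_out_b / p_out_b.sum()
    enzyme *= 170.0 / enzyme.max()
    planted = float(enzyme[mask].sum() / enzyme.sum())

    channels = {"TGN46": tgn_b, "GALA": enzyme}
    channels = apply_noise(channels, preset, rng) if noise else _noise_free(channels, preset)
    truth = GroundTruth(kind="coloc", seed=seed, preset=preset.group,
                        data={"planted_fraction": planted, "drawn_fraction": f})
    return CellImage(channels=channels, pixel_size_nm=preset.coloc_pixel_nm,
                     bit_depth=preset.bit_depth), truth


# ---------------------------------------------------------------------------
# p62 images
# ---------------------------------------------------------------------------

def make_p62_image(preset: GeneratorPreset, seed: int, noise: bool = True
                   ) -> tuple[CellImage, GroundTruth]:
    """Render CELL (diffuse cytoplasm, for the cell mask) + P62 (puncta)."""
    rng = np.random.default_rng(seed)
    size = preset.p62_field_px
    px_um = preset.p62_pixel_nm / 1000.0
    cell = np.zeros((size, size))
    cy, cx = size / 2.0, size / 2.0
    area_px = preset.cell_area_um2 / px_um**2
    ecc = rng.uniform(1.1, 1.5)
    b_px = np.sqrt(area_px / (np.pi * ecc))
    a_px = ecc * b_px
    rot = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    yr = (yy - cy) * np.cos(rot) + (xx - cx) * np.sin(rot)
    xr = -(yy - cy) * np.sin(rot) + (xx - cx) * np.cos(rot)
    inside = (yr / a_px) ** 2 + (xr / b_px) ** 2 <= 1.0
    cell[inside] = 45.0
    true_area_um2 = float(inside.sum()) * px_um**2

    n_puncta = int(rng.poisson(preset.p62_rate_per_um2 * true_area_um2))
    p62 = np.zeros((size, size))
    centers: list[tuple[float, float]] = []
    placed = 0
    for _ in range(n_puncta):
        ok = False
        for _ in range(150):
            t = rng.uniform(0, 2 * np.pi)
            r = 0.92 * np.sqrt(rng.random())
            pos = (cy + r * a_px * np.sin(t + rot) * 1.0, cx + r * b_px * np.cos(t + rot))
            iy, ix = int(pos[0]), int(pos[1])
            if not (0 <= iy < size and 0 <= ix < size and inside[iy, ix]):
                continue
            if all(np.hypot(pos[0] - y0, pos[1] - x0) > 8 for y0, x0 in centers):
                ok = True
                break
        if not ok:
            logger.info("could not place p62 punctum; reducing count")
            continue
        centers.append(pos)
        placed += 1
        _add_blob(p62, pos[0], pos[1], 1.2, preset.p62_amp)
    p62 += 0.05 * cell  # faint diffuse cytoplasmic p62

    channels = {"CELL": cell, "P62": p62}
    channels = apply_optics(channels, preset, rng) if noise else _noise_free(channels, preset)
    truth = GroundTruth(
        kind="p62", seed=seed, preset=preset.group,
        data={"n_aggregates": placed, "cell_area_um2": true_area_um2,
              "density_per_um2": placed / true_area_um2},
    )
    return CellImage(channels=channels, pixel_size_nm=preset.p62_pixel_nm,
                     bit_depth=preset.bit_depth), truth


# ---------------------------------------------------------------------------
# LysoSensor images
# ---------------------------------------------------------------------------

def make_lysosensor_image(preset: GeneratorPreset, seed: int, noise: bool = True
                          ) -> tuple[CellImage, GroundTruth]:
    """Render an acidotropic-dye punctate channel whose brightness scales with
    the cell's (relative) lysosomal acidity."""
    rng = np.random.default_rng(seed)
    size = preset.lysosensor_field_px
    img = np.zeros((size, size))
    scale = max(0.1, float(rng.normal(preset.lysosensor_mean, preset.lysosensor_sd)))
    amp = preset.lysosensor_base_amp * scale
    centers: list[tuple[float, float]] = []
    cy, cx = size / 2.0, size / 2.0
    for _ in range(preset.lysosensor_n_puncta):
        for _ in range(150):
            pos = (rng.uniform(10, size - 10), rng.uniform(10, size - 10))
            if np.hypot(pos[0] - cy, pos[1] - cx) > 0.45 * size:
                continue
            if all(np.hypot(pos[0] - y0, pos[1] - x0) > 7 for y0, x0 in centers):
                centers.append(pos)
                _add_blob(img, pos[0], pos[1], 1.5, amp)
                break
    channels = {"LYSOSENSOR": img}
    channels = apply_optics(channels, preset, rng) if noise else _noise_free(channels, preset)
    truth = GroundTruth(kind="lysosensor", seed=seed, preset=preset.group,
                        data={"intensity_scale": scale})
    return CellImage(channels=channels, pixel_size_nm=preset.lysosensor_pixel_nm,
                     bit_depth=preset.bit_depth), truth


_KIND_DISPATCH = {
    "size": lambda p, s, noise: make_lysosome_image(p, s, kind="size", noise=noise),
    "network": lambda p, s, noise: make_lysosome_image(p, s, kind="network", noise=noise),
    "golgi": make_golgi_image,
    "coloc": make_coloc_image,
    "p62": make_p62_image,
    "lysosensor": make_lysosensor_image,
}


def make_cell_image(preset: GeneratorPreset, seed: int, kind: str = "size",
                    noise: bool = True) -> tuple[CellImage, GroundTruth]:
    """Dispatch to the per-readout renderer (size / network / golgi / coloc /
    p62 / lysosensor)."""
    try:
        fn = _KIND_DISPATCH[kind]
    except KeyError:
        raise ValueError(f"unknown image kind {kind!r}; choose from {sorted(_KIND_DISPATCH)}") from None
    if kind in ("size", "network"):
        return fn(preset, seed, noise)
    return fn(preset, seed, noise=noise)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

DEFAULT_CLASS_FRACTIONS = {"B": 0.2, "LB": 0.1, "VUS": 0.5, "LP": 0.15, "P": 0.05}


def make_variant_table(
    seed: int,
    n_variants: int,
    class_fractions: dict | None = None,
    predictor_agreement: float = 0.8,
    rubric: KDARubric = DEFAULT_RUBRIC,
    include_reference: bool = True,
) -> tuple[list[AnnotatedVariant], GroundTruth]:
    """Generate an annotated variant table with stored rubric-true scores.

    ``class_fractions`` sets the ACMG class mix (must be non-negative and sum
    to 1); predictor calls agree with the class's deleterious tendency with
    probability ``predictor_agreement``. When ``include_reference`` is true
    the eight published candidate rows are appended verbatim after the
    random records.
    """
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    if any(f < 0 for f in fractions.values()) or abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(fractions)
    probs = np.array([fractions[c] for c in classes])
    deleterious_prob = {"B": 0.1, "LB": 0.2, "VUS": 0.5, "LP": 0.85, "P": 0.95}

    variants: list[AnnotatedVariant] = []
    for i in range(n_variants):
        acmg = classes[int(rng.choice(len(classes), p=probs))]
        tier = rng.random()
        if tier < 0.25:
            maf = None
        elif tier < 0.55:
            maf = float(10 ** rng.uniform(-7, np.log10(5e-6)))
        elif tier < 0.85:
            maf = float(10 ** rng.uniform(np.log10(5e-6), -3))
        else:
            maf = float(10 ** rng.uniform(-3, -1.5))
        base = deleterious_prob[acmg]

        def call() -> bool | None:
            r = rng.random()
            if r > 0.95:
                return None
            return bool(rng.random() < (base if rng.random() < predictor_agreement else 1 - base))

        tags = frozenset(
            t for t in ("LY", "ATP", "GLG", "NR", "MIT") if rng.random() < 0.3
        )
        v = AnnotatedVariant(
            gene_symbol=f"GENE{i:05d}",
            protein_change=f"p.(Ala{100 + i}Val)",
            cdna_change=f"c.{300 + 3 * i}C>T",
            inheritance=("M", "F", "de_novo", "unknown")[int(rng.integers(4))],
            caller_count=int(rng.integers(1, 5)),
            maf_nfe=maf,
            maf_any_population_max=maf,
            cadd_phred=float(rng.uniform(5, 40)),
            acmg_class=acmg,
            consequence=("missense", "synonymous", "intronic", "lof", "other")[
                int(rng.choice(5, p=[0.7, 0.1, 0.1, 0.05, 0.05]))
            ],
            mutationtaster_call=call(),
            polyphen2_call=call(),
            sift_call=call(),
            fathmm_mkl_call=call(),
            spliceai_flag=bool(rng.random() < 0.05) or None,
            gerp_score=float(rng.uniform(-2, 6)),
            missense_z=float(rng.uniform(-2, 5)),
            pli=float(rng.random()),
            brain_expression=bool(rng.random() < 0.7),
            pathway_tags=tags,
        )
        variants.append(v)

    if include_reference:
        variants.extend(REFERENCE_VARIANTS.values())

    # rubric-true component scores, by explicit per-criterion loop
    true_scores = []
    for v in variants:
        comp = {c: rubric.score(v, c) for c in CRITERIA}
        true_scores.append({"label": v.label, "components": comp,
                            "total": sum(comp.values())})
    truth = GroundTruth(
        kind="variant_table", seed=seed, preset=None,
        data={"class_fractions": fractions, "scores": true_scores,
              "n_random": n_variants},
    )
    return variants, truth


__all__ = [
    "GroundTruth",
    "apply_optics",
    "make_lysosome_image",
    "make_golgi_image",
    "make_coloc_image",
    "make_p62_image",
    "make_lysosensor_image",
    "make_cell_image",
    "make_variant_table",
    "DEFAULT_CLASS_FRACTIONS",
]
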