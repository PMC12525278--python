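"""Quantitative readouts of organelle biology in fibroblast images.

Operators: Manders colocalization (M1 and the intensity-weighted overlap
coefficient), lysosome diameter from the peak-to-peak distance of a line
intensity profile, lysosomal-network porosity over 50x50-px tiles, Golgi
morphology (farthest-point nucleus distance, fragment count, fragmentation
classification), p62 aggregate density per cell area, LysoSensor relative
intensity, and densitometry against a protein standard curve.

All image-derived measures run on maximum projections; physical units come in
only through the image pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.stats import linregress
from skimage.filters import threshold_otsu
from skimage.measure import label as _sklabel

from .image import CellImage, LabelMask, line_profile, segment_channel


@dataclass
class MorphometryRecord:
    """One measurement of one cell (tidy-table row)."""

    cell_id: str
    group: str
    replicate: int
    measure: str
    value: float
    units: str


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class GolgiMorphology:
    classification: str  # "unfragmented" | "fragmented_or_beehive"
    fragment_count: int
    nucleus_distance_um: float


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def manders_m1(ref_channel, other_channel, other_mask) -> float:
    """Fraction of total ``ref`` intensity lying within ``other_mask``.

    M1 = sum(ref[mask]) / sum(ref); 0 when the reference channel is empty.
    """
    ref = np.asarray(ref_channel, dtype=float)
    other_mask = np.asarray(other_mask, dtype=bool)
    if ref.shape != other_mask.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs mask {other_mask.shape}")
    total = ref.sum()
    if total == 0:
        return 0.0
    return float(ref[other_mask].sum() / total)


def overlap_coefficient(ref_channel, other_channel) -> float:
    """Intensity-weighted overlap, sum(R*G) / sqrt(sum(R^2) * sum(G^2)).

    Lies in [0, 1] for non-negative channels and is invariant under positive
    rescaling of either channel (Cauchy-Schwarz).
    """
    r = np.asarray(ref_channel, dtype=float).ravel()
    g = np.asarray(other_channel, dtype=float).ravel()
    if r.shape != g.shape:
        raise ValueError("shape mismatch between channels")
    rr, gg = (r**2).sum(), (g**2).sum()
    if rr == 0 and gg == 0:
        raise ValueError("both channels are all-zero")
    if rr == 0 or gg == 0:
        return 0.0
    return float((r * g).sum() / np.sqrt(rr * gg))


def measure_manders(
    image: CellImage,
    ref_role: str,
    other_role: str,
    background: str | float | None = "otsu",
) -> float:
    """Per-cell M1 of ``ref_role`` inside the Otsu mask of ``other_role``.

    ``background`` controls reference-channel background subtraction before
    the ratio: ``"otsu"`` estimates the background from sub-threshold
    reference pixels (their mean plus one standard deviation, covering the
    camera offset and most of the read-noise floor), a float subtracts that
    constant, ``None`` uses the raw channel.
    """
    ref = image.plane(ref_role).astype(float)
    mask = segment_channel(image, other_role, min_object_px=1, floor_frac=0.25).binary()
    if background is not None:
        if background == "otsu":
            if ref.max() > ref.min():
                bg = ref[ref <= threshold_otsu(ref)]
                level = float(bg.mean() + bg.std())
            else:
                level = 0.0
        else:
            level = float(background)
        ref = np.clip(ref - level, 0, None)
    return manders_m1(ref, image.plane(other_role), mask)


# ---------------------------------------------------------------------------
# lysosome size
# ---------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def profile_peak_distance(
    profile, spacing_nm: float, smooth: int = 3, prominence_frac: float = 0.10
) -> tuple[float, bool]:
    """Distance in nm between the two outermost local maxima of a profile.

    The profile is smoothed with a centered moving mean; peaks must have a
    prominence of at least ``prominence_frac`` of the profile range; peak
    positions are refined by parabolic interpolation. Returns ``(nm,
    resolved)``: with a single peak (unresolved object) the full width at
    half maximum is returned and ``resolved`` is False.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile too short (need at least 3 samples)")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="same")
    rng = y.max() - y.min()
    if rng == 0:
        raise ValueError("flat profile: no peaks")
    peaks, _ = find_peaks(y, prominence=prominence_frac * rng)
    if peaks.size >= 2:
        left = _parabolic_refine(y, int(peaks[0]))
        right = _parabolic_refine(y, int(peaks[-1]))
        return (right - left) * spacing_nm, True
    # unresolved: report FWHM around the global maximum
    if peaks.size == 1:
        imax = int(peaks[0])
    else:
        imax = int(np.argmax(y))
    half = y.min() + 0.5 * rng
    above = y >= half
    left = imax
    while left > 0 and above[left - 1]:
        left -= 1
    right = imax
    while right < y.size - 1 and above[right + 1]:
        right += 1
    return (right - left) * spacing_nm, False


def lysosome_diameter(
    image: CellImage,
    mask: LabelMask,
    object_label: int,
    smooth: int = 3,
    prominence_frac: float = 0.10,
    margin_px: float = 4.0,
    role: str = "LAMP1",
) -> tuple[float, bool]:
    """Diameter (nm) of one labeled lysosome.

    An intensity profile is taken through the object centroid along its major
    axis (principal component of the pixel coordinates), extended by
    ``margin_px`` beyond the object to capture the rim peaks; the diameter is
    the distance between the two outermost profile peaks. Membrane-marker
    staining outlines the organelle, so a resolved lysosome shows two rim
    peaks; single-peak objects fall back to the FWHM with ``resolved=False``.
    """
    obj = mask.labels == object_label
    coords = np.argwhere(obj)
    if coords.shape[0] < 3:
        raise ValueError(f"object {object_label} smaller than 3 pixels")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    extent = np.abs(centered @ direction).max() + margin_px
    ny, nx = mask.labels.shape
    p0 = center - direction * extent
    p1 = center + direction * extent
    p0 = np.clip(p0, [0, 0], [ny - 1, nx - 1])
    p1 = np.clip(p1, [0, 0], [ny - 1, nx - 1])
    prof = line_profile(image, role, p0, p1)
    return profile_peak_distance(
        prof.values, prof.spacing_nm, smooth=smooth, prominence_frac=prominence_frac
    )


def measure_lysosome_diameters(
    image: CellImage, role: str = "LAMP1", min_object_px: int = 8, **kwargs
) -> list[tuple[int, float, bool]]:
    """Segment the lysosome channel and size every object.

    Returns ``(label, diameter_nm, resolved)`` per object; objects too small
    to profile are skipped.
    """
    mask = segment_channel(image, role, min_object_px=min_object_px)
    out = []
    for lab in range(1, mask.n_objects + 1):
        try:
            nm, resolved = lysosome_diameter(image, mask, lab, role=role, **kwargs)
        except ValueError:
            continue
        out.append((lab, nm, resolved))
    return out


# ---------------------------------------------------------------------------
# network porosity
# ---------------------------------------------------------------------------

def _binary_closing_edt(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing with a Euclidean disk via two distance
    transforms (fast for large radii)."""
    dilated = ndimage.distance_transform_edt(~mask) <= radius
    return ndimage.distance_transform_edt(dilated) > radius


def network_region(lysosome_mask, closing_radius_px: float = 25.0) -> np.ndarray:
    """Hull of the lysosomal network: morphological closure of the signal
    mask (bridging gaps up to ~2x the closing radius), reduced to its largest
    connected component so stray satellite objects do not shift the tiling
    grid off the main network."""
    mask = np.asarray(lysosome_mask, dtype=bool)
    closed = _binary_closing_edt(mask, closing_radius_px)
    labels, n = ndimage.label(closed)
    if n <= 1:
        return closed
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def network_porosity(
    lysosome_mask, region=None, tile_px: int = 50, closing_radius_px: float = 25.0
) -> np.ndarray:
    """Per-tile porosity (%) of the lysosomal network.

    Tiles of ``tile_px`` x ``tile_px`` are laid on a regular grid anchored at
    the region bounding-box origin; only tiles entirely inside the region are
    kept. Within a tile, a pore is a region pixel not covered by lysosome
    signal; porosity = 100 * pores / tile area. High porosity = sparse,
    dispersed network; low = tight clustering.
    """
    mask = np.asarray(lysosome_mask, dtype=bool)
    if region is None:
        region = network_region(mask, closing_radius_px)
    region = np.asarray(region, dtype=bool)
    rows = np.any(region, axis=1)
    cols = np.any(region, axis=0)
    if not rows.any():
        raise ValueError("empty network region")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    if (r1 - r0 + 1) < tile_px or (c1 - c0 + 1) < tile_px:
        raise ValueError(
            f"network region ({r1 - r0 + 1}x{c1 - c0 + 1} px) smaller than one "
            f"{tile_px}x{tile_px} tile; use a smaller tile_px or a larger field"
        )
    porosities = []
    for r in range(r0, r1 - tile_px + 2, tile_px):
        for c in range(c0, c1 - tile_px + 2, tile_px):
            tile_region = region[r : r + tile_px, c : c + tile_px]
            if tile_region.shape != (tile_px, tile_px) or not tile_region.all():
                continue  # straddles the region boundary
            tile_signal = mask[r : r + tile_px, c : c + tile_px]
            pores = tile_px * tile_px - int(tile_signal.sum())
            porosities.append(100.0 * pores / (tile_px * tile_px))
    return np.asarray(porosities)


def measure_porosity(
    image: CellImage, role: str = "LAMP1", tile_px: int = 50,
    closing_radius_px: float = 25.0, min_object_px: int = 8,
) -> np.ndarray:
    """Segment the lysosome channel (objects hole-filled, so the measure sees
    whole organelles rather than membrane rims) and tile the closed network."""
    seg = segment_channel(image, role, min_object_px=min_object_px)
    filled = ndimage.binary_fill_holes(seg.binary())
    return network_porosity(filled, tile_px=tile_px, closing_radius_px=closing_radius_px)


# ---------------------------------------------------------------------------
# Golgi morphology
# ---------------------------------------------------------------------------

def golgi_metrics(
    golgi_mask,
    nucleus_mask,
    pixel_size_nm: float,
    max_fragments: int = 5,
    distance_factor: float = 2.0,
    connectivity: int = 1,
) -> GolgiMorphology:
    """Golgi fragmentation metrics of one cell.

    The farthest Golgi pixel from the nucleus centroid is located; the
    nucleus distance is from that pixel to the nearest nucleus pixel (um).
    Fragment count is the number of connected components of the Golgi mask.
    A cell is called ``fragmented_or_beehive`` when the count exceeds
    ``max_fragments`` or the distance exceeds ``distance_factor`` times the
    nucleus equivalent radius.
    """
    golgi = np.asarray(golgi_mask, dtype=bool)
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus.any():
        raise ValueError("empty nucleus mask")
    if not golgi.any():
        raise ValueError("empty Golgi mask")
    if golgi.shape != nucleus.shape:
        raise ValueError("mask shapes differ")
    centroid = np.argwhere(nucleus).mean(axis=0)
    gcoords = np.argwhere(golgi)
    d2 = ((gcoords - centroid) ** 2).sum(axis=1)
    farthest = gcoords[int(np.argmax(d2))]
    dist_to_nucleus_px = ndimage.distance_transform_edt(~nucleus)[tuple(farthest)]
    dist_um = float(dist_to_nucleus_px) * pixel_size_nm / 1000.0
    structure = ndimage.generate_binary_structure(2, connectivity)
    _, n_fragments = ndimage.label(golgi, structure=structure)
    r_eq_um = np.sqrt(nucleus.sum() / np.pi) * pixel_size_nm / 1000.0
    fragmented = (n_fragments > max_fragments) or (dist_um > distance_factor * r_eq_um)
    return GolgiMorphology(
        classification="fragmented_or_beehive" if fragmented else "unfragmented",
        fragment_count=int(n_fragments),
        nucleus_distance_um=dist_um,
    )


def measure_golgi(
    image: CellImage, golgi_role: str = "TGN46", nucleus_role: str = "DAPI",
    min_object_px: int = 6, floor_frac: float = 0.25, **kwargs
) -> GolgiMorphology:
    golgi = segment_channel(image, golgi_role, min_object_px=min_object_px,
                            floor_frac=floor_frac).binary()
    nucleus = segment_channel(image, nucleus_role, min_object_px=min_object_px,
                              floor_frac=floor_frac).binary()
    nucleus = ndimage.binary_fill_holes(nucleus)
    return golgi_metrics(golgi, nucleus, image.pixel_size_nm, **kwargs)


# ---------------------------------------------------------------------------
# p62 aggregates
# ---------------------------------------------------------------------------

def p62_aggregate_density(
    p62_channel,
    cell_mask,
    pixel_size_nm: float,
    min_area_um2: float = 0.05,
    max_area_um2: float = 5.0,
    threshold: float | None = None,
    floor_frac: float = 0.25,
) -> float:
    """Aggregates per um^2 of cell area.

    An aggregate is a thresholded (Otsu by default) connected component inside
    the cell mask with area within the configured band.
    """
    p62 = np.asarray(p62_channel, dtype=float)
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValueError("empty cell mask")
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    cell_area_um2 = float(cell.sum()) * px_area_um2
    if p62.max() == p62.min():
        return 0.0
    t = threshold_otsu(p62) if threshold is None else threshold
    t = max(t, floor_frac * p62.max())
    binary = (p62 > t) & cell
    labels = _sklabel(binary, connectivity=1)
    if labels.max() == 0:
        return 0.0
    sizes = np.bincount(labels.ravel())[1:] * px_area_um2
    n = int(((sizes >= min_area_um2) & (sizes <= max_area_um2)).sum())
    return n / cell_area_um2


# ---------------------------------------------------------------------------
# LysoSensor
# ---------------------------------------------------------------------------

def cell_mean_intensity(image: CellImage, role: str = "LYSOSENSOR",
                        floor_frac: float = 0.25) -> float:
    """Mean intensity within the channel's segmented (Otsu) signal."""
    plane = image.plane(role).astype(float)
    mask = segment_channel(image, role, min_object_px=1, floor_frac=floor_frac).binary()
    if not mask.any():
        return 0.0
    return float(plane[mask].mean())


def lysosensor_relative_intensity(
    intensities_by_group: dict, control_group: str = "CT"
) -> dict:
    """Normalize per-cell mean intensities to the control group.

    ``intensities_by_group`` maps group -> list of replicates, each a sequence
    of per-cell mean intensities. Each replicate's cells are divided by the
    control group's mean of the same replicate index, so the control grand
    mean is ~1 by construction. Returns the same structure in relative units.
    """
    if control_group not in intensities_by_group:
        raise ValueError(f"control group {control_group!r} absent")
    control = [np.asarray(rep, dtype=float) for rep in intensities_by_group[control_group]]
    if not control:
        raise ValueError("control group is empty")
    control_means = [rep.mean() for rep in control]
    if any(m == 0 for m in control_means):
        raise ValueError("zero control-replicate mean")
    out = {}
    for group, reps in intensities_by_group.items():
        out[group] = [
            np.asarray(rep, dtype=float) / control_means[min(i, len(control_means) - 1)]
            for i, rep in enumerate(reps)
        ]
    return out


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def standard_curve_quantify(band_intensities, standards) -> list[tuple[float, bool]]:
    """Quantify band masses (ng) against a protein standard curve.

    ``standards`` is a sequence of ``(intensity, mass_ng)`` pairs (at least
    two, with distinct intensities); an ordinary least-squares line maps
    intensity to ng. Returns ``(mass_ng, in_range)`` per unknown band, where
    ``in_range`` is False when the band intensity falls outside the standard
    intensity range (extrapolated value).
    """
    standards = [(float(i), float(m)) for i, m in standards]
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    xs = np.array([s[0] for s in standards])
    ys = np.array([s[1] for s in standards])
    if np.unique(xs).size < 2:
        raise ValueError("degenerate standards: identical intensities")
    fit = linregress(xs, ys)
    lo, hi = xs.min(), xs.max()
    out = []
    for b in band_intensities:
        mass = fit.slope * float(b) + fit.intercept
        out.append((float(mass), bool(lo <= b <= hi)))
    return out


__all__ = [
    "MorphometryRecord",
    "GolgiMorphology",
    "records_to_frame",
    "manders_m1",
    "overlap_coefficient",
    "measure_manders",
    "profile_peak_distance",
    "lysosome_diameter",
    "measure_lysosome_diameters",
    "network_region",
    "network_porosity",
    "measure_porosity",
    "golgi_metrics",
    "measure_golgi",
    "p62_aggregate_density",
    "cell_mean_intensity",
    "lysosensor_relative_intensity",
    "standard_curve_quantify",
]
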