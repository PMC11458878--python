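"""Seeded synthetic scanner images with ground-truth sidecars.

Emulates the 16-bit grayscale output of a fluorescence slide scanner imaging
a hydrogel-post well array, with the failure modes the real assay exhibits:
bright dust specks stuck to posts (saturating blobs) and fallen posts
(rendered at background).  Every downstream stage — grid location,
max-average window extraction, artifact QC, imputation, masking — is
testable against the returned :class:`SimulationTruth` without any real scan.

All randomness flows from one explicit seed; identical seed + parameters
give bit-identical images.  The default noise model is additive Gaussian
with configurable sigma followed by rounding and 16-bit clipping; a Poisson
(shot-noise) mode is available.  Optics are deliberately idealized: no PSF,
no bleed-through, no tissue texture — posts are rendered as flat square
blocks, which is exactly what makes noiseless round-trip tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from shapely import affinity
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .geometry import ArrayGeometry, post_rect

__all__ = [
    "SimulationTruth",
    "uniform_truth",
    "inject_artifacts",
    "simulate_scan",
    "simulate_tissue_mask",
    "ellipse_region",
    "leaf_section_truth",
    "SATURATION",
    "CLEAN",
    "DUST",
    "FALLEN",
]

SATURATION = 65535
CLEAN, DUST, FALLEN = "clean", "dust", "fallen"

DEFAULT_ANCHOR = (20, 20)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated scan.

    ``intensities`` holds each post's true fluorescence (AFU) with shape
    ``(n_rows, n_cols, posts_per_well)``; ``labels`` the per-post artifact
    state (clean/dust/fallen); ``tissue_fraction`` the per-well fraction of
    the footprint covered by tissue.
    """

    intensities: np.ndarray
    labels: np.ndarray
    background: float
    noise_model: str = "gaussian"
    noise_sigma: float = 0.0
    seed: int = 0
    tissue_fraction: np.ndarray | None = None
    grid_anchor: tuple[int, int] = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (n_rows, n_cols, posts_per_well)")
        if self.labels.shape != self.intensities.shape:
            raise ValueError("labels shape must match intensities")
        # invariant: true intensities lie in [0, SATURATION] after clipping
        self.intensities = np.clip(self.intensities, 0, SATURATION)
        bad = set(np.unique(self.labels)) - {CLEAN, DUST, FALLEN}
        if bad:
            raise ValueError(f"unknown artifact labels: {bad}")
        if self.tissue_fraction is not None:
            tf = np.asarray(self.tissue_fraction, dtype=float)
            if tf.shape != self.intensities.shape[:2]:
                raise ValueError("tissue_fraction must be (n_rows, n_cols)")
            if np.any(tf < 0) or np.any(tf > 1):
                raise ValueError("tissue fractions must lie in [0, 1]")
            self.tissue_fraction = tf
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def label_counts(self) -> dict[str, int]:
        flat = self.labels.ravel()
        return {k: int(np.sum(flat == k)) for k in (CLEAN, DUST, FALLEN)}

    def fallen_set(self) -> set[tuple[int, int, int]]:
        return {tuple(idx) for idx in np.argwhere(self.labels == FALLEN)}


def uniform_truth(
    geometry: ArrayGeometry,
    post_intensities: float | Mapping[int, float] | np.ndarray,
    background: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SimulationTruth:
    """Truth with every well identical: one intensity per post sub-position."""
    shape = (geometry.n_rows, geometry.n_cols, geometry.posts_per_well)
    if np.isscalar(post_intensities):
        inten = np.full(shape, float(post_intensities))
    elif isinstance(post_intensities, Mapping):
        inten = np.empty(shape)
        for p in range(geometry.posts_per_well):
            inten[:, :, p] = post_intensities[p]
    else:
        arr = np.asarray(post_intensities, dtype=float)
        inten = np.broadcast_to(arr, shape).copy()
    labels = np.full(shape, CLEAN, dtype=object)
    return SimulationTruth(
        intensities=inten,
        labels=labels,
        background=background,
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )


def inject_artifacts(
    truth: SimulationTruth,
    n_dust: int = 0,
    n_fallen: int = 0,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Randomly relabel clean posts as dust or fallen (without replacement)."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    labels = truth.labels.copy()
    clean_idx = np.argwhere(labels == CLEAN)
    total = n_dust + n_fallen
    if total > len(clean_idx):
        raise ValueError(f"cannot inject {total} artifacts into {len(clean_idx)} clean posts")
    chosen = clean_idx[rng.choice(len(clean_idx), size=total, replace=False)]
    for k, (r, c, p) in enumerate(chosen):
        labels[r, c, p] = DUST if k < n_dust else FALLEN
    return replace(truth, labels=labels)


def _image_shape(geometry: ArrayGeometry, anchor: tuple[int, int]) -> tuple[int, int]:
    pitch = geometry.pitch_px
    side = geometry.well_side_px
    width = int(np.ceil(anchor[0] + (geometry.n_cols - 1) * pitch + side + anchor[0]))
    height = int(np.ceil(anchor[1] + (geometry.n_rows - 1) * pitch + side + anchor[1]))
    return height, width


def simulate_scan(
    geometry: ArrayGeometry,
    truth: SimulationTruth,
    image_shape: tuple[int, int] | None = None,
    dust_radius_px: float = 6.0,
) -> tuple[np.ndarray, SimulationTruth]:
    """Render a 16-bit scan of the array described by ``truth``.

    Clean posts become flat square blocks of their true intensity at their
    grid position; dust posts a saturating disc overlapping the post; fallen
    posts are left at background.  Gaussian mode adds N(0, sigma) to every
    pixel; Poisson mode draws each pixel from Poisson(expected value).
    Values are rounded and clipped to [0, 65535] (uint16).
    """
    expected_shape = (geometry.n_rows, geometry.n_cols, geometry.posts_per_well)
    if truth.intensities.shape != expected_shape:
        raise ValueError(
            f"truth shape {truth.intensities.shape} does not match geometry {expected_shape}"
        )
    anchor = truth.grid_anchor
    min_shape = _image_shape(geometry, anchor)
    if image_shape is None:
        image_shape = min_shape
    elif image_shape[0] < min_shape[0] or image_shape[1] < min_shape[1]:
        raise ValueError(
            f"image shape {image_shape} too small for grid requiring {min_shape}"
        )

    field_f = np.full(image_shape, float(truth.background))
    rng = np.random.default_rng(truth.seed)

    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            for p in range(geometry.posts_per_well):
                label = truth.labels[r, c, p]
                x0, y0, x1, y1 = post_rect(geometry, r, c, p, anchor)
                if label == CLEAN:
                    field_f[y0:y1, x0:x1] = truth.intensities[r, c, p]
                elif label == DUST:
                    cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
                    rad = int(np.ceil(dust_radius_px))
                    yy, xx = np.mgrid[
                        max(0, int(cy) - rad) : min(image_shape[0], int(cy) + rad + 1),
                        max(0, int(cx) - rad) : min(image_shape[1], int(cx) + rad + 1),
                    ]
                    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= dust_radius_px**2
                    sub = field_f[
                        max(0, int(cy) - rad) : min(image_shape[0], int(cy) + rad + 1),
                        max(0, int(cx) - rad) : min(image_shape[1], int(cx) + rad + 1),
                    ]
                    sub[disc] = SATURATION
                # fallen: stays at background

    if truth.noise_model == "poisson":
        field_f = rng.poisson(np.clip(field_f, 0, None)).astype(float)
    elif truth.noise_sigma > 0:
        field_f = field_f + rng.normal(0.0, truth.noise_sigma, size=field_f.shape)
    image = np.clip(np.rint(field_f), 0, SATURATION).astype(np.uint16)
    return image, truth


# ---------------------------------------------------------------------------
# Tissue footprints


def ellipse_region(
    center_um: tuple[float, float],
    semi_axes_um: tuple[float, float],
    angle_deg: float = 0.0,
    quad_segs: int = 64,
) -> BaseGeometry:
    """Elliptical tissue outline in physical (um) coordinates."""
    circ = Point(center_um).buffer(1.0, quad_segs=quad_segs)
    ell = affinity.scale(circ, semi_axes_um[0], semi_axes_um[1], origin=center_um)
    if angle_deg:
        ell = affinity.rotate(ell, angle_deg, origin=center_um)
    return ell


def _well_box_um(geometry: ArrayGeometry, row: int, col: int) -> Polygon:
    pitch = geometry.well_size_um + geometry.well_spacing_um
    x0 = col * pitch
    y0 = row * pitch
    return box(x0, y0, x0 + geometry.well_size_um, y0 + geometry.well_size_um)


def simulate_tissue_mask(
    geometry: ArrayGeometry,
    region: BaseGeometry,
    seed: int | None = None,
) -> np.ndarray:
    """Fraction of each well footprint covered by ``region``, in [0, 1].

    The region is a closed shapely geometry in physical coordinates with the
    array's well (0, 0) upper-left corner at the origin.  Fractions are exact
    polygon-intersection areas (up to the polygonal approximation of curved
    outlines).  An empty region yields an all-zero table.
    """
    frac = np.zeros((geometry.n_rows, geometry.n_cols))
    if region.is_empty:
        return frac
    well_area = geometry.well_size_um**2
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            cell = _well_box_um(geometry, r, c)
            frac[r, c] = cell.intersection(region).area / well_area
    return np.clip(frac, 0.0, 1.0)


def leaf_section_truth(
    geometry: ArrayGeometry,
    abundances: Mapping[str, float],
    panel,
    background: float = 100.0,
    negative_floor: float = 30.0,
    internal_level: float = 2000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    leaf_center_um: tuple[float, float] | None = None,
    leaf_semi_axes_um: tuple[float, float] | None = None,
    vein_halfwidth_um: float | None = None,
    vein_factor: float = 1.0,
    vein_targets: tuple[str, ...] = ("miR-167a",),
) -> tuple[SimulationTruth, np.ndarray]:
    """Truth for a leaf-like tissue section over the array.

    Each endogenous post's intensity is ``background + negative_floor +
    tissue_fraction * abundances[target]``; the negative-control post sits at
    ``background + negative_floor`` everywhere (non-specific binding floor),
    so control subtraction recovers ``tissue_fraction * abundance`` exactly
    in the noiseless limit.  An optional central vein band multiplies the
    listed targets' signal by ``vein_factor``, emulating depressed abundance
    along the midvein.  Returns ``(truth, vein_mask)`` where ``vein_mask``
    flags wells whose center lies in the vein band.
    """
    pitch = geometry.well_size_um + geometry.well_spacing_um
    array_w = geometry.n_cols * pitch - geometry.well_spacing_um
    array_h = geometry.n_rows * pitch - geometry.well_spacing_um
    if leaf_center_um is None:
        leaf_center_um = (array_w / 2.0, array_h / 2.0)
    if leaf_semi_axes_um is None:
        leaf_semi_axes_um = (0.38 * array_w, 0.30 * array_h)
    region = ellipse_region(leaf_center_um, leaf_semi_axes_um)
    frac = simulate_tissue_mask(geometry, region)

    centers_y = np.arange(geometry.n_rows) * pitch + geometry.well_size_um / 2.0
    vein = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
    if vein_halfwidth_um is not None:
        in_band = np.abs(centers_y - leaf_center_um[1]) <= vein_halfwidth_um
        vein[in_band, :] = True
        vein &= frac > 0

    shape = (geometry.n_rows, geometry.n_cols, geometry.posts_per_well)
    inten = np.full(shape, background + negative_floor)
    for entry in panel.entries:
        p = entry.post_index
        if entry.role == "endogenous":
            signal = frac * abundances[entry.target_name]
            if entry.target_name in vein_targets:
                signal = np.where(vein, signal * vein_factor, signal)
            inten[:, :, p] = background + negative_floor + signal
        elif entry.role == "internal_control":
            inten[:, :, p] = internal_level
    inten = np.clip(inten, 0, SATURATION)
    labels = np.full(shape, CLEAN, dtype=object)
    truth = SimulationTruth(
        intensities=inten,
        labels=labels,
        background=background,
        noise_sigma=noise_sigma,
        seed=seed,
        tissue_fraction=frac,
    )
    return truth, vein
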