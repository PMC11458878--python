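"""Core image quantification: max-average window spot calling, artifact QC,
fallen-post imputation, and negative-control subtraction.

Each hydrogel post nominally spans an ``s x s`` pixel block (8 x 8 at
5 um/pixel for a 40 um post), but the true block can sit a few pixels off
its nominal grid position.  The measurement therefore slides an ``s x s``
window over a search region around the nominal position and reports the
window with the highest mean intensity — the max-average convolution.  The
search region defaults to the nominal window expanded by half the inter-post
gap, which keeps neighbouring posts in the same well out of each other's
search regions.

QC mirrors the assay's two failure modes: saturating dust specks (raw
intensity above an upper threshold) and fallen posts (below a lower
threshold); both are replaced by the background estimate, and fallen posts
are then repaired by averaging the same-probe posts in the up to eight
neighbouring wells.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import ArrayGeometry, post_rect, well_rect
from .panel import PanelDefinition

__all__ = [
    "measure_post",
    "quantify_image",
    "estimate_background",
    "suggest_thresholds",
    "flag_artifacts",
    "impute_fallen",
    "subtract_negative",
    "build_heatmap",
    "FLAG_CLEAN",
    "FLAG_HIGH",
    "FLAG_LOW",
    "FLAG_IMPUTED",
    "FLAG_ISOLATED",
]

SATURATION = 65535

FLAG_CLEAN = "clean"
FLAG_HIGH = "artifact_high"
FLAG_LOW = "artifact_low"
FLAG_IMPUTED = "imputed"
FLAG_ISOLATED = "isolated"

POST_COLUMNS = [
    "well_row",
    "well_col",
    "post_index",
    "target",
    "role",
    "raw_intensity",
    "qc_flag",
    "final_intensity",
    "win_x",
    "win_y",
]


def measure_post(
    image: np.ndarray,
    search_window: tuple[int, int, int, int],
    post_side_px: int,
    return_origin: bool = False,
) -> float | tuple[float, tuple[int, int]]:
    """Highest mean over all ``post_side_px``-square windows in the search region.

    ``search_window`` is a half-open pixel rectangle ``(x0, y0, x1, y1)``
    that must contain at least one full post window and lie inside the
    image.  Ties are broken by the smallest (y, then x) window origin.
    Window sums are accumulated in int64 for integer images, so the result
    is bit-exact against brute-force enumeration.
    """
    x0, y0, x1, y1 = search_window
    k = int(post_side_px)
    if k < 1:
        raise ValueError("post_side_px must be >= 1")
    if x1 - x0 < k or y1 - y0 < k:
        raise ValueError(
            f"search window {search_window} smaller than {k}x{k} post window"
        )
    if x0 < 0 or y0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValueError(f"search window {search_window} outside image {image.shape}")
    region = image[y0:y1, x0:x1]
    acc = region.astype(np.int64) if np.issubdtype(region.dtype, np.integer) else region.astype(np.float64)
    sums = sliding_window_view(acc, (k, k)).sum(axis=(2, 3))
    flat = int(np.argmax(sums))  # first occurrence = smallest (y, x) origin
    oy, ox = np.unravel_index(flat, sums.shape)
    value = float(sums[oy, ox]) / (k * k)
    if return_origin:
        return value, (x0 + int(ox), y0 + int(oy))
    return value


def _clamp_window(
    nominal: tuple[int, int, int, int],
    margin: int,
    bounds: tuple[int, int, int, int],
    image_shape: tuple[int, int],
) -> tuple[int, int, int, int]:
    x0, y0, x1, y1 = nominal
    bx0, by0, bx1, by1 = bounds
    return (
        max(x0 - margin, bx0, 0),
        max(y0 - margin, by0, 0),
        min(x1 + margin, bx1, image_shape[1]),
        min(y1 + margin, by1, image_shape[0]),
    )


def quantify_image(
    image: np.ndarray,
    geometry: ArrayGeometry,
    grid_anchor: tuple[float, float],
    pitch_px: float | None = None,
    panel: PanelDefinition | None = None,
    search_margin_px: int | None = None,
) -> pd.DataFrame:
    """Measure every post on the grid; one row per (well, post).

    ``search_margin_px`` expands each post's nominal window on all sides
    (clamped to the well interior and the image); ``None`` selects half the
    inter-post gap implied by the geometry's post layout.
    """
    if search_margin_px is None:
        offs = sorted(dx for dx, _ in geometry.post_offsets_px())
        if len(offs) > 1:
            gap = min(b - a for a, b in zip(offs, offs[1:])) - geometry.post_side_px
            search_margin_px = max(gap // 2, 0)
        else:
            search_margin_px = geometry.well_side_px  # clamped to well anyway

    rows = []
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            wrect = well_rect(geometry, r, c, grid_anchor, pitch_px)
            for p in range(geometry.posts_per_well):
                nominal = post_rect(geometry, r, c, p, grid_anchor, pitch_px)
                win = _clamp_window(nominal, search_margin_px, wrect, image.shape)
                raw, origin = measure_post(
                    image, win, geometry.post_side_px, return_origin=True
                )
                entry = panel.target_of(p) if panel is not None else None
                rows.append(
                    (
                        r,
                        c,
                        p,
                        entry.target_name if entry else f"post-{p}",
                        entry.role if entry else "unknown",
                        raw,
                        FLAG_CLEAN,
                        raw,
                        origin[0],
                        origin[1],
                    )
                )
    return pd.DataFrame(rows, columns=POST_COLUMNS)


def estimate_background(
    image: np.ndarray,
    well_rectangle: tuple[int, int, int, int],
    post_windows: Iterable[tuple[int, int, int, int]],
) -> float:
    """Median of well pixels outside all post windows.

    Falls back to the global image median (with a warning) if the post
    windows tile the entire well.
    """
    x0, y0, x1, y1 = well_rectangle
    if x0 < 0 or y0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValueError(f"well rectangle {well_rectangle} outside image {image.shape}")
    mask = np.ones((y1 - y0, x1 - x0), dtype=bool)
    for px0, py0, px1, py1 in post_windows:
        mask[
            max(py0 - y0, 0) : max(py1 - y0, 0), max(px0 - x0, 0) : max(px1 - x0, 0)
        ] = False
    pixels = image[y0:y1, x0:x1][mask]
    if pixels.size == 0:
        warnings.warn(
            "no non-post pixels in well; falling back to global image median",
            stacklevel=2,
        )
        return float(np.median(image))
    return float(np.median(pixels))


def estimate_array_background(
    image: np.ndarray,
    geometry: ArrayGeometry,
    grid_anchor: tuple[float, float],
    pitch_px: float | None = None,
    search_margin_px: int = 2,
) -> tuple[float, float]:
    """(median, MAD) of all well pixels outside the (expanded) post windows."""
    keep = []
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            x0, y0, x1, y1 = well_rect(geometry, r, c, grid_anchor, pitch_px)
            mask = np.ones((y1 - y0, x1 - x0), dtype=bool)
            for p in range(geometry.posts_per_well):
                px0, py0, px1, py1 = post_rect(geometry, r, c, p, grid_anchor, pitch_px)
                m = search_margin_px
                mask[
                    max(py0 - m - y0, 0) : py1 + m - y0,
                    max(px0 - m - x0, 0) : px1 + m - x0,
                ] = False
            keep.append(image[y0:y1, x0:x1][mask])
    pixels = np.concatenate(keep).astype(float)
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels - med)))
    return med, mad


def suggest_thresholds(
    raw_intensities: np.ndarray,
    background: float,
    background_mad: float,
) -> tuple[float, float]:
    """Data-driven (upper, lower) artifact thresholds.

    Upper: 99.9th percentile of post intensities, clipped to just below
    saturation.  Lower: background minus three (scaled) MADs.  Both are
    heuristics and should be overridden when the intensity scale is known.
    """
    upper = min(float(np.percentile(raw_intensities, 99.9)), SATURATION - 0.5)
    lower = background - 3.0 * 1.4826 * background_mad
    return upper, lower


def flag_artifacts(
    measurements: pd.DataFrame,
    upper_threshold: float,
    lower_threshold: float,
    background: float,
) -> pd.DataFrame:
    """Flag dust (above upper) and dropout (below lower) posts.

    Flagged posts have their final intensity set to the background estimate,
    realizing the protocol's "set these areas to the background signal".
    """
    if not lower_threshold < upper_threshold:
        raise ValueError(
            f"lower_threshold ({lower_threshold}) must be < upper_threshold "
            f"({upper_threshold})"
        )
    df = measurements.copy()
    high = df["raw_intensity"] > upper_threshold
    low = df["raw_intensity"] < lower_threshold
    df["qc_flag"] = FLAG_CLEAN
    df.loc[high, "qc_flag"] = FLAG_HIGH
    df.loc[low, "qc_flag"] = FLAG_LOW
    df["final_intensity"] = df["raw_intensity"]
    df.loc[high | low, "final_intensity"] = float(background)
    return df


def impute_fallen(
    measurements: pd.DataFrame,
    panel: PanelDefinition | None = None,
    fallen_set: Iterable[tuple[int, int, int]] | None = None,
    background: float = 0.0,
) -> tuple[pd.DataFrame, float]:
    """Repair fallen posts from their same-probe well neighbours.

    Each fallen post's final intensity becomes the mean of the same
    ``post_index`` (same capture probe) posts in the 8-connected
    neighbouring wells, excluding neighbours that are themselves fallen;
    edge and corner wells use their truncated neighbourhoods.  A fallen
    post with no valid neighbour is left at ``background`` with the
    ``isolated`` flag and a warning.  ``fallen_set`` defaults to the posts
    QC flagged ``artifact_low``.  Returns ``(measurements, retention)``
    where retention is the fraction of posts not fallen.
    """
    df = measurements.copy()
    if fallen_set is None:
        mask = df["qc_flag"] == FLAG_LOW
        fallen = {
            (int(r), int(c), int(p))
            for r, c, p in df.loc[mask, ["well_row", "well_col", "post_index"]].itertuples(
                index=False
            )
        }
    else:
        fallen = {(int(r), int(c), int(p)) for r, c, p in fallen_set}

    n_posts = len(df)
    retention = 1.0 - len(fallen) / n_posts if n_posts else 1.0
    if not fallen:
        return df, retention

    # final intensities before repair, keyed by (row, col, post)
    finals = {
        (int(r), int(c), int(p)): v
        for r, c, p, v in df[
            ["well_row", "well_col", "post_index", "final_intensity"]
        ].itertuples(index=False)
    }
    updates = {}
    for r, c, p in fallen:
        vals = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                key = (r + dr, c + dc, p)
                if key in finals and key not in fallen:
                    vals.append(finals[key])
        if vals:
            updates[(r, c, p)] = (float(np.mean(vals)), FLAG_IMPUTED)
        else:
            warnings.warn(
                f"fallen post {(r, c, p)} has no valid neighbours; "
                "left at background",
                stacklevel=2,
            )
            updates[(r, c, p)] = (float(background), FLAG_ISOLATED)

    idx = pd.MultiIndex.from_frame(df[["well_row", "well_col", "post_index"]])
    for key, (value, flag) in updates.items():
        sel = idx.get_loc(key)
        df.iloc[sel, df.columns.get_loc("final_intensity")] = value
        df.iloc[sel, df.columns.get_loc("qc_flag")] = flag
    return df, retention


def subtract_negative(
    measurements: pd.DataFrame,
    panel: PanelDefinition,
    tissue_fraction: np.ndarray | Mapping[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Per-well net signals: target minus negative control, clipped at zero.

    Returns one row per well with a net-signal column per endogenous target,
    the internal-control signal (if the panel has one), the tissue fraction
    (NaN when not supplied) and a ``masked_in`` column (initially True).
    Wells missing their negative-control measurement are excluded and
    recorded in ``result.attrs["errors"]``.
    """
    neg_name = panel.negative_control.target_name
    endo = panel.endogenous_targets
    internal = panel.internal_control

    wide = measurements.pivot_table(
        index=["well_row", "well_col"],
        columns="target",
        values="final_intensity",
        aggfunc="first",
    )
    errors = []
    if neg_name not in wide.columns:
        wide[neg_name] = np.nan
    missing = wide[neg_name].isna()
    for r, c in wide.index[missing]:
        errors.append(
            {"well_row": int(r), "well_col": int(c), "error": "missing negative control"}
        )
    wide = wide[~missing]

    out = pd.DataFrame(index=wide.index)
    for t in endo:
        out[t] = np.maximum(wide[t] - wide[neg_name], 0.0)
    out[neg_name] = 0.0  # the control's own net signal, by construction
    if internal is not None:
        out["internal_control"] = wide[internal.target_name]
    out = out.reset_index()

    if tissue_fraction is None:
        out["tissue_fraction"] = np.nan
    elif isinstance(tissue_fraction, np.ndarray):
        out["tissue_fraction"] = [
            float(tissue_fraction[r, c]) for r, c in zip(out["well_row"], out["well_col"])
        ]
    else:
        out["tissue_fraction"] = [
            float(tissue_fraction[(r, c)]) for r, c in zip(out["well_row"], out["well_col"])
        ]
    out["masked_in"] = True
    out.attrs["errors"] = errors
    out.attrs["targets"] = endo
    return out


def build_heatmap(
    records: pd.DataFrame,
    geometry: ArrayGeometry,
    target: str,
) -> np.ndarray:
    """One 16-bit pixel per well holding the rounded net signal.

    Wells masked out (or absent from ``records``) are set to 0; values are
    clipped to the 16-bit range.
    """
    if target not in records.columns:
        raise KeyError(f"no net-signal column for target {target!r}")
    heat = np.zeros((geometry.n_rows, geometry.n_cols), dtype=np.uint16)
    sel = records if "masked_in" not in records else records[records["masked_in"]]
    vals = np.clip(np.rint(sel[target].to_numpy(dtype=float)), 0, SATURATION)
    heat[sel["well_row"].to_numpy(int), sel["well_col"].to_numpy(int)] = vals.astype(
        np.uint16
    )
    return heat
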