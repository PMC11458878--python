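"""Tissue masking and section-level summary statistics.

A digital mask restricts statistics to wells genuinely under the tissue
section: a well is kept when the fraction of its footprint covered by
tissue is strictly greater than the threshold (default 0.5).  Summaries
over masked-in wells are reported as mean +/- sample SD with the percent
coefficient of variation, and sections are compared with a two-tailed
unpaired t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "apply_mask",
    "binarize_brightfield",
    "SectionSummary",
    "section_summary",
    "compare_sections",
    "relative_amounts",
    "per_mass_amount",
    "significance_label",
]

DEFAULT_MASK_THRESHOLD = 0.5


def apply_mask(records: pd.DataFrame, threshold: float = DEFAULT_MASK_THRESHOLD) -> pd.DataFrame:
    """Set ``masked_in`` = (tissue_fraction > threshold), strict inequality.

    A well exactly at the threshold is excluded; raising the threshold can
    only remove wells.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if "tissue_fraction" not in records.columns:
        raise KeyError("records lack a tissue_fraction column")
    df = records.copy()
    df["masked_in"] = df["tissue_fraction"].to_numpy(dtype=float) > threshold
    return df


def binarize_brightfield(
    image: np.ndarray,
    geometry,
    grid_anchor: tuple[float, float],
    intensity_threshold: float,
    tissue_is_dark: bool = True,
) -> np.ndarray:
    """Per-well tissue fraction from a brightfield image.

    Pixels are classified as tissue by a plain intensity threshold (tissue
    is darker than the open well under brightfield illumination by default);
    each well's fraction is the classified share of its footprint.  The
    threshold is a declared parameter of this package, not a calibrated
    constant.
    """
    from .geometry import well_rect

    frac = np.zeros((geometry.n_rows, geometry.n_cols))
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            x0, y0, x1, y1 = well_rect(geometry, r, c, grid_anchor)
            block = image[y0:y1, x0:x1]
            if block.size == 0:
                continue
            hits = block < intensity_threshold if tissue_is_dark else block > intensity_threshold
            frac[r, c] = float(np.mean(hits))
    return frac


@dataclass(frozen=True)
class SectionSummary:
    target: str
    mean: float
    sd: float
    cv_percent: float | None
    n_wells: int
    values: tuple[float, ...] = ()


def section_summary(records: pd.DataFrame, target: str) -> SectionSummary:
    """Mean, sample SD (n-1) and CV% of a target over masked-in wells."""
    if target not in records.columns:
        raise KeyError(f"no column for target {target!r}")
    sel = records[records["masked_in"]] if "masked_in" in records else records
    values = sel[target].to_numpy(dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ValueError(
            f"insufficient data: {len(values)} masked-in wells for {target!r} (need >= 2)"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else None
    return SectionSummary(target, mean, sd, cv, len(values), tuple(values))


def significance_label(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "NS"


def compare_sections(
    summary_a: SectionSummary,
    summary_b: SectionSummary,
    equal_var: bool = False,
) -> tuple[float, float, str]:
    """Two-tailed unpaired t-test between two section summaries.

    Welch's test by default (``equal_var=False``); pass ``equal_var=True``
    for the pooled-variance variant.  Two zero-variance groups with equal
    means give p = 1 by convention.
    """
    a = np.asarray(summary_a.values, dtype=float)
    b = np.asarray(summary_b.values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, "NS"
        return np.inf if np.mean(a) > np.mean(b) else -np.inf, 0.0, "***"
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), significance_label(float(p))


def relative_amounts(amounts: dict[str, float], reference_target: str) -> dict[str, float]:
    """Amounts normalized to a reference target; the reference maps to 1.

    Scale-invariant: multiplying every amount by c > 0 leaves ratios fixed.
    """
    if reference_target not in amounts:
        raise KeyError(f"reference target {reference_target!r} not in amounts")
    ref = amounts[reference_target]
    if ref <= 0:
        raise ValueError(f"reference amount must be > 0, got {ref}")
    return {t: v / ref for t, v in amounts.items()}


def per_mass_amount(total_amount_amol: float, tissue_mass_mg: float) -> float:
    """Amount per unit tissue mass, amol/mg."""
    if tissue_mass_mg <= 0:
        raise ValueError(f"tissue mass must be > 0, got {tissue_mass_mg}")
    return total_amount_amol / tissue_mass_mg


def agreement_percent(a: float, b: float) -> float:
    """min/max agreement between two estimates, as a percent."""
    if a <= 0 or b <= 0:
        raise ValueError("estimates must be positive")
    return 100.0 * min(a, b) / max(a, b)
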