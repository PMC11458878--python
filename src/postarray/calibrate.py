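"""Spike-in calibration curves, 3-sigma-blank detection limits, and
crosstalk matrices for multiplexed panels.

A calibration series spikes known synthetic miRNA amounts (amol) into the
wells and records the control(0 amol)-subtracted net signal (AFU).  The
default functional form is a power law fitted on log-log axes,

    log(signal) = a + b * log(amount),

which spans the decades of a spike-in series and inverts in closed form; a
plain linear form is available.  The limit of detection is the amount whose
fitted net signal equals three times the standard deviation of the 0-amol
blank replicates — the blank mean does not enter, because signals are
already control-subtracted.

Specificity of a multiplexed panel is summarised by the crosstalk matrix:
spiking one target at a time, row i holds each probe's signal as a percent
of the matched probe's signal, so the diagonal is 100% by construction and
off-diagonal entries measure cross-hybridisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "ExtrapolationWarning",
    "fit_calibration",
    "compute_lod",
    "signal_to_amount",
    "CrosstalkMatrix",
    "crosstalk",
]


class CalibrationError(ValueError):
    """Calibration input or fit does not meet quality requirements."""


class ExtrapolationWarning(UserWarning):
    """A value was obtained outside the calibrated range."""


@dataclass
class CalibrationCurve:
    """A fitted spike-in calibration with its blank statistics.

    ``fit_params`` is ``(a, b)``: for the power form,
    ``signal = exp(a) * amount**b``; for the linear form,
    ``signal = a + b * amount``.
    """

    points: pd.DataFrame
    fit_kind: str
    fit_params: tuple[float, float]
    blank_sd: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    lod_amol: float | None = None

    @property
    def signal_range(self) -> tuple[float, float]:
        nb = self.points[self.points["amount_amol"] > 0]["net_signal"]
        return float(nb.min()), float(nb.max())

    def predict(self, amount: float | np.ndarray) -> float | np.ndarray:
        a, b = self.fit_params
        arr = np.atleast_1d(np.asarray(amount, dtype=float))
        if self.fit_kind == "power":
            out = np.zeros_like(arr)
            pos = arr > 0
            out[pos] = np.exp(a) * arr[pos] ** b
        else:
            out = a + b * arr
        return float(out[0]) if np.isscalar(amount) or np.ndim(amount) == 0 else out

    def invert(self, signal: float) -> float:
        a, b = self.fit_params
        if b <= 0:
            raise CalibrationError(f"fit is non-invertible (slope b = {b} <= 0)")
        if signal <= 0:
            return 0.0
        if self.fit_kind == "power":
            return float(np.exp((np.log(signal) - a) / b))
        return float((signal - a) / b)

    def summary(self) -> str:
        a, b = self.fit_params
        lines = [
            f"Calibration curve ({self.fit_kind})",
            "-" * 34,
            f"points (non-blank): {int((self.points['amount_amol'] > 0).sum())}",
            f"blank replicates:   {int((self.points['amount_amol'] == 0).sum())}",
            f"a (intercept):      {a:.4f}",
            f"b (slope):          {b:.4f}",
            f"blank SD (AFU):     {self.blank_sd:.3f}",
            f"residual RMS:       {np.sqrt(np.mean(self.residuals**2)) if self.residuals.size else float('nan'):.4f}",
        ]
        if self.lod_amol is not None:
            lines.append(f"LOD (amol):         {self.lod_amol:.4g}")
        return "\n".join(lines)


def _as_points(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        df = pd.DataFrame(points, columns=["amount_amol", "net_signal"])
    if not {"amount_amol", "net_signal"} <= set(df.columns):
        raise CalibrationError("points need amount_amol and net_signal columns")
    if (df["amount_amol"] < 0).any():
        raise CalibrationError("amounts must be >= 0")
    return df


def fit_calibration(points, fit_kind: str = "power") -> CalibrationCurve:
    """Least-squares calibration fit with blank statistics.

    ``points`` is a DataFrame (or iterable of pairs) of ``amount_amol`` and
    ``net_signal``, replicates as repeated rows; the 0-amol blank must be
    present and at least three distinct non-blank amounts spanning at least
    one decade are required.  Raises :class:`CalibrationError` on degenerate
    input or a non-increasing fit.
    """
    if fit_kind not in ("power", "linear"):
        raise CalibrationError(f"unknown fit kind {fit_kind!r}")
    df = _as_points(points)
    blanks = df.loc[df["amount_amol"] == 0, "net_signal"].to_numpy(dtype=float)
    if blanks.size == 0:
        raise CalibrationError("calibration requires a 0-amol blank")
    blank_sd = float(np.std(blanks, ddof=1)) if blanks.size > 1 else 0.0

    nb = df[df["amount_amol"] > 0]
    amounts = nb["amount_amol"].to_numpy(dtype=float)
    signals = nb["net_signal"].to_numpy(dtype=float)
    distinct = np.unique(amounts)
    if distinct.size < 3:
        raise CalibrationError(
            f"need >= 3 distinct non-blank amounts, got {distinct.size}"
        )
    if distinct.max() / distinct.min() < 10:
        raise CalibrationError("non-blank amounts must span at least one decade")
    if np.allclose(signals, signals[0]):
        raise CalibrationError("all net signals equal; nothing to fit")

    if fit_kind == "power":
        if (signals <= 0).any():
            raise CalibrationError("power-law fit requires positive net signals")
        x, y = np.log(amounts), np.log(signals)
    else:
        x, y = amounts, signals
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    if b <= 0:
        raise CalibrationError(
            f"fitted signal is non-increasing in amount (b = {b:.4g}); "
            "check the spike-in series"
        )
    return CalibrationCurve(
        points=df, fit_kind=fit_kind, fit_params=(float(a), float(b)),
        blank_sd=blank_sd, residuals=resid,
    )


def compute_lod(curve: CalibrationCurve) -> float:
    """Limit of detection: the amount whose fitted signal is 3 x blank SD.

    Returns 0 when the blank SD is 0; warns (but still returns a value) when
    3 x blank SD falls outside the fitted signal range.
    """
    if curve.blank_sd < 0:
        raise CalibrationError("blank_sd must be >= 0")
    if curve.blank_sd == 0:
        curve.lod_amol = 0.0
        return 0.0
    crit = 3.0 * curve.blank_sd
    lo, hi = curve.signal_range
    if not lo <= crit <= hi:
        warnings.warn(
            f"3 x blank SD ({crit:.3g} AFU) lies outside the fitted signal range "
            f"[{lo:.3g}, {hi:.3g}]; LOD is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    lod = curve.invert(crit)
    curve.lod_amol = lod
    return lod


def signal_to_amount(curve: CalibrationCurve, net_signal: float) -> float:
    """Invert the fitted curve: net signal (AFU) to amount (amol).

    Zero maps to zero; values outside the calibrated signal range are
    returned with an :class:`ExtrapolationWarning`.
    """
    if net_signal < 0:
        raise ValueError(f"net_signal must be >= 0, got {net_signal}")
    if net_signal == 0:
        return 0.0
    lo, hi = curve.signal_range
    if not lo <= net_signal <= hi:
        warnings.warn(
            f"net signal {net_signal:.3g} outside calibrated range [{lo:.3g}, {hi:.3g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return curve.invert(net_signal)


@dataclass
class CrosstalkMatrix:
    """Percent crosstalk: rows = spiked target, columns = measured probe."""

    targets: tuple[str, ...]
    matrix: pd.DataFrame  # percent

    @property
    def offdiagonal(self) -> np.ndarray:
        m = self.matrix.to_numpy(dtype=float)
        return m[~np.eye(len(self.targets), dtype=bool)]

    @property
    def mean_offdiag(self) -> float:
        return float(np.mean(self.offdiagonal))

    @property
    def max_offdiag(self) -> float:
        return float(np.max(self.offdiagonal))


def crosstalk(
    single_spike_runs: Mapping[str, Mapping[str, float]],
    targets: Sequence[str] | None = None,
) -> tuple[CrosstalkMatrix, tuple[float, float]]:
    """Crosstalk matrix from one single-target spike-in run per target.

    ``single_spike_runs[t]`` maps each probe to its control-subtracted net
    signal in the run where only target ``t`` was spiked.  Row ``t`` is each
    probe's signal as a percent of probe ``t``'s own (matched) signal, so
    rows are invariant to the spiked amount.  Returns the matrix plus
    ``(mean, max)`` of the off-diagonal entries.
    """
    if targets is None:
        targets = list(single_spike_runs)
    rows = []
    for t in targets:
        if t not in single_spike_runs:
            raise KeyError(f"no spike-in run for target {t!r}")
        run = single_spike_runs[t]
        matched = run[t]
        if matched <= 0:
            raise CalibrationError(
                f"matched signal for spiked target {t!r} is {matched} <= 0; "
                "cannot normalize its row"
            )
        rows.append([100.0 * max(run[u], 0.0) / matched for u in targets])
    mat = pd.DataFrame(rows, index=list(targets), columns=list(targets))
    cm = CrosstalkMatrix(tuple(targets), mat)
    return cm, (cm.mean_offdiag, cm.max_offdiag)
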