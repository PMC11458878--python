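"""Relative quantification of RT-PCR threshold cycles by 2^-ddCt.

The comparison arm of the assay: Ct values from TaqMan RT-PCR are
normalized to an endogenous control (snoR85 for *Arabidopsis*) within each
sample, differenced against a reference sample, and exponentiated:

    dCt  = mean Ct(target) - mean Ct(endogenous control)   per sample
    ddCt = dCt(sample) - dCt(reference sample)
    fold = 2 ** -ddCt

Replicate Cts are averaged on the Ct scale before differencing (the
conventional reading of the method); per-replicate propagation is available
for uncertainty estimates.  Fold changes can then be renormalized to an
anchor target (miR-159a in the reference workflow) so that low-abundance
targets plot on a comparable scale.  No amplification-efficiency (Pfaffl)
correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "renormalize_to_target", "validate_ct_table"]

CT_COLUMNS = ["sample", "target", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame, endo_control: str) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("Ct values must be positive and finite")
    for sample, grp in table.groupby("sample"):
        if endo_control not in set(grp["target"]):
            raise ValueError(
                f"sample {sample!r} has no Ct for endogenous control {endo_control!r}"
            )
    return table


def ddct_fold_change(
    table: pd.DataFrame,
    endo_control: str,
    reference_sample: str,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """2^-ddCt fold changes per (sample, target).

    Returns a DataFrame with columns sample, target, dct, ddct, fold (and
    fold_sd when ``per_replicate`` is set, from replicate-wise dCt spread
    propagated through the exponent).  The reference sample's fold is 1 for
    every target by construction.
    """
    validate_ct_table(table, endo_control)
    mean_ct = (
        table.groupby(["sample", "target"])["ct"].mean().unstack("target")
    )
    if reference_sample not in mean_ct.index:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    targets = [t for t in mean_ct.columns if t != endo_control]
    for t in targets:
        if pd.isna(mean_ct.loc[reference_sample, t]):
            raise ValueError(
                f"reference sample {reference_sample!r} has no Ct for target {t!r}"
            )

    dct = mean_ct[targets].sub(mean_ct[endo_control], axis=0)
    ddct = dct.sub(dct.loc[reference_sample], axis=1)
    fold = np.power(2.0, -ddct)

    out = (
        ddct.stack()
        .rename("ddct")
        .to_frame()
        .join(dct.stack().rename("dct"))
        .join(fold.stack().rename("fold"))
        .reset_index()
        .rename(columns={"level_0": "sample"})
    )
    out = out[["sample", "target", "dct", "ddct", "fold"]]

    if per_replicate:
        sds = []
        for _, row in out.iterrows():
            reps = table[
                (table["sample"] == row["sample"]) & (table["target"] == row["target"])
            ]["ct"].to_numpy(dtype=float)
            ctrl = table[
                (table["sample"] == row["sample"]) & (table["target"] == endo_control)
            ]["ct"].to_numpy(dtype=float)
            # replicate-wise dCt spread, propagated through 2^-x
            sd_dct = np.sqrt(
                (np.var(reps, ddof=1) if reps.size > 1 else 0.0)
                + (np.var(ctrl, ddof=1) if ctrl.size > 1 else 0.0)
            )
            sds.append(row["fold"] * np.log(2.0) * sd_dct)
        out["fold_sd"] = sds
    return out


def renormalize_to_target(
    folds: pd.DataFrame | dict[str, float],
    anchor_target: str,
) -> pd.DataFrame | dict[str, float]:
    """Fold changes renormalized to an anchor target (anchor maps to 1).

    Accepts either a mapping target -> fold (one sample) or the DataFrame
    produced by :func:`ddct_fold_change`, which is renormalized within each
    sample.  Invariant to rescaling all folds by a common positive factor.
    """
    if isinstance(folds, dict):
        if anchor_target not in folds:
            raise KeyError(f"anchor target {anchor_target!r} not present")
        anchor = folds[anchor_target]
        if anchor <= 0:
            raise ValueError(f"anchor fold must be > 0, got {anchor}")
        return {t: v / anchor for t, v in folds.items()}

    out = folds.reset_index(drop=True).copy()
    ratios = np.empty(len(out))
    for sample, grp in out.groupby("sample"):
        sel = grp[grp["target"] == anchor_target]
        if sel.empty:
            raise KeyError(f"anchor target {anchor_target!r} missing in sample {sample!r}")
        anchor = float(sel["fold"].iloc[0])
        if anchor <= 0:
            raise ValueError(f"anchor fold must be > 0 in sample {sample!r}, got {anchor}")
        ratios[grp.index] = grp["fold"] / anchor
    out["ratio"] = ratios
    return out
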