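"""Relative transcript quantification from qPCR cycle thresholds.

Implements the comparative-Ct (2^-ddCt) method: technical replicates are
averaged on the Ct scale, each sample's target Ct is referenced to a
housekeeping gene (dCt), dCt is referenced to a calibrator sample (ddCt), and
relative expression is ``2 ** -ddCt``.  An optional post-hoc rescaling
divides all relative expressions of a target by the mean over a chosen group
(e.g. "the average of all knockdown time points"), putting control and
knockdown series on one shared scale.

Standard-curve amplification efficiency is a QC report, not a correction:
``E = 10 ** (-1 / slope) - 1`` from the least-squares line of Ct against
log10 input amount, with a pass flag for E in [0.9, 1.1].

Ct tables are tidy DataFrames with columns
``sample, timepoint, target, replicate, ct``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "standard_curve_efficiency"]

CT_COLUMNS = ["sample", "timepoint", "target", "replicate", "ct"]


def _mean_cts(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample", "target", "ct") if c not in ct_table]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if ct_table["ct"].isna().any() or not np.isfinite(ct_table["ct"]).all():
        raise ValueError("non-finite Ct values")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    g = ct_table.groupby(["sample", "target"], sort=False)["ct"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    if (out["count"] < 1).any():
        raise ValueError("sample/target combination with zero replicates")
    return out


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_target: str = "RpL32",
    calibrator: str | list[str] | None = None,
    rescale: list[str] | None = None,
    dispersion_limit: float = 0.5,
) -> pd.DataFrame:
    """Relative expression of every sample × target by 2^-ddCt.

    ``calibrator`` names the calibrator sample(s); their mean dCt per target
    is the ddCt reference, so the calibrator's relative expression is exactly
    1 before rescaling.  ``rescale`` optionally names a sample group whose
    mean relative expression becomes the unit of the reported values.
    Replicate dispersion (SD of the Ct triplicates) is reported and flagged
    when above ``dispersion_limit`` cycles.
    """
    means = _mean_cts(ct_table)
    ref = means[means["target"] == reference_target].set_index("sample")
    targets = means[means["target"] != reference_target]
    if targets.empty:
        raise ValueError("no non-reference targets in Ct table")

    rows = []
    for rec in targets.itertuples(index=False):
        if rec.sample not in ref.index:
            raise ValueError(
                f"sample {rec.sample!r} has no {reference_target} reference Cts"
            )
        rows.append(
            dict(
                sample=rec.sample,
                target=rec.target,
                timepoint=(
                    ct_table.loc[
                        (ct_table["sample"] == rec.sample)
                        & (ct_table["target"] == rec.target),
                        "timepoint",
                    ].iloc[0]
                    if "timepoint" in ct_table
                    else None
                ),
                delta_ct=rec.mean - ref.loc[rec.sample, "mean"],
                ct_sd=rec.std,
                ref_ct_sd=ref.loc[rec.sample, "std"],
            )
        )
    out = pd.DataFrame(rows)

    if calibrator is None:
        raise ValueError("a calibrator sample must be named")
    cal = [calibrator] if isinstance(calibrator, str) else list(calibrator)
    for target, grp in out.groupby("target", sort=False):
        base = grp.loc[grp["sample"].isin(cal), "delta_ct"]
        if base.empty:
            raise ValueError(f"calibrator {cal} has no Cts for target {target!r}")
        out.loc[grp.index, "delta_delta_ct"] = grp["delta_ct"] - base.mean()
    out["rel_expr"] = 2.0 ** (-out["delta_delta_ct"])

    out["rescaled_by"] = ""
    if rescale is not None:
        for target, grp in out.groupby("target", sort=False):
            group = grp.loc[grp["sample"].isin(rescale), "rel_expr"]
            if group.empty:
                raise ValueError(f"rescale group has no samples for target {target!r}")
            out.loc[grp.index, "rel_expr"] = grp["rel_expr"] / group.mean()
        out["rescaled_by"] = f"mean of {sorted(rescale)}"
    out["high_dispersion"] = (out["ct_sd"] > dispersion_limit) | (
        out["ref_ct_sd"] > dispersion_limit
    )
    if (out["rel_expr"] <= 0).any():
        raise AssertionError("relative expression must be positive")
    return out


def standard_curve_efficiency(
    dilution_series: list[tuple[float, float]]
) -> dict:
    """Amplification efficiency from a primer-pair dilution series.

    ``dilution_series`` holds ``(log10 input amount, mean Ct)`` pairs; at
    least 3 points spanning at least 2 log10 are required.  Returns the
    least-squares ``slope``, ``efficiency`` (1.0 = perfect doubling), ``r2``
    and a QC ``passes`` flag for efficiency within [0.9, 1.1].
    """
    pts = np.asarray(dilution_series, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("dilution series must be (log10 amount, Ct) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("dilution series needs at least two distinct amounts")
    if pts.shape[0] < 3 or x.max() - x.min() < 2.0:
        raise ValueError("need >= 3 dilution points spanning >= 2 log10")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0)
    return dict(
        slope=slope,
        efficiency=efficiency,
        r2=float(fit.rvalue**2),
        passes=bool(0.9 <= efficiency <= 1.1),
    )
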