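"""Model evaluation on the acquisition frames and cohort-level statistics.

Goodness of fit is judged on the original frames rather than the 1-s fitting
grid: the fitted curve is frame-averaged back onto the schedule (the
measured value is itself a frame mean) and compared with the measured frame
activities by

    MRE = (1/n) sum |C_meas(t_i) - C_fit(t_i)| / C_meas(t_i)
    MSE = (1/n) sum (C_meas(t_i) - C_fit(t_i))^2      [curves in kBq/mL]
    AIC = n log(MSE) + 2 N

with n the number of frames (24 on the study schedule), N the model's total
parameter count (4 for the 1TCM, 7 for the spleen-delay dual-input model, 6
for the fitted-delay and measured-PV variants) and a natural logarithm.

Cohort comparisons use one-sided Wilcoxon signed-rank tests on paired error
terms, the Mann-Whitney U test for group differences and Pearson correlation
with the t-based significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .curves import FrameTAC, SampledCurve, frame_average

__all__ = [
    "BQ_PER_KBQ",
    "UndefinedCorrelationError",
    "FitMetrics",
    "compute_metrics",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "pearson_with_t_test",
    "cohort_summary",
]

BQ_PER_KBQ = 1000.0

#: Frames with |measured| below this (Bq/mL) are excluded from the MRE sum.
MRE_ZERO_EPS = 1e-6

#: Model id -> total parameter count N entering the AIC.
N_PARAMS = {"1tcm": 4, "taniguchi": 7, "rijzewijk": 6, "new_dual_input": 6}


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a zero-variance variable."""


@dataclass(frozen=True)
class FitMetrics:
    """Frame-level error summary of one fitted model."""

    mre: float
    mse: float
    aic: float
    n_params: int
    n_frames: int


def compute_metrics(
    fitted: SampledCurve,
    measured: FrameTAC,
    n_params: int,
    mse_floor: float = 1e-12,
    sample_at_midpoint: bool = False,
    zero_eps: float = MRE_ZERO_EPS,
) -> FitMetrics:
    """MRE, MSE (kBq/mL units) and AIC of a fitted curve on the measured frames.

    By default the fitted 1-s curve is frame-averaged onto the schedule;
    ``sample_at_midpoint`` instead samples it at the frame midpoints.
    Frames whose measured activity is below ``zero_eps`` in magnitude are
    dropped from the MRE sum (with the divisor reduced accordingly) and a
    warning is emitted.  ``mse_floor`` keeps the AIC finite for a perfect
    fit.
    """
    if sample_at_midpoint:
        fitted_frames = np.interp(
            measured.schedule.midpoints,
            np.concatenate([[0.0], fitted.t]),
            np.concatenate([[0.0], fitted.values]),
        )
    else:
        fitted_frames = frame_average(fitted, measured.schedule).values
    resid = measured.values - fitted_frames
    n_frames = measured.schedule.n_frames

    ok = np.abs(measured.values) >= zero_eps
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} frame(s) with near-zero measured activity "
            "excluded from the MRE",
            stacklevel=2,
        )
    if np.any(ok):
        mre = float(np.mean(np.abs(resid[ok]) / measured.values[ok]))
    else:
        mre = float("nan")

    resid_kbq = resid / BQ_PER_KBQ
    mse = float(np.mean(resid_kbq**2))
    aic = n_frames * float(np.log(max(mse, mse_floor))) + 2 * n_params
    return FitMetrics(mre=mre, mse=mse, aic=aic, n_params=n_params, n_frames=n_frames)


def wilcoxon_signed_rank(
    a, b, alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for paired samples.

    The default alternative 'greater' tests that the values in ``a`` exceed
    those in ``b``.  Zero differences are dropped; tied magnitudes are
    mid-ranked; the exact null distribution is used for small samples and
    the normal approximation with continuity correction beyond n = 25.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative=alternative,
        method=method,
    )
    return float(res.pvalue)


def mann_whitney_u(a, b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value for two independent samples (two-sided by
    default; tie-corrected normal approximation for larger samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.pvalue)


def pearson_with_t_test(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided t-based p-value.

    p is computed from t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def cohort_summary(table: pd.DataFrame) -> dict:
    """Summarise a cohort table with one row per subject-model pair.

    Expects at least ``subject`` and ``model`` columns plus numeric
    parameter/metric columns.  Returns per-model means +/- sample SDs
    (n - 1 denominator) of every numeric column, per-model medians of the
    error metrics (``mre``, ``mse``, ``aic``, where present) and, for each
    error metric, a model-by-model matrix of one-sided Wilcoxon signed-rank
    p-values (row model's errors greater than column model's, paired by
    subject).
    """
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    for col in ("subject", "model"):
        if col not in table.columns:
            raise ValueError(f"cohort table needs a '{col}' column")
    numeric = table.select_dtypes(include=[np.number]).columns
    grouped = table.groupby("model")[list(numeric)]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)

    error_cols = [c for c in ("mre", "mse", "aic") if c in table.columns]
    medians = grouped.median()[error_cols] if error_cols else pd.DataFrame()

    models = list(table["model"].unique())
    comparisons: dict[str, pd.DataFrame] = {}
    for col in error_cols:
        wide = table.pivot(index="subject", columns="model", values=col)
        mat = pd.DataFrame(index=models, columns=models, dtype=float)
        for m_row in models:
            for m_col in models:
                if m_row == m_col:
                    continue
                pair = wide[[m_row, m_col]].dropna()
                if len(pair) < 5:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mat.loc[m_row, m_col] = wilcoxon_signed_rank(
                        pair[m_row].to_numpy(),
                        pair[m_col].to_numpy(),
                        alternative="greater",
                    )
        comparisons[col] = mat
    return {"means": means, "sds": sds, "error_medians": medians, "comparisons": comparisons}
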