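"""Image-quality evaluation of translated slices.

Per-slice MSE, PSNR and SSIM are computed between translated and real ADC
slices after linear rescaling to the 8-bit [0, 255] range (whole slice,
including the zero background).  Per-method summaries report the mean with a
seeded percentile-bootstrap 95% confidence interval over slices; method
comparisons use the two-sided Wilcoxon signed-rank test paired by slice
(exact null for small n after zero-difference removal, normal approximation
with tie correction otherwise).  SSIM uses the standard reference
parameterisation (Gaussian window sigma=1.5, 11x11, K1=0.01, K2=0.03).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "MetricRecord",
    "MetricSummary",
    "mse",
    "psnr",
    "ssim",
    "ssim_difference_map",
    "bootstrap_ci",
    "wilcoxon_paired",
    "evaluate_run",
    "summarize_records",
    "compare_methods",
    "PSNR_CAP_DB",
]

#: sentinel PSNR for identical images (mse == 0); excluded from means.
PSNR_CAP_DB = 100.0

#: exact Wilcoxon null enumeration is used up to this many nonzero pairs.
WILCOXON_EXACT_MAX_N = 25

_SSIM_KW = dict(gaussian_weights=True, sigma=1.5, win_size=11,
                use_sample_covariance=False, K1=0.01, K2=0.03)


@dataclass
class MetricRecord:
    patient_id: str
    slice_index: int
    mse: float
    psnr: float
    ssim: float  # percent


@dataclass
class MetricSummary:
    metric: str
    mean: float
    ci_low: float
    ci_high: float
    n_slices: int


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared pixel difference."""
    a, b = _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, max_value: float = 255.0) -> float:
    """10*log10(max_value^2 / MSE); identical inputs return the capped
    sentinel ``PSNR_CAP_DB`` (flagged, excluded from summary means)."""
    err = mse(a, b)
    if err == 0.0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(max_value ** 2 / err))


def ssim(a, b, data_range: float = 255.0) -> float:
    """Single-scale structural similarity in [-1, 1] (multiply by 100 for
    the percent convention used in reporting)."""
    a, b = _check_pair(a, b)
    if min(a.shape) < _SSIM_KW["win_size"]:
        raise ValueError(
            f"image smaller than the {_SSIM_KW['win_size']}px SSIM window"
        )
    return float(structural_similarity(a, b, data_range=data_range, **_SSIM_KW))


def ssim_difference_map(a, b, data_range: float = 255.0) -> np.ndarray:
    """Per-pixel 1 - local SSIM, clipped to [0, 1]: 0 = no structural
    difference, 1 = complete difference."""
    a, b = _check_pair(a, b)
    _, smap = structural_similarity(a, b, data_range=data_range, full=True,
                                    **_SSIM_KW)
    return np.clip(1.0 - smap, 0.0, 1.0)


def bootstrap_ci(values, level: float = 0.95, n_boot: int = 10000,
                 seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean over slices."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def wilcoxon_paired(x, y):
    """Two-sided Wilcoxon signed-rank test on slice-paired metric lists.

    Returns ``(p_value, statistic)``; if every difference is zero the result
    is degenerate and ``(nan, nan)`` is returned (flagged by a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero: degenerate test")
        return float("nan"), float("nan")
    method = "exact" if nz.size <= WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.pvalue), float(res.statistic)


# ---------------------------------------------------------------------------
# run-level evaluation
# ---------------------------------------------------------------------------

def evaluate_run(translate_fn, test_slices, ci_seed: int = 0,
                 n_boot: int = 10000):
    """Translate every test CT slice and score it against the real ADC.

    ``translate_fn(slice) -> [0, 1] array`` is the model under test (e.g. a
    checkpointed generator wrapped by ``training.translate_slices``, or a
    ground-truth passthrough as an oracle).  Returns ``(records, summaries)``
    as DataFrames; metrics are on the [0, 255] scale, SSIM in percent.
    """
    if not test_slices:
        raise ValueError("empty test set")
    records = []
    for s in test_slices:
        pred = np.asarray(translate_fn(s), dtype=float) * 255.0
        real = np.asarray(s.adc, dtype=float) * 255.0
        records.append(MetricRecord(
            patient_id=s.patient_id, slice_index=s.slice_index,
            mse=mse(pred, real), psnr=psnr(pred, real),
            ssim=100.0 * ssim(pred, real),
        ))
    rec_df = pd.DataFrame([r.__dict__ for r in records])
    summaries = summarize_records(rec_df, ci_seed=ci_seed, n_boot=n_boot)
    return rec_df, summaries


def summarize_records(rec_df: pd.DataFrame, ci_seed: int = 0,
                      n_boot: int = 10000) -> pd.DataFrame:
    """Mean and bootstrap 95% CI per metric (capped PSNR sentinels excluded
    from the PSNR aggregate, with a warning)."""
    rows = []
    for metric in ("mse", "psnr", "ssim"):
        vals = rec_df[metric].to_numpy(dtype=float)
        if metric == "psnr":
            capped = vals >= PSNR_CAP_DB
            if capped.any():
                warnings.warn(
                    f"excluding {int(capped.sum())} capped PSNR value(s) "
                    "(identical images) from the mean"
                )
                vals = vals[~capped]
        if vals.size >= 2:
            lo, hi = bootstrap_ci(vals, seed=ci_seed, n_boot=n_boot)
        else:
            lo = hi = float(vals.mean()) if vals.size else float("nan")
        rows.append(MetricSummary(metric, float(vals.mean()) if vals.size
                                  else float("nan"), lo, hi, len(rec_df)))
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_methods(records_by_method: dict[str, pd.DataFrame],
                    reference: str) -> pd.DataFrame:
    """Comparison table mirroring the ablation layout: one block per method
    with mean (95% CI) per metric and Wilcoxon p-values against ``reference``."""
    ref = records_by_method[reference]
    rows = []
    for name, rec in records_by_method.items():
        summ = summarize_records(rec)
        row = {"method": name, "n_slices": len(rec)}
        for _, s in summ.iterrows():
            row[f"{s['metric']}_mean"] = s["mean"]
            row[f"{s['metric']}_ci_low"] = s["ci_low"]
            row[f"{s['metric']}_ci_high"] = s["ci_high"]
        for metric in ("mse", "psnr", "ssim"):
            if name == reference:
                row[f"{metric}_p_vs_{reference}"] = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, _ = wilcoxon_paired(rec[metric].to_numpy(),
                                           ref[metric].to_numpy())
                row[f"{metric}_p_vs_{reference}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
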