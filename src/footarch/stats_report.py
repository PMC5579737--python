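"""Evaluation statistics for repeated arch-parameter measurements.

Accuracy is summarized by the average signed error (AE) against ground truth,
repeatability by the standard deviation (STD) of repeated measurements and a
coefficient of variation (CV), and reliability by Pearson and Spearman
correlation with the ground truth, plus ordinary least-squares regression
between parameters. A quartile rule on the arch-index distribution classifies
feet into high / normal / low arch.

The module ships the published 11-subject evaluation tables of the reference
measurement study as fixtures (`accuracy_table`, `table_ranks`): per-subject ground
truth, average errors and repeat STDs for AI/AW/AH, and the rank tables used
for Spearman correlation. The AW rank table is stored verbatim even though
its printed ranks are internally inconsistent (two distinct values share rank
7.5); `spearman_from_ranks` reproduces the published coefficients from those
printed ranks, while `spearman_rho` ranks raw values itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "accuracy_table",
    "table_ranks",
    "published_weight_sets",
    "average_error",
    "repeatability_std",
    "coefficient_of_variation",
    "pearson_r",
    "spearman_rho",
    "spearman_from_ranks",
    "linear_regression",
    "quartile_classifier",
    "summarize_accuracy_table",
]

# -- published evaluation fixtures (11 subjects) ----------------------------

_T1 = [
    # subject, AI_gt, AI_ae, AI_std, AW_gt, AW_ae, AW_std, AH_gt, AH_ae, AH_std
    (1, 29.06, 1.63, 0.89, 29, 1.86, 1.77, 8, -1.06, 0.51),
    (2, 31.14, -0.40, 0.37, 28, -0.86, 2.49, 8, 0.95, 0.63),
    (3, 25.27, -1.35, 1.12, 30, 0.67, 0.99, 11, 1.93, 0.87),
    (4, 27.90, -0.81, 0.96, 37, 1.71, 1.93, 12, 2.06, 0.56),
    (5, 23.59, -1.29, 0.28, 28, -0.65, 0.57, 9, 0.57, 0.84),
    (6, 26.66, 0.95, 0.36, 40, 1.38, 2.90, 12, 0.49, 0.56),
    (7, 28.26, 0.60, 0.48, 41, 1.12, 1.21, 11, 0.38, 0.45),
    (8, 25.86, -1.34, 0.85, 35, 1.76, 1.97, 14, -1.00, 1.15),
    (9, 26.73, -0.02, 0.79, 38, 2.24, 0.41, 16, 1.29, 1.07),
    (10, 29.30, -0.21, 1.23, 41, -0.80, 1.93, 10, 0.42, 0.43),
    (11, 27.75, 0.33, 0.38, 39, 2.05, 1.74, 11, -0.31, 0.44),
]

_RANKS = {
    # parameter: (subject, gt_value, gt_rank, measured_value, measured_rank)
    "AI": [
        (5, 23.59, 1, 22.30, 1), (3, 25.27, 2, 23.92, 2),
        (8, 25.86, 3, 24.52, 3), (6, 26.66, 4, 27.61, 6),
        (9, 26.73, 5, 26.71, 4), (11, 27.75, 6, 28.08, 7),
        (4, 27.90, 7, 27.09, 5), (7, 28.26, 8, 28.86, 8),
        (1, 29.06, 9, 30.69, 10), (10, 29.30, 10, 29.09, 9),
        (2, 31.14, 11, 30.74, 11),
    ],
    "AW": [
        (2, 28, 1.5, 27.14, 1), (5, 28, 1.5, 27.35, 2),
        (1, 29, 3, 30.86, 4), (3, 30, 4, 30.67, 3),
        (8, 35, 5, 36.76, 5), (4, 37, 6, 38.71, 7.5),
        (9, 38, 7, 40.24, 8), (11, 39, 8, 41.05, 9),
        (6, 40, 9, 41.38, 10), (7, 41, 10.5, 42.12, 11),
        (10, 41, 10.5, 40.20, 7.5),
    ],
    "AH": [
        (1, 8, 1.5, 6.94, 1), (2, 8, 1.5, 8.95, 2),
        (5, 9, 3, 9.57, 3), (10, 10, 4, 10.42, 4),
        (3, 11, 6, 12.93, 8), (7, 11, 6, 11.38, 6),
        (11, 11, 6, 10.69, 5), (4, 12, 8.5, 14.06, 10),
        (6, 12, 8.5, 12.49, 7), (8, 14, 10, 13.00, 9),
        (9, 16, 11, 17.29, 11),
    ],
}

# published optimal MRF weight triples per target parameter
published_weight_sets = {
    "AI": (2.9, 9.3, 1.8),
    "AW": (4.7, 6.7, 0.9),
    "AH": (6.2, 7.3, 1.2),
}


def accuracy_table() -> pd.DataFrame:
    """Per-subject ground truth, average error and repeat STD for AI/AW/AH."""
    return pd.DataFrame(
        _T1,
        columns=["subject", "AI_gt", "AI_ae", "AI_std", "AW_gt", "AW_ae",
                 "AW_std", "AH_gt", "AH_ae", "AH_std"],
    ).set_index("subject")


def table_ranks(parameter: str) -> pd.DataFrame:
    """Published per-subject rank table for 'AI', 'AW' or 'AH'."""
    return pd.DataFrame(
        _RANKS[parameter],
        columns=["subject", "gt", "gt_rank", "measured", "measured_rank"],
    ).set_index("subject")


# -- statistics -------------------------------------------------------------


def average_error(measured, truth) -> float:
    """Mean signed error, mean(measured - truth)."""
    m = np.asarray(measured, dtype=float)
    t = np.asarray(truth, dtype=float)
    if m.size == 0 or m.shape != t.shape:
        raise ValueError("measured and truth must be equal-length, non-empty")
    return float(np.mean(m - t))


def repeatability_std(repeats, ddof: int = 1) -> float:
    """Standard deviation of repeated measurements (sample std by default)."""
    r = np.asarray(repeats, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two repeats")
    return float(np.std(r, ddof=ddof))


def coefficient_of_variation(values, formula: str = "std_over_mean",
                             ddof: int = 1) -> float:
    """Dispersion of repeated measurements relative to their mean.

    ``formula`` selects std/mean (the conventional CV) or its reciprocal
    mean/std; both are exposed because published usage is ambiguous.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(v))
    std = float(np.std(v, ddof=ddof))
    if formula == "std_over_mean":
        if mean == 0:
            raise ZeroDivisionError("zero mean")
        return std / mean
    if formula == "mean_over_std":
        if std == 0:
            return float("inf") if mean else float("nan")
        return mean / std
    raise ValueError(f"unknown CV formula {formula!r}")


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman_from_ranks(rank_x, rank_y) -> float:
    """Classical d-squared Spearman formula on given (possibly tied) ranks:

        rho = 1 - 6 sum(d_i^2) / (n (n^2 - 1)).
    """
    rx = np.asarray(rank_x, dtype=float)
    ry = np.asarray(rank_y, dtype=float)
    n = rx.size
    if n < 3 or ry.size != n:
        raise ValueError("need two equal-length rank vectors, n >= 3")
    d = rx - ry
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: average ranks for ties, d-squared formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input has no rank order")
    return spearman_from_ranks(sps.rankdata(x), sps.rankdata(y))


def linear_regression(x, y):
    """OLS fit y = slope*x + intercept with Pearson r and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0:
        raise ValueError("degenerate x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), \
        float(res.pvalue)


def quartile_classifier(ai_values) -> tuple[tuple[float, float], list[str]]:
    """Classify feet by arch index quartiles.

    Q1 and Q3 (linear interpolation between order statistics) bound the
    normal range; AI < Q1 marks a high arch (little midfoot contact),
    AI > Q3 a low arch.
    """
    v = np.asarray(ai_values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least four values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    labels = ["high" if a < q1 else "low" if a > q3 else "normal" for a in v]
    return (float(q1), float(q3)), labels


def summarize_accuracy_table() -> dict:
    """AVG-row statistics of the embedded evaluation table."""
    t = accuracy_table()
    out = {}
    for p in ("AI", "AW", "AH"):
        gt = t[f"{p}_gt"].to_numpy()
        ae = t[f"{p}_ae"].to_numpy()
        std = t[f"{p}_std"].to_numpy()
        out[p] = {
            "avg_gt": float(gt.mean()),
            "avg_ae": float(ae.mean()),
            "avg_std": float(std.mean()),
            "error_rate_percent": float(abs(ae.mean()) / gt.mean() * 100.0),
        }
    return out
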