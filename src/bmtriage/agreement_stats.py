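"""Agreement statistics: consistency ICC and weighted kappa.

Two raters are compared throughout: the detector and the ground truth
for continuous quantities (lesion counts, total volumes), and ordinal
triage groups for categorical concordance.

``icc_consistency`` is the single-measures two-way mixed consistency
coefficient ICC(3,1),

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E),

with MS_R the between-subject and MS_E the residual mean square from the
two-way ANOVA without interaction; its confidence interval uses the
Shrout-Fleiss F construction.  A consistency ICC ignores a fixed additive
shift between the raters.

``weighted_kappa`` is Cohen's kappa with distance-based disagreement
weights over ordered categories,

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij),

with O the observed contingency table, E the table expected from the
margins, and w_ij = |i-j|/(k-1) (linear, default), ((i-j)/(k-1))^2
(quadratic) or 1[i != j] (unweighted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["IccResult", "KappaResult", "icc_consistency", "weighted_kappa"]


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    model: str = "two_way_mixed_consistency"


@dataclass
class KappaResult:
    kappa: float
    weights: str
    n: int


def icc_consistency(x: Sequence[float], y: Sequence[float], confidence: float = 0.95) -> IccResult:
    """ICC(3,1) between two paired measurement series with a 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = x.size
    k = 2
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    data = np.column_stack([x, y])
    if np.ptp(data) == 0:
        raise ValueError("ICC undefined: all measurements identical (zero total variance)")
    grand = data.mean()
    ss_rows = k * float(((data.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((data.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    if ss_err < 1e-12 * ss_total:  # guard against catastrophic cancellation
        ss_err = 0.0
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_rows == 0 and ms_err == 0:
        raise ValueError("ICC undefined: no between-subject or residual variance")
    if ms_err == 0:
        # perfect consistency (possibly up to a fixed shift)
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n)
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    alpha = 1.0 - confidence
    f_obs = ms_rows / ms_err
    f_low = f_obs / f_dist.ppf(1 - alpha / 2, df_rows, df_err)
    f_high = f_obs * f_dist.ppf(1 - alpha / 2, df_err, df_rows)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    return IccResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high), n_subjects=n)


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    i = np.arange(k)[:, None]
    j = np.arange(k)[None, :]
    if weights == "linear":
        return np.abs(i - j) / (k - 1) if k > 1 else np.zeros((1, 1))
    if weights == "quadratic":
        return ((i - j) / (k - 1)) ** 2 if k > 1 else np.zeros((1, 1))
    if weights == "unweighted":
        return (i != j).astype(float)
    raise ValueError(f"unknown weight scheme {weights!r}")


def weighted_kappa(
    a: Sequence,
    b: Sequence,
    weights: str = "linear",
    categories: Optional[Sequence] = None,
) -> KappaResult:
    """Chance-corrected ordinal agreement between two label sequences."""
    a = list(a)
    b = list(b)
    if not a or len(a) != len(b):
        raise ValueError("a and b must be non-empty sequences of equal length")
    if categories is None:
        categories = sorted(set(a) | set(b))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    bad = [lab for lab in set(a) | set(b) if lab not in index]
    if bad:
        raise ValueError(f"labels outside category set {categories}: {sorted(map(str, bad))}")
    k = len(categories)
    n = len(a)
    obs = np.zeros((k, k))
    for la, lb in zip(a, b):
        obs[index[la], index[lb]] += 1
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    expected = np.outer(row, col) / n
    w = _weight_matrix(k, weights)
    denom = float((w * expected).sum())
    if denom == 0:
        # all mass in a single category: agreement is trivially perfect
        kappa = 1.0
    else:
        kappa = 1.0 - float((w * obs).sum()) / denom
    return KappaResult(kappa=kappa, weights=weights, n=n)
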