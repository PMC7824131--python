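"""Plane-agreement metrics and cohort-level statistics.

Per-pair metrics on normalized coefficient 4-vectors (a, b, c, d):

* included angle  theta = arccos(|v1 . v2|)           (degrees)
* coefficient distance d = ||v1 - v2||_2              (dimensionless)
* yaw   theta_y = arctan(b / a)                       (degrees)
* roll  theta_r = arctan(-c / sqrt(a^2 + b^2))        (degrees)

Both 4-vectors are normalized (unit norm, canonical sign) before any metric
is computed, and the absolute dot product is used, so antipodal coefficient
representations of the same plane give theta = 0 and the algebraic identity
d^2 = 2 (1 - cos theta) holds for every pair.

Cohort agreement between two measurement arms follows the standard method-
comparison toolkit: mean/SD and a t-based 95% CI of the paired differences,
Pearson correlation, a paired t-test, and Bland-Altman bias with 1.96-SD
limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Plane, normalize_plane


def _as_unit4(p) -> np.ndarray:
    if isinstance(p, Plane):
        v = p.vector
    else:
        v = np.asarray(p, dtype=float).reshape(4)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        warnings.warn("plane coefficients were not normalized; normalizing", stacklevel=3)
        v = normalize_plane(v).vector
    return v


def included_angle(p1, p2) -> float:
    """Included angle (degrees) between two planes' coefficient 4-vectors."""
    v1, v2 = _as_unit4(p1), _as_unit4(p2)
    c = np.clip(abs(float(v1 @ v2)), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))


def coeff_distance(p1, p2) -> float:
    """Euclidean distance between the two coefficient 4-vectors."""
    v1, v2 = _as_unit4(p1), _as_unit4(p2)
    return float(np.linalg.norm(v1 - v2))


def yaw(p) -> float:
    """Yaw angle arctan(b/a) in degrees, in (-90, 90]."""
    v = _as_unit4(p)
    ang = np.rad2deg(np.arctan2(v[1], v[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def roll(p) -> float:
    """Roll angle arctan(-c / sqrt(a^2 + b^2)) in degrees."""
    v = _as_unit4(p)
    return float(np.rad2deg(np.arctan2(-v[2], np.hypot(v[0], v[1]))))


@dataclass(frozen=True)
class PlanePairMetrics:
    """The four per-case metrics between a predicted and a reference plane."""

    theta: float
    dist: float
    dyaw: float
    droll: float


def plane_pair_metrics(pred, ref) -> PlanePairMetrics:
    return PlanePairMetrics(
        theta=included_angle(pred, ref),
        dist=coeff_distance(pred, ref),
        dyaw=abs(yaw(pred) - yaw(ref)),
        droll=abs(roll(pred) - roll(ref)),
    )


def evaluate_cohort(pairs) -> tuple[pd.DataFrame, dict]:
    """Per-pair metrics plus cohort summary for (predicted, reference) pairs.

    The summary carries means/SDs of the four metrics and the fractions of
    cases with coefficient distance < 0.05 and included angle < 1.0 degrees.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty cohort")
    rows = [asdict(plane_pair_metrics(p, r)) for p, r in pairs]
    df = pd.DataFrame(rows)
    summary = {}
    for col in df.columns:
        summary[f"mean_{col}"] = float(df[col].mean())
        summary[f"sd_{col}"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
    summary["frac_dist_lt_0.05"] = float((df["dist"] < 0.05).mean())
    summary["frac_theta_lt_1deg"] = float((df["theta"] < 1.0).mean())
    summary["n"] = len(df)
    return df, summary


@dataclass(frozen=True)
class AgreementStats:
    """Agreement of two paired measurement arms (B - A differences)."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    r: float
    p: float | None  # None when the differences have zero variance
    bias: float
    loa_low: float
    loa_high: float
    n: int


def agreement(method_a, method_b) -> AgreementStats:
    """Paired agreement statistics between two equally long value arrays."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diff = b - a
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):  # numerically constant differences
        sd = 0.0
    if sd > 0:
        tcrit = stats.t.ppf(0.975, df=n - 1)
        half = tcrit * sd / np.sqrt(n)
        ci_low, ci_high = mean - half, mean + half
        p = float(stats.ttest_rel(b, a).pvalue)
    else:
        ci_low = ci_high = mean
        p = None
    if a.std() > 0 and b.std() > 0:
        r = float(stats.pearsonr(a, b).statistic)
    else:
        r = 1.0 if np.allclose(a, b) else 0.0
    return AgreementStats(
        mean=mean,
        sd=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        r=r,
        p=p,
        bias=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=n,
    )


def bland_altman_plot(method_a, method_b, path, label: str = "") -> AgreementStats:
    """Scatter of pair means vs differences with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    st = agreement(a, b)
    means = (a + b) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, b - a, s=14, alpha=0.7)
    ax.axhline(st.bias, color="k", lw=1, label=f"bias {st.bias:+.3g}")
    for lim in (st.loa_low, st.loa_high):
        ax.axhline(lim, color="r", lw=1, ls="--")
    ax.set_xlabel(f"mean of methods {label}".strip())
    ax.set_ylabel("difference (B - A)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return st
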