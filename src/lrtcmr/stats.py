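"""Method-comparison statistics.

Bland-Altman agreement (bias, 95% limits of agreement, reproducibility
coefficient RPC = 1.96 * SD of the paired differences, i.e. exactly the
LoA half-width), ordinary least-squares regression with t-based 95%
confidence intervals and R^2, the paired t-test, and ROC/AUC via the
Mann-Whitney U identity with a seeded-bootstrap confidence interval.

Sign convention: differences are proposed - conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "PairedMeasurements",
    "AgreementStats",
    "bland_altman",
    "linreg",
    "paired_t",
    "roc_auc",
    "compare_methods",
    "normality_checks",
]


@dataclass
class PairedMeasurements:
    """Per-subject values from the conventional (x) and proposed (y) arms."""

    subject: list
    x: np.ndarray
    y: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D of equal length")
        if self.x.size < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite measurement")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def diff(self) -> np.ndarray:
        return self.y - self.x


@dataclass
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    rpc: float
    slope: float | None = None
    intercept: float | None = None
    slope_ci: tuple | None = None
    intercept_ci: tuple | None = None
    r2: float | None = None
    p_regression: float | None = None
    p_paired_t: float | None = None
    zero_variance: bool = False
    auc: float | None = None
    auc_ci: tuple | None = None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in ("slope_ci", "intercept_ci", "auc_ci"):
            v = d.pop(k)
            if v is not None:
                d[k + "_low"], d[k + "_high"] = float(v[0]), float(v[1])
        return d


def bland_altman(p: PairedMeasurements) -> tuple[float, float, float, float]:
    """(bias, loa_low, loa_high, rpc); rpc = 1.96 * sample SD (n-1) of the
    differences, so loa = bias +/- rpc exactly."""
    d = p.diff
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rpc = 1.96 * sd
    return bias, bias - rpc, bias + rpc, rpc


def linreg(x, y):
    """OLS y = slope*x + intercept with 95% t-CIs, R^2 and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for regression inference")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 0:
        raise ValueError("var(x) = 0")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    df = n - 2
    s2 = sse / df if df > 0 else 0.0
    se_slope = np.sqrt(s2 / sxx)
    se_int = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    tcrit = scipy.stats.t.ppf(0.975, df)
    if se_slope > 0:
        tstat = slope / se_slope
        p = 2.0 * scipy.stats.t.sf(abs(tstat), df)
    else:
        p = 0.0 if slope != 0 else 1.0
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_ci": (slope - tcrit * se_slope, slope + tcrit * se_slope),
        "intercept_ci": (intercept - tcrit * se_int, intercept + tcrit * se_int),
        "r2": float(r2),
        "p": float(p),
    }


def paired_t(p: PairedMeasurements):
    """Paired t-test; flags zero-variance differences instead of failing."""
    d = p.diff
    sd = d.std(ddof=1)
    if sd <= 1e-300 or not np.isfinite(sd) or sd == 0.0:
        return {"t": np.nan, "df": p.n - 1, "p": np.nan, "zero_variance": True}
    t = float(d.mean() / (sd / np.sqrt(p.n)))
    df = p.n - 1
    return {
        "t": t,
        "df": df,
        "p": float(2.0 * scipy.stats.t.sf(abs(t), df)),
        "zero_variance": False,
    }


def _auc_mannwhitney(labels, scores) -> float:
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(labels, scores, ci: bool = True, n_boot: int = 2000, seed: int = 0):
    """AUC by the Mann-Whitney identity (ties averaged) with a seeded
    bootstrap 95% CI over detection units."""
    auc = _auc_mannwhitney(labels, scores)
    if not ci:
        return auc, None
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = labels.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lb = labels[idx]
        if lb.all() or not lb.any():
            continue
        boots.append(_auc_mannwhitney(lb, scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return auc, (float(lo), float(hi))


def compare_methods(p: PairedMeasurements, labels=None, scores=None, seed: int = 0) -> AgreementStats:
    """Full comparison for one metric: Bland-Altman + regression + paired t
    (+ ROC when detection labels/scores are supplied)."""
    bias, lo, hi, rpc = bland_altman(p)
    out = AgreementStats(bias=bias, loa_low=lo, loa_high=hi, rpc=rpc)
    try:
        reg = linreg(p.x, p.y)
        out.slope = reg["slope"]
        out.intercept = reg["intercept"]
        out.slope_ci = reg["slope_ci"]
        out.intercept_ci = reg["intercept_ci"]
        out.r2 = reg["r2"]
        out.p_regression = reg["p"]
    except ValueError:
        pass
    t = paired_t(p)
    out.p_paired_t = t["p"]
    out.zero_variance = t["zero_variance"]
    if labels is not None and scores is not None:
        out.auc, out.auc_ci = roc_auc(labels, scores, seed=seed)
    return out


def normality_checks(p: PairedMeasurements) -> dict:
    """Shapiro-Wilk on the differences and Levene across arms (reported,
    not acceptance-bearing)."""
    sw = scipy.stats.shapiro(p.diff)
    lv = scipy.stats.levene(p.x, p.y)
    return {
        "shapiro_w": float(sw.statistic),
        "shapiro_p": float(sw.pvalue),
        "levene_stat": float(lv.statistic),
        "levene_p": float(lv.pvalue),
    }
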