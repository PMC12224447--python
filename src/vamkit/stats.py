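"""VOI reduction and the cohort statistical battery.

The analysis battery mirrors standard practice for region-of-interest
group studies: per-column robust outlier screening (ROUT at Q = 1%), a
D'Agostino-Pearson omnibus normality gate deciding between parametric
and rank-based tests, unpaired t / Mann-Whitney group comparisons,
Pearson / Spearman correlations, BMI-controlled partial correlations of
parameter means with age, and Benjamini-Hochberg FDR adjustment within
each comparison family (Q = 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "OutlierConfig",
    "voi_mean",
    "rout_outliers",
    "normality_gate",
    "two_group_compare",
    "correlate",
    "partial_correlation",
    "bh_fdr",
]


@dataclass
class StatResult:
    """One hypothesis test or correlation outcome."""

    comparison_id: str
    test_name: str
    statistic: float
    p_value: float
    n_used: int
    r: float = float("nan")
    q_value: float = float("nan")
    effect_direction: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class OutlierConfig:
    """FDR level for ROUT outlier calling (Prism-style default Q = 1%)."""

    rout_q: float = 0.01
    max_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.rout_q < 0.5:
            raise ValueError(f"rout_q must be in (0, 0.5), got {self.rout_q}")


# ---------------------------------------------------------------------------
# VOI reduction


def voi_mean(param_map: np.ndarray, voi_labels: np.ndarray, label: int,
             valid_mask: np.ndarray | None = None) -> dict:
    """Mean / SD / 95% CI / count over the valid voxels of one VOI.

    Valid voxels are those carrying the label, finite in the map, and
    inside ``valid_mask`` when given (e.g. the healthy hemisphere).
    Returns NaN statistics with ``n_voxels = 0`` when nothing is valid.
    """
    param_map = np.asarray(param_map, dtype=float)
    sel = np.asarray(voi_labels) == label
    if valid_mask is not None:
        sel &= np.asarray(valid_mask, dtype=bool)
    vals = param_map[sel]
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n == 0:
        nan = float("nan")
        return {"mean": nan, "sd": nan, "ci95": (nan, nan), "n_voxels": 0}
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    else:
        half = 0.0
    return {"mean": mean, "sd": sd, "ci95": (mean - half, mean + half),
            "n_voxels": n}


# ---------------------------------------------------------------------------
# ROUT outlier screening


def _robust_location_scale(x: np.ndarray, n_iter: int = 100,
                           tol: float = 1e-10) -> tuple[float, float]:
    """IRLS constant-model fit with Lorentzian weights + robust SD.

    The robust SD is the 68.27th percentile of absolute residuals with
    the small-sample correction n/(n-K), K = 1 for a constant model.
    """
    n = len(x)
    loc = float(np.median(x))
    scale = float(np.percentile(np.abs(x - loc), 68.27)) * n / (n - 1)
    if scale == 0:
        return loc, 0.0
    for _ in range(n_iter):
        r = (x - loc) / scale
        w = 1.0 / (1.0 + r**2)
        new_loc = float(np.sum(w * x) / np.sum(w))
        scale = float(np.percentile(np.abs(x - new_loc), 68.27)) * n / (n - 1)
        if scale == 0:
            return new_loc, 0.0
        if abs(new_loc - loc) < tol * max(scale, 1.0):
            loc = new_loc
            break
        loc = new_loc
    return loc, scale


def rout_outliers(values: np.ndarray,
                  config: OutlierConfig | None = None) -> np.ndarray:
    """Boolean outlier flags per value via the ROUT procedure.

    A robust location is fitted by iteratively reweighted least squares
    (Lorentzian weights), residuals are standardized by the corrected
    68.27th-percentile robust SD, two-sided t p-values (n-1 df) are
    screened with a Benjamini-Hochberg-style step-up at ``rout_q``, and
    at most ``max_fraction`` of the sample may be flagged.  Samples with
    n < 10 are returned unflagged with a warning.
    """
    config = config or OutlierConfig()
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    if len(x) < 10:
        warnings.warn("ROUT screening skipped: need n >= 10", stacklevel=2)
        return flags
    loc, scale = _robust_location_scale(x)
    if scale == 0:  # all (robustly) identical -> no outliers
        return flags
    t_stat = np.abs(x - loc) / scale
    pvals = 2.0 * sps.t.sf(t_stat, df=len(x) - 1)
    order = np.argsort(pvals)
    m = len(x)
    thresh = config.rout_q * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    k_star = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    k_star = min(k_star, int(np.floor(config.max_fraction * m)))
    flags[order[:k_star]] = True
    return flags


# ---------------------------------------------------------------------------
# normality gate and gated tests


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """D'Agostino-Pearson omnibus gate: ("gaussian"|"non_gaussian", p).

    K^2 combines the skewness and kurtosis Z statistics and is referred
    to chi-square with 2 df; samples smaller than the test's validity
    floor (n = 8) are conservatively routed to the non-parametric path.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        warnings.warn("normality gate needs n >= 8; treating as non-Gaussian",
                      stacklevel=2)
        return "non_gaussian", float("nan")
    if np.ptp(x) == 0:
        return "non_gaussian", 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(x)
    return ("gaussian" if p >= alpha else "non_gaussian"), float(p)


def two_group_compare(values_a: np.ndarray, values_b: np.ndarray,
                      comparison_id: str = "",
                      gate_alpha: float = 0.05) -> StatResult | None:
    """Unpaired two-sided group comparison with a normality gate.

    Both groups Gaussian by the gate -> Student's t (pooled variance);
    otherwise Mann-Whitney (exact for group sizes <= 20 without ties,
    tie-corrected normal approximation otherwise).  Returns ``None``
    when either group has fewer than 2 usable values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return None
    gaussian = (normality_gate(a, gate_alpha)[0] == "gaussian"
                and normality_gate(b, gate_alpha)[0] == "gaussian")
    direction = float(np.sign(np.mean(a) - np.mean(b)))
    if gaussian:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        name = "t"
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        small = max(len(a), len(b)) <= 20
        method = "exact" if (small and not has_ties) else "asymptotic"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method=method)
        name = "mann-whitney"
    return StatResult(comparison_id=comparison_id, test_name=name,
                      statistic=float(stat), p_value=float(min(p, 1.0)),
                      n_used=len(a) + len(b), effect_direction=direction)


def correlate(x: np.ndarray, y: np.ndarray, comparison_id: str = "",
              gate_alpha: float = 0.05) -> StatResult | None:
    """Pearson (both variables Gaussian) or Spearman correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    gaussian = (normality_gate(x, gate_alpha)[0] == "gaussian"
                and normality_gate(y, gate_alpha)[0] == "gaussian")
    if gaussian:
        r, p = sps.pearsonr(x, y)
        name = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        name = "spearman"
    return StatResult(comparison_id=comparison_id, test_name=name,
                      statistic=float(r), p_value=float(p), n_used=len(x),
                      r=float(r), effect_direction=float(np.sign(r)))


def _rankdata(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                        comparison_id: str = "",
                        method: str = "auto",
                        gate_alpha: float = 0.05) -> StatResult | None:
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))`` on raw
    values (Pearson path) or on ranks (Spearman path); the path is
    chosen by the normality gate on x and y when ``method="auto"``.
    Significance from ``t = r*sqrt((n-3)/(1-r^2))`` with n-3 df.
    Degenerate confounding (|r_xz| = 1 or |r_yz| = 1) returns ``None``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = len(x)
    if n < 5:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "auto":
        gaussian = (normality_gate(x, gate_alpha)[0] == "gaussian"
                    and normality_gate(y, gate_alpha)[0] == "gaussian")
        method = "pearson" if gaussian else "spearman"
    if method == "spearman":
        x, y, z = _rankdata(x), _rankdata(y), _rankdata(z)
        name = "partial-spearman"
    else:
        name = "partial-pearson"

    def _r(u, v):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    r_xy, r_xz, r_yz = _r(x, y), _r(x, z), _r(y, z)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        return None
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
        t = float("inf")
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(comparison_id=comparison_id, test_name=name,
                      statistic=float(t), p_value=p, n_used=n, r=r,
                      effect_direction=float(np.sign(r)))


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone q-values).

    NaN p-values are passed through as NaN q-values and never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return reject, qvals
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
    reject[ok] = rej
    qvals[ok] = qv
    return reject, qvals
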