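"""Statistical evaluation layer.

Recording-level agreement and development statistics: Bland-Altman
analysis of annotated vs classifier-produced category fractions (with a
two-tailed one-sample t-test of zero mean error), the monthly developmental
change Delta (OLS slope of occupancy vs age, percentage points/month),
Pearson/Spearman correlations, the ten-test battery for comparing two
dependent overlapping correlations, quadratic age-trajectory fits with
pointwise confidence bands, and posture/movement transition rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    mean_error: float           # predicted - annotated, percentage points
    sd_error: float
    band: tuple[float, float]   # mean +/- 2 SD
    t_stat: float
    df: int
    p_value: float
    delta_band: float | None = None  # +/- monthly-change overlay (pp/month)


def bland_altman(annotated, predicted, delta: float | None = None,
                 as_percent: bool = True) -> BlandAltmanResult:
    """Paired-method agreement on per-recording category fractions.

    The error is ``predicted - annotated``; a two-tailed one-sample t-test
    (df = n - 1) tests the null hypothesis that errors have zero mean.
    Fractions are reported in percentage points when ``as_percent``.
    """
    a = np.asarray(annotated, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("annotated/predicted must be aligned 1-D vectors")
    if len(a) < 3:
        raise ValueError("need n >= 3 recordings")
    scale = 100.0 if as_percent else 1.0
    err = (p - a) * scale
    mean = float(err.mean())
    sd = float(err.std(ddof=1))
    if sd > 1e-12:
        t, pv = sps.ttest_1samp(err, 0.0)
    else:
        t, pv = (0.0, 1.0) if mean == 0 else (np.inf * np.sign(mean), 0.0)
    return BlandAltmanResult(mean_error=mean, sd_error=sd,
                             band=(mean - 2 * sd, mean + 2 * sd),
                             t_stat=float(t), df=len(a) - 1,
                             p_value=float(pv), delta_band=delta)


def monthly_delta(ages, fractions, as_percent: bool = True) -> float:
    """Monthly developmental change: OLS slope of a category's occupancy
    fraction against age, in percentage points per month."""
    ages = np.asarray(ages, float)
    f = np.asarray(fractions, float)
    if len(ages) < 3:
        raise ValueError("need n >= 3")
    if np.var(ages) == 0:
        raise ValueError("zero age variance")
    slope = np.polyfit(ages, f, 1)[0]
    return float(slope * (100.0 if as_percent else 1.0))


def correlations(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson's r or Spearman's rho with a two-tailed p value.

    Spearman p values use an exact permutation distribution for n <= 9 and
    the t approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        import itertools

        if len(x) <= 9:
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            rho = float(np.corrcoef(rx, ry)[0, 1])
            count = 0
            total = 0
            for perm in itertools.permutations(ry):
                rp = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
                count += abs(rp) >= abs(rho) - 1e-12
                total += 1
            return rho, count / total
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


# --------------------------------------------------------------------------
# Comparing two dependent overlapping correlations
# --------------------------------------------------------------------------

@dataclass
class CocorResult:
    """Ten-test battery for H0: r.jk = r.jh with overlapping variable j.

    ``tests`` maps test name -> (statistic, two-tailed p); Zou's method
    instead yields a confidence interval for r.jk - r.jh.
    """

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    tests: dict
    zou_ci: tuple[float, float]


def _det3(r_jk, r_jh, r_kh):
    return 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh


def _dunn_clark_c(r_jk, r_jh, r_kh):
    num = (r_kh * (1 - r_jk**2 - r_jh**2)
           - 0.5 * r_jk * r_jh * (1 - r_jk**2 - r_jh**2 - r_kh**2))
    return num / ((1 - r_jk**2) * (1 - r_jh**2))


def cocor_battery(r_jk: float, r_jh: float, r_kh: float, n: int,
                  alpha: float = 0.05) -> CocorResult:
    """Compare two dependent overlapping correlations (j the common
    variable): Pearson-Filon z, Hotelling t, Williams t, Olkin z, Dunn &
    Clark z, Hendrickson-Stanley-Hills t, Steiger z, Meng-Rosenthal-Rubin
    z, Hittner-May-Silver z, and Zou's confidence interval.
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    R = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")

    det = _det3(r_jk, r_jh, r_kh)
    diff = r_jk - r_jh
    z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
    tests: dict = {}

    def p_from_z(z):
        return 2 * sps.norm.sf(abs(z))

    def p_from_t(t, df):
        return 2 * sps.t.sf(abs(t), df)

    # (1) Pearson & Filon (1898)
    k = (r_kh * (1 - r_jk**2 - r_jh**2)
         - 0.5 * r_jk * r_jh * (1 - r_jk**2 - r_jh**2 - r_kh**2))
    denom = (1 - r_jk**2) ** 2 + (1 - r_jh**2) ** 2 - 2 * k
    z = diff * np.sqrt(n) / np.sqrt(denom)
    tests["pearson1898"] = (float(z), float(p_from_z(z)))

    # (2) Hotelling (1940)
    t = diff * np.sqrt((n - 3) * (1 + r_kh) / (2 * det))
    tests["hotelling1940"] = (float(t), float(p_from_t(t, n - 3)))

    # (3) Williams (1959)
    rbar = (r_jk + r_jh) / 2
    t = diff * np.sqrt(
        (n - 1) * (1 + r_kh)
        / (2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3))
    tests["williams1959"] = (float(t), float(p_from_t(t, n - 3)))

    # (4) Olkin (1967)
    denom = ((1 - r_jk**2) ** 2 + (1 - r_jh**2) ** 2 - 2 * r_kh**3
             - (2 * r_kh - r_jk * r_jh) * (1 - r_jk**2 - r_jh**2 - r_kh**2))
    z = diff * np.sqrt(n) / np.sqrt(denom)
    tests["olkin1967"] = (float(z), float(p_from_z(z)))

    # (5) Dunn & Clark (1969)
    c = _dunn_clark_c(r_jk, r_jh, r_kh)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * c))
    tests["dunn1969"] = (float(z), float(p_from_z(z)))

    # (6) Hendrickson, Stanley & Hills (1970) modification of Williams' t
    t = (diff * np.sqrt((n - 3) * (1 + r_kh))
         / np.sqrt(2 * det + diff**2 * (1 - r_kh) ** 3 / (4 * (n - 3))))
    tests["hendrickson1970"] = (float(t), float(p_from_t(t, n - 3)))

    # (7) Steiger (1980): Dunn & Clark with average correlations
    rm = (r_jk + r_jh) / 2
    c7 = ((r_kh * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_kh**2))
          / (1 - rm**2) ** 2)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * c7))
    tests["steiger1980"] = (float(z), float(p_from_z(z)))

    # (8) Meng, Rosenthal & Rubin (1992)
    r2bar = (r_jk**2 + r_jh**2) / 2
    f = min((1 - r_kh) / (2 * (1 - r2bar)), 1.0)
    h = (1 - f * r2bar) / (1 - r2bar)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 * (1 - r_kh) * h))
    tests["meng1992"] = (float(z), float(p_from_z(z)))

    # (9) Hittner, May & Silver (2003): back-transformed average Fisher Z
    rbm = np.tanh((z_jk + z_jh) / 2)
    c9 = ((r_kh * (1 - 2 * rbm**2) - 0.5 * rbm**2 * (1 - 2 * rbm**2 - r_kh**2))
          / (1 - rbm**2) ** 2)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * c9))
    tests["hittner2003"] = (float(z), float(p_from_z(z)))

    # (10) Zou (2007) confidence interval for r.jk - r.jh
    zc = sps.norm.ppf(1 - alpha / 2)
    se = 1 / np.sqrt(n - 3)
    l1, u1 = np.tanh(z_jk - zc * se), np.tanh(z_jk + zc * se)
    l2, u2 = np.tanh(z_jh - zc * se), np.tanh(z_jh + zc * se)
    c = _dunn_clark_c(r_jk, r_jh, r_kh)
    lower = diff - np.sqrt((r_jk - l1) ** 2 + (u2 - r_jh) ** 2
                           - 2 * c * (r_jk - l1) * (u2 - r_jh))
    upper = diff + np.sqrt((u1 - r_jk) ** 2 + (r_jh - l2) ** 2
                           - 2 * c * (u1 - r_jk) * (r_jh - l2))
    return CocorResult(r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n, tests=tests,
                       zou_ci=(float(lower), float(upper)))


# --------------------------------------------------------------------------
# Trajectory fits and transition rates
# --------------------------------------------------------------------------

@dataclass
class QuadraticFit:
    coef: np.ndarray            # highest degree first
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    residual_sd: float


def quadratic_trajectory(ages, fractions, ci: float = 0.95) -> QuadraticFit:
    """Degree-2 least-squares trajectory with a pointwise confidence band."""
    ages = np.asarray(ages, float)
    y = np.asarray(fractions, float)
    if len(ages) < 4:
        raise ValueError("need n >= 4")
    X = np.column_stack([ages**2, ages, np.ones_like(ages)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear design (degenerate ages)")
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    dof = len(ages) - 3
    s2 = float(((y - fitted) ** 2).sum() / max(dof, 1))
    xtx_inv = np.linalg.inv(X.T @ X)
    lev = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    se = np.sqrt(s2 * lev)
    tcrit = sps.t.ppf(0.5 + ci / 2, max(dof, 1))
    return QuadraticFit(coef=coef, fitted=fitted,
                        ci_lower=fitted - tcrit * se,
                        ci_upper=fitted + tcrit * se,
                        residual_sd=np.sqrt(s2))


@dataclass
class TransitionRates:
    posture_per_min: float
    movement_per_min: float
    analyzed_minutes: float


def transition_rates(posture_labels, movement_labels,
                     retained: np.ndarray | None = None,
                     step_s: float = 60.0 / 52.0) -> TransitionRates:
    """Label changes between consecutive retained frames per analyzed
    minute. A gap in the retained frames does not count as a transition.

    ``step_s`` is the frame hop in seconds (60 samples at 52 Hz by
    default); pass 1.0 for per-second label tracks.
    """
    p = np.asarray(posture_labels)
    m = np.asarray(movement_labels)
    if p.shape != m.shape or len(p) < 2:
        raise ValueError("need >= 2 aligned frames")
    keep = np.ones(len(p), bool) if retained is None else np.asarray(retained, bool)
    idx = np.flatnonzero(keep)
    if len(idx) < 2:
        raise ValueError("fewer than 2 retained frames")
    adjacent = np.diff(idx) == 1
    p_trans = int(np.sum((p[idx[1:]] != p[idx[:-1]]) & adjacent))
    m_trans = int(np.sum((m[idx[1:]] != m[idx[:-1]]) & adjacent))
    minutes = len(idx) * step_s / 60.0
    return TransitionRates(posture_per_min=p_trans / minutes,
                           movement_per_min=m_trans / minutes,
                           analyzed_minutes=minutes)
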