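"""Circular descriptive statistics and the two hypothesis tests the
detour analysis relies on.

Flight bearings, dance angles and signed errors are directions, so
ordinary moments are meaningless: the mean of {+170, -170} degrees is 0
linearly but 180 circularly.  Everything here works on the unit circle:
the circular mean and mean resultant length R, the circular standard
deviation sqrt(-2 ln R), von Mises maximum-likelihood fitting, the
Mardia-Watson-Wheeler uniform-scores test for k-sample differences in
circular distribution, and Fisher's test for homogeneity of von Mises
concentration parameters ("equal kappa").  Both tests offer an exact-style
permutation fallback for small or tied samples.

Angles are degrees throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CircularSample",
    "CircTestResult",
    "circ_mean_resultant",
    "circ_sd",
    "vonmises_fit",
    "kappa_from_R",
    "mww_test",
    "equal_kappa_test",
]

_KAPPA_CAP = 1e6


@dataclass
class CircularSample:
    """A set of angles (degrees) with a group label."""

    angles: np.ndarray
    group_label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.angles, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("CircularSample requires at least one angle")
        if not np.all(np.isfinite(arr)):
            raise ValueError("angles must be finite")
        # wrap to (-180, 180]
        self.angles = 180.0 - np.mod(180.0 - arr, 360.0)

    def __len__(self):
        return self.angles.size


@dataclass
class CircTestResult:
    statistic: float
    df: int
    p_value: float
    method: str  # "asymptotic" or "permutation"
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return {"statistic": self.statistic, "df": self.df,
                "p": self.p_value, "method": self.method}


def _as_angles(sample) -> np.ndarray:
    if isinstance(sample, CircularSample):
        return sample.angles
    return np.asarray(sample, dtype=float).ravel()


def circ_mean_resultant(sample) -> tuple:
    """Circular mean direction (degrees) and mean resultant length R.

    Returns ``(mean, R)``; the mean is NaN (with a warning) when R is
    numerically zero, e.g. for antipodal pairs.
    """
    a = np.radians(_as_angles(sample))
    c, s = np.cos(a).sum(), np.sin(a).sum()
    n = a.size
    r = float(np.hypot(c, s) / n)
    if r < 1e-12:
        warnings.warn("resultant length ~0: circular mean undefined")
        return float("nan"), 0.0
    mean = np.degrees(np.arctan2(s, c))
    return float(180.0 - np.mod(180.0 - mean, 360.0)), r


def circ_sd(R: float) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    if R > 1 and R < 1 + 1e-9:  # accumulated float error on tight samples
        R = 1.0
    if not 0 <= R <= 1:
        raise ValueError("R must lie in [0, 1]")
    if R == 0:
        warnings.warn("R=0: circular s.d. infinite")
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


def kappa_from_R(R: float) -> float:
    """Von Mises concentration from mean resultant length.

    Standard A^-1 approximation (Fisher 1993, eq. 4.40-4.42); capped at
    1e6 for numerically degenerate R ~ 1.
    """
    if R < 0.53:
        k = 2 * R + R ** 3 + 5 * R ** 5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        denom = R ** 3 - 4 * R ** 2 + 3 * R
        k = 1 / denom if denom > 1e-12 else _KAPPA_CAP
    return float(min(k, _KAPPA_CAP))


def vonmises_fit(sample) -> tuple:
    """MLE (mu, kappa) of a von Mises distribution, degrees.

    For nearly uniform samples (R ~ 0) the direction is arbitrary and
    kappa ~ 0 is returned with a warning.
    """
    angles = _as_angles(sample)
    if angles.size < 2:
        raise ValueError("need at least 2 angles to fit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu, r = circ_mean_resultant(angles)
    if r < 1e-12:
        warnings.warn("R~0: concentration indistinguishable from uniform")
        return 0.0, 0.0
    kappa = kappa_from_R(r)
    if kappa >= _KAPPA_CAP:
        warnings.warn("R~1: kappa capped")
    return mu, kappa


# --------------------------------------------------------------------------
# Mardia-Watson-Wheeler uniform-scores test
# --------------------------------------------------------------------------

def _mww_statistic(angles: np.ndarray, labels: np.ndarray) -> float:
    """W from pre-assigned uniform scores (ranks fixed across permutations)."""
    n = angles.size
    ranks = stats.rankdata(angles)  # midranks on ties
    beta = 2.0 * np.pi * ranks / n
    w = 0.0
    for g in np.unique(labels):
        m = labels == g
        ni = int(m.sum())
        ci, si = np.cos(beta[m]).sum(), np.sin(beta[m]).sum()
        w += (ci * ci + si * si) / ni
    return float(2.0 * w)


def mww_test(samples: Sequence, method: str = "asymptotic",
             n_perm: int = 9999, seed=None) -> CircTestResult:
    """Mardia-Watson-Wheeler k-sample test on circular data.

    Pooled angles are converted to uniform scores beta_j = 2*pi*rank/N;
    the statistic W = 2 * sum_i (C_i^2 + S_i^2)/n_i is chi-square with
    2(k-1) df under the null of a common distribution.  Ties are broken
    by midranks (with a warning); ``method="permutation"`` shuffles
    group labels instead of using the asymptotic reference.
    """
    groups = [_as_angles(s) for s in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    angles = np.concatenate(groups)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    k = len(groups)
    df = 2 * (k - 1)

    warns = []
    if np.unique(angles).size < angles.size:
        warns.append("ties present: midranks used; permutation p recommended")
        warnings.warn(warns[-1])

    w_obs = _mww_statistic(angles, labels)
    if method == "asymptotic":
        p = float(stats.chi2.sf(w_obs, df))
        return CircTestResult(w_obs, df, p, "asymptotic", warns)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _mww_statistic(angles, lab) >= w_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CircTestResult(w_obs, df, float(p), "permutation", warns)


# --------------------------------------------------------------------------
# Equal-kappa (concentration homogeneity) test
# --------------------------------------------------------------------------

def _equal_kappa_statistic(groups) -> tuple:
    """Fisher's concentration-homogeneity chi-square and its regime.

    Three variance-stabilising regimes chosen by the pooled mean
    resultant length: arcsine for R < 0.45, asinh for 0.45 <= R <= 0.70
    and a Bartlett-type statistic on circular dispersions for R > 0.70
    (Fisher 1993, section 5.4.4).
    """
    ns = np.array([g.size for g in groups], dtype=float)
    rs = np.array([circ_mean_resultant(g)[1] for g in groups])
    n_tot = ns.sum()
    r_bar = float((ns * rs).sum() / n_tot)
    p = len(groups)

    if r_bar < 0.45:
        g1 = np.arcsin(np.clip(2.0 * rs * np.sqrt(3.0 / 8.0), -1, 1))
        w = 4.0 * (ns - 4.0) / 3.0
        u = float((w * g1 ** 2).sum() - (w * g1).sum() ** 2 / w.sum())
        regime = "arcsin"
    elif r_bar <= 0.70:
        g2 = np.arcsinh((rs - 1.089) / 0.258)
        w = (ns - 3.0) / 0.798
        u = float((w * g2 ** 2).sum() - (w * g2).sum() ** 2 / w.sum())
        regime = "asinh"
    else:
        # 2*kappa*(n_i - R_i_sum) ~ chi2(n_i - 1): Bartlett on dispersions
        nu = ns - 1.0
        d = np.maximum((ns - ns * rs) / nu, 1e-12)
        nu_tot = nu.sum()
        pooled = float((nu * d).sum() / nu_tot)
        u = nu_tot * np.log(pooled) - float((nu * np.log(d)).sum())
        corr = 1.0 + ((1.0 / nu).sum() - 1.0 / nu_tot) / (3.0 * (p - 1))
        u = float(u / corr)
        regime = "bartlett"
    return u, regime


def equal_kappa_test(samples: Sequence, method: str = "asymptotic",
                     n_perm: int = 9999, seed=None) -> CircTestResult:
    """Test homogeneity of von Mises concentrations across k samples.

    Used to ask whether one group's angles are more *scattered* than
    another's (e.g. dancers vs recruits) irrespective of their mean
    directions.  Chi-square with k-1 df asymptotically; groups of n < 5
    or R = 1 exactly trigger the permutation fallback, which recentres
    nothing (the statistic is location-free in each regime's input R).
    """
    groups = [_as_angles(s) for s in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    df = k - 1
    warns = []
    rs = [circ_mean_resultant(g)[1] for g in groups]
    degenerate = any(r > 1 - 1e-12 for r in rs)
    if degenerate and method == "asymptotic":
        warns.append("degenerate group (R=1): using permutation")
        warnings.warn(warns[-1])
        method = "permutation"
    if any(g.size < 5 for g in groups):
        warns.append("group with n < 5: asymptotic regime unreliable")

    u_obs, regime = _equal_kappa_statistic(groups)
    if method == "asymptotic":
        p = float(stats.chi2.sf(u_obs, df))
        return CircTestResult(u_obs, df, p, "asymptotic", warns)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    # permute *centred* angles so only concentration differences matter
    centred = []
    for g in groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu, r = circ_mean_resultant(g)
        mu = 0.0 if not np.isfinite(mu) else mu
        centred.append(180.0 - np.mod(180.0 - (g - mu), 360.0))
    pooled = np.concatenate(centred)
    sizes = [g.size for g in groups]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        try:
            u_p, _ = _equal_kappa_statistic(parts)
        except (ValueError, FloatingPointError):
            continue
        if u_p >= u_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CircTestResult(u_obs, df, float(p), "permutation", warns)
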