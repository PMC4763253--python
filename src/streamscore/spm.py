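"""One-dimensional statistical parametric mapping for paired curve data.

A paired t statistic is computed at every grid point of a subjects x time
difference matrix; the smoothness (FWHM) of the residual field is
estimated from normalised residual gradients; random field theory supplies
a family-wise threshold via the expected Euler characteristic of the
thresholded t field, and suprathreshold clusters receive p-values from the
standard extent approximation.  A sign-flip permutation analogue using the
same cluster-forming threshold and a max-cluster-mass null serves as the
assumption-free oracle.  Inference is two-tailed on |t|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

_SQRT_4LN2 = math.sqrt(4.0 * math.log(2.0))
#: cap applied to infinite t values (zero-variance points) before clustering
_T_CAP_Q = 0.9999


class SPMError(ValueError):
    pass


@dataclass
class SPMResult:
    t_field: np.ndarray
    df: int
    fwhm: float
    resels: float
    t_crit: float
    clusters: list          # (start_idx, end_idx_inclusive, extent_pts, cluster_p)
    method: str             # rft | permutation
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return any(p <= self.alpha for *_, p in self.clusters)


def paired_t_field(diffs: np.ndarray) -> tuple[np.ndarray, int]:
    """Pointwise one-sample t on subject difference fields.

    NaNs are excluded listwise per point; the reported df is the minimum
    per-point n minus one.  Zero-variance points yield +/-inf with a
    warning.
    """
    D = np.asarray(diffs, dtype=float)
    if D.ndim != 2 or D.shape[0] < 3:
        raise SPMError("need a (subjects x time) matrix with >= 3 subjects")
    n = np.sum(~np.isnan(D), axis=0)
    if np.any(n < 2):
        raise SPMError("fewer than 2 subjects defined at some point")
    mean = np.nanmean(D, axis=0)
    sd = np.nanstd(D, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        log.warning("zero variance at %d point(s); t set to +/-inf", zero_var.sum())
        t = np.where(zero_var, np.where(mean > 0, np.inf,
                                        np.where(mean < 0, -np.inf, 0.0)), t)
    return t, int(n.min()) - 1


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness of a residual field, in grid units.

    Residuals are normalised pointwise to unit sum of squares; the FWHM of
    the equivalent Gaussian kernel is sqrt(4 ln 2) over the RMS gradient of
    the normalised field.  White noise gives sqrt(2 ln 2) ~ 1.18 grid
    units.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise SPMError("need a (subjects x time) residual matrix with >= 2 points")
    ssq = np.sum(R ** 2, axis=0)
    if np.any(ssq == 0):
        raise SPMError("constant residuals: smoothness undefined (infinite)")
    dy = np.diff(R, axis=1)
    v = np.sum(dy ** 2, axis=0) / (0.5 * (ssq[:-1] + ssq[1:]))
    if np.all(v == 0):
        raise SPMError("constant residuals: smoothness undefined (infinite)")
    resels_per_node = np.sqrt(v) / _SQRT_4LN2
    return float(1.0 / np.mean(resels_per_node))


def residual_fields(diffs: np.ndarray) -> np.ndarray:
    """Subject fields minus the pointwise mean."""
    D = np.asarray(diffs, dtype=float)
    return D - np.nanmean(D, axis=0, keepdims=True)


def _ec_density_1d(u: float, df: int) -> float:
    """1D EC density of a t field at threshold u."""
    return (_SQRT_4LN2 / (2.0 * math.pi)
            * (1.0 + u * u / df) ** (-(df - 1) / 2.0))


def expected_ec(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of the u-thresholded t field (one tail)."""
    return float(t_dist.sf(u, df) + resels * _ec_density_1d(u, df))


def rft_threshold(df: int, resels: float, alpha: float = 0.05,
                  two_tailed: bool = True) -> float:
    """Smallest u with expected EC <= alpha (alpha/2 per tail if two-tailed)."""
    if resels <= 0:
        raise SPMError("resels must be positive")
    if not (0.0 < alpha < 1.0):
        raise SPMError("alpha must lie in (0, 1)")
    target = alpha / 2.0 if two_tailed else alpha
    f = lambda u: expected_ec(u, df, resels) - target
    hi = 10.0
    while f(hi) > 0 and hi < 1e4:
        hi *= 2.0
    if f(hi) > 0:
        raise SPMError("alpha unreachable for these df/resels")
    lo = 1e-6
    if f(lo) < 0:
        raise SPMError("alpha unreachable: EC already below target at u ~ 0")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _cap_infinite(t: np.ndarray, df: int) -> np.ndarray:
    cap = t_dist.ppf(_T_CAP_Q, df)
    return np.clip(t, -cap, cap)


def _suprathreshold_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end_inclusive) index pairs."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def cluster_inference(
    t_field: np.ndarray, t_crit: float, fwhm: float, df: int,
    alpha: float = 0.05, resels: float | None = None,
) -> list[tuple[int, int, int, float]]:
    """Suprathreshold clusters of |t| with RFT extent p-values.

    Cluster p follows the 1D extent approximation: with E[m] clusters
    expected and expected suprathreshold volume E[N] (in resels),
    P(extent >= k) = exp(-beta k^2), beta = (Gamma(3/2) E[m] / E[N])^2,
    and the cluster-level p is 1 - exp(-E[m] P(extent >= k)).
    """
    t = _cap_infinite(np.asarray(t_field, float), df)
    L = t.size
    if resels is None:
        resels = (L - 1) / fwhm
    mask = np.abs(t) >= t_crit
    runs = _suprathreshold_runs(mask)
    if not runs:
        return []
    em = 2.0 * expected_ec(t_crit, df, resels)          # both tails
    en = 2.0 * t_dist.sf(t_crit, df) * resels           # expected volume, resels
    beta = (math.gamma(1.5) * em / max(en, 1e-300)) ** 2
    clusters = []
    for s, e in runs:
        extent_pts = e - s + 1
        k = extent_pts / fwhm
        p_ge_k = math.exp(-beta * k * k)
        p = 1.0 - math.exp(-em * p_ge_k)
        clusters.append((int(s), int(e), int(extent_pts), float(min(max(p, 1e-300), 1.0))))
    return clusters


def spm_cluster_test(diffs: np.ndarray, alpha: float = 0.05) -> SPMResult:
    """Full RFT route: paired t field, smoothness, threshold, clusters."""
    t, df = paired_t_field(diffs)
    R = residual_fields(diffs)
    fwhm = estimate_fwhm(R)
    resels = (t.size - 1) / fwhm
    t_crit = rft_threshold(df, resels, alpha)
    clusters = cluster_inference(t, t_crit, fwhm, df, alpha, resels)
    return SPMResult(t, df, fwhm, resels, t_crit, clusters, "rft", alpha)


def _t_fields_signflip(D: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t fields for many sign-flip patterns at once.

    The pointwise sum of squares is flip-invariant, so only the flipped
    means need recomputing: a single matmul covers all permutations.
    """
    n, L = D.shape
    ssq = np.sum(D ** 2, axis=0)                 # (L,)
    means = signs @ D / n                        # (n_perm, L)
    var = (ssq[None, :] - n * means ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def _max_cluster_masses(T: np.ndarray, t_crit: float) -> np.ndarray:
    """Max cluster mass (sum of |t| - t_crit) per row of a t-field stack."""
    excess = np.abs(T) - t_crit
    mask = excess > 0
    structure = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    labels, n_lab = ndimage.label(mask, structure=structure)
    out = np.zeros(T.shape[0])
    if n_lab == 0:
        return out
    masses = ndimage.sum_labels(np.where(mask, excess, 0.0), labels,
                                index=np.arange(1, n_lab + 1))
    # map each label to its row, then take per-row maxima
    rows = ndimage.minimum(
        np.repeat(np.arange(T.shape[0])[:, None], T.shape[1], axis=1),
        labels, index=np.arange(1, n_lab + 1),
    ).astype(int)
    np.maximum.at(out, rows, masses)
    return out


def signflip_cluster_test(
    diffs: np.ndarray, alpha: float = 0.05, n_perm: int = 1000,
    seed: int = 0, t_crit: float | None = None,
) -> SPMResult:
    """Sign-flip permutation analogue of the RFT cluster test.

    The cluster-forming threshold defaults to the RFT threshold, so RFT
    and permutation cluster boundaries coincide; cluster p-values come
    from the null distribution of the maximum cluster mass over random
    sign flips of the subject difference fields.
    """
    D = np.asarray(diffs, dtype=float)
    if np.isnan(D).any():
        raise SPMError("permutation route requires fully defined fields")
    t, df = paired_t_field(D)
    try:
        fwhm = estimate_fwhm(residual_fields(D))
    except SPMError:
        if t_crit is None:
            raise
        fwhm = np.nan    # degenerate field with an explicit threshold
    resels = (t.size - 1) / fwhm
    if t_crit is None:
        t_crit = rft_threshold(df, resels, alpha)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, D.shape[0]))
    signs[0] = 1.0                                   # include the identity
    null_mass = _max_cluster_masses(_t_fields_signflip(D, signs), t_crit)
    t_capped = _cap_infinite(t, df)
    runs = _suprathreshold_runs(np.abs(t_capped) >= t_crit)
    clusters = []
    for s, e in runs:
        mass = float(np.sum(np.abs(t_capped[s:e + 1]) - t_crit))
        p = (1 + int(np.sum(null_mass >= mass))) / (n_perm + 1)
        clusters.append((int(s), int(e), int(e - s + 1), float(p)))
    return SPMResult(t, df, fwhm, resels, float(t_crit), clusters,
                     "permutation", alpha)
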