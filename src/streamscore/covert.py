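"""Covert-attention mixture model and the q-grid exclusion scan.

The model assumes attention is wholly on the tones or the noises in each
0.5-s window, independently with probability q on the tones.  The chance
that attention has been continuously on the tones for exactly k windows
just before the switch is geometric: w_k = (1-q) q^k for k < K and
w_K = q^K, with K windows in the pre-switch period.  The predicted
switch-aligned build-up curve is the attend curve averaged over these
time shifts: M(t) = sum_k w_k A(t + k * 0.5).  The scan tests every q on a
grid with the paired SPM cluster test and returns the q values for which
no cluster of model-data difference survives; the paper-style outcome is
the interval of q values not excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import spm as _spm
from .spm import signflip_cluster_test, SPMError
from .timeline import TRIPLET_PERIOD_S

DEFAULT_WINDOW_S = TRIPLET_PERIOD_S
DEFAULT_K = 25                    # 12.5-s pre-switch period / 0.5-s windows


class CovertModelError(ValueError):
    pass


def attention_weights(q: float, K: int) -> np.ndarray:
    """Run-length weights w_0..w_K (geometric, truncated at K)."""
    if not (0.0 <= q <= 1.0):
        raise CovertModelError("q must lie in [0, 1]")
    if K < 1:
        raise CovertModelError("K must be at least 1")
    k = np.arange(K + 1)
    w = (1.0 - q) * q ** k.astype(float)
    w[K] = q ** K
    return w


def _fill_curve(values: np.ndarray) -> np.ndarray:
    """Interpolate interior NaNs linearly; clamp the edges to the nearest
    defined value."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise CovertModelError("attend curve entirely undefined")
    idx = np.arange(v.size)
    return np.interp(idx, idx[ok], v[ok])


def model_switch_curve(
    attend_values: np.ndarray,
    q: float,
    K: int = DEFAULT_K,
    window_s: float = DEFAULT_WINDOW_S,
    n_post: int | None = None,
) -> np.ndarray:
    """Predicted switch-aligned curve on the post-switch triplet grid.

    ``attend_values`` is the attend build-up curve sampled on the 0.5-s
    grid from sequence start (NaN where undefined).  The value at
    post-switch index j is sum_k w_k A[j + k], with A clamped at its last
    defined value beyond its support.
    """
    A = _fill_curve(attend_values)
    w = attention_weights(q, K)
    if n_post is None:
        n_post = A.size
    shift = int(round(window_s / TRIPLET_PERIOD_S))
    if abs(window_s / TRIPLET_PERIOD_S - shift) > 1e-9:
        raise CovertModelError("window_s must be a multiple of the triplet grid")
    idx = np.minimum(
        np.arange(n_post)[None, :] + shift * np.arange(K + 1)[:, None],
        A.size - 1,
    )
    return w @ A[idx]


@dataclass
class QScanResult:
    q_grid: np.ndarray
    significant: np.ndarray      # bool per q: a model-data cluster survived
    max_abs_t: np.ndarray
    n_clusters: np.ndarray
    min_cluster_p: np.ndarray

    @property
    def nonsignificant_q(self) -> np.ndarray:
        return self.q_grid[~self.significant]

    def intervals(self) -> list[tuple[float, float]]:
        """Nonsignificant q values as a union of grid intervals."""
        ok = ~self.significant
        out = []
        i = 0
        while i < ok.size:
            if ok[i]:
                j = i
                while j + 1 < ok.size and ok[j + 1]:
                    j += 1
                out.append((float(self.q_grid[i]), float(self.q_grid[j])))
                i = j + 1
            else:
                i += 1
        if len(out) > 1:
            warnings.warn("nonsignificant q set is not contiguous", stacklevel=2)
        return out


def scan_q(
    subject_attend: np.ndarray,
    subject_switch: np.ndarray,
    q_grid: np.ndarray | None = None,
    K: int = DEFAULT_K,
    alpha: float = 0.05,
    method: str = "rft",
    n_perm: int = 1000,
    seed: int = 0,
    analysis_start: int = 0,
) -> QScanResult:
    """Scan q over a grid, testing modeled vs observed switch curves.

    ``subject_attend`` is (subjects x time-from-start) and
    ``subject_switch`` (subjects x time-from-switch), both on the 0.5-s
    grid.  For each q the mixture is applied to each subject's attend
    curve, the per-subject difference fields are formed, and the SPM
    cluster test is run; q survives if no suprathreshold cluster is
    significant at ``alpha``.  ``analysis_start`` drops the first grid
    points (e.g. 4 for the 2-s convention).
    """
    A = np.asarray(subject_attend, dtype=float)
    S = np.asarray(subject_switch, dtype=float)
    if A.shape[0] != S.shape[0]:
        raise CovertModelError("attend and switch matrices need matching subjects")
    if A.shape[0] < 3:
        raise CovertModelError("at least 3 subjects required for the t field")
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 1001)
    q_grid = np.asarray(q_grid, dtype=float)
    n_post = S.shape[1]
    n_subj = A.shape[0]
    filled = np.stack([_fill_curve(A[i]) for i in range(n_subj)])
    sig = np.zeros(q_grid.size, dtype=bool)
    max_t = np.zeros(q_grid.size)
    n_cl = np.zeros(q_grid.size, dtype=int)
    min_p = np.ones(q_grid.size)
    sl = slice(analysis_start, None)
    # t_crit varies smoothly with resels; cache solves on a rounded key
    tcrit_cache: dict = {}

    def _rft_test(diffs):
        t, df = _spm.paired_t_field(diffs)
        fwhm = _spm.estimate_fwhm(_spm.residual_fields(diffs))
        resels = (t.size - 1) / fwhm
        key = (df, round(resels, 2))
        if key not in tcrit_cache:
            tcrit_cache[key] = _spm.rft_threshold(df, key[1], alpha)
        t_crit = tcrit_cache[key]
        clusters = _spm.cluster_inference(t, t_crit, fwhm, df, alpha, resels)
        return _spm.SPMResult(t, df, fwhm, resels, t_crit, clusters,
                              "rft", alpha)

    for qi, q in enumerate(q_grid):
        modeled = np.stack([
            model_switch_curve(filled[i], q, K=K, n_post=n_post)
            for i in range(n_subj)
        ])
        diffs = (S - modeled)[:, sl]
        # restrict to the largest window where every subject is defined
        defined = ~np.isnan(diffs).any(axis=0)
        diffs = diffs[:, defined]
        if diffs.shape[1] < 3:
            sig[qi] = False
            continue
        try:
            if method == "rft":
                res = _rft_test(diffs)
            else:
                res = signflip_cluster_test(diffs, alpha=alpha,
                                            n_perm=n_perm, seed=seed)
        except SPMError:
            # degenerate fields (e.g. perfect fit): nothing to reject
            sig[qi] = False
            continue
        finite_t = res.t_field[np.isfinite(res.t_field)]
        max_t[qi] = float(np.max(np.abs(finite_t))) if finite_t.size else np.inf
        n_cl[qi] = len(res.clusters)
        if res.clusters:
            min_p[qi] = min(p for *_, p in res.clusters)
        sig[qi] = res.significant
    return QScanResult(q_grid, sig, max_t, n_cl, min_p)
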