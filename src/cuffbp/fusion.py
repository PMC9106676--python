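"""Covariance-intersection fusion of BP estimates weighted by their PI.

For estimates {xi_i, P_i} the fused estimate is

    P_c^{-1} = sum_i w_i / P_i,      xi_c = P_c * sum_i w_i xi_i / P_i,

with non-negative weights summing to one.  The covariance intersection rule
is valid under unknown cross-correlations between estimators.  For scalar
fusion, exact minimization of P_c degenerates to putting all weight on the
lowest-variance input; the default strategy is therefore inverse-variance
weighting, which blends the models, with the degenerate ``min_pc`` vertex
solution available explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Estimate",
    "FusedEstimate",
    "covariance_intersection",
    "fuse_estimates",
    "align_beats",
]


@dataclass
class Estimate:
    """Scalar BP estimate with uncertainty: mean ``xi`` (mmHg) and variance
    proxy ``P`` (mmHg^2) derived from the PI."""

    xi: float
    P: float
    model_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.xi):
            raise ValueError("xi must be finite")
        if not self.P > 0:
            raise ValueError("P must be positive")


@dataclass
class FusedEstimate:
    xi: float
    P: float
    weights: np.ndarray
    model_ids: tuple = ()
    all_outliers: bool = field(default=False)


def covariance_intersection(
    estimates: list[Estimate], strategy: str = "inverse_variance"
) -> FusedEstimate:
    """Fuse scalar estimates by covariance intersection.

    ``inverse_variance``: w_i proportional to 1/P_i.  ``min_pc``: the weight
    vector on the simplex minimizing P_c, which for scalars is the vertex at
    the minimum-variance input (first on ties).
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    xi = np.array([e.xi for e in estimates], dtype=float)
    P = np.array([e.P for e in estimates], dtype=float)
    if not (P > 0).all():
        raise ValueError("all P must be positive")
    n = len(estimates)
    if strategy == "inverse_variance":
        w = (1.0 / P) / np.sum(1.0 / P)
    elif strategy == "min_pc":
        w = np.zeros(n)
        w[int(np.argmin(P))] = 1.0
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    inv_pc = float(np.sum(w / P))
    P_c = 1.0 / inv_pc
    xi_c = P_c * float(np.sum(w * xi / P))
    return FusedEstimate(
        xi=xi_c,
        P=P_c,
        weights=w,
        model_ids=tuple(e.model_id for e in estimates),
    )


def align_beats(times_ref: np.ndarray, times_other: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Nearest-neighbour match of beat times within ``tol`` seconds.

    Returns for each reference beat the index into ``times_other`` or -1.
    Raises if fewer than half the beats match (misaligned series).
    """
    times_ref = np.asarray(times_ref, dtype=float)
    times_other = np.asarray(times_other, dtype=float)
    if times_other.size == 0:
        raise ValueError("empty series cannot be aligned")
    pos = np.searchsorted(times_other, times_ref)
    out = np.full(times_ref.size, -1, dtype=int)
    for i, p in enumerate(pos):
        best, bd = -1, tol
        for j in (p - 1, p):
            if 0 <= j < times_other.size:
                d = abs(times_other[j] - times_ref[i])
                if d <= bd:
                    best, bd = j, d
        out[i] = best
    if (out >= 0).sum() < 0.5 * times_ref.size:
        raise ValueError("beat series misaligned: fewer than half the beats match within tolerance")
    return out


def fuse_estimates(
    est: pd.DataFrame,
    pi: pd.DataFrame,
    strategy: str = "inverse_variance",
    pi_map: str = "variance",
) -> pd.DataFrame:
    """Fuse beat-aligned per-model estimates using their PIs.

    ``est`` and ``pi`` share an index (beats) and columns (models).  Models
    with missing PI (outlier cluster) or missing estimate are excluded per
    beat; P = PI^2 (``pi_map='variance'``) or P = PI (``'sd'``).  If no model
    survives, the fused value falls back to the unweighted mean of the raw
    estimates with ``all_outliers`` set and no PI.
    """
    if not est.columns.equals(pi.columns) or not est.index.equals(pi.index):
        raise ValueError("est and pi must share index and columns")
    if pi_map not in ("variance", "sd"):
        raise ValueError("pi_map must be 'variance' or 'sd'")
    fused = np.full(len(est), np.nan)
    fused_pi = np.full(len(est), np.nan)
    flag = np.zeros(len(est), dtype=bool)
    n_used = np.zeros(len(est), dtype=int)
    E = est.to_numpy(dtype=float)
    S = pi.to_numpy(dtype=float)
    models = list(est.columns)
    for b in range(len(est)):
        ok = np.isfinite(E[b]) & np.isfinite(S[b]) & (S[b] > 0)
        if ok.any():
            P = S[b, ok] ** 2 if pi_map == "variance" else S[b, ok]
            parts = [Estimate(E[b, j], p, m) for j, p, m in zip(np.nonzero(ok)[0], P, np.array(models)[ok])]
            f = covariance_intersection(parts, strategy=strategy)
            fused[b] = f.xi
            fused_pi[b] = np.sqrt(f.P) if pi_map == "variance" else f.P
            n_used[b] = int(ok.sum())
        else:
            raw = E[b][np.isfinite(E[b])]
            if raw.size:
                fused[b] = raw.mean()
            flag[b] = True
    return pd.DataFrame(
        {"fused": fused, "fused_pi": fused_pi, "all_outliers": flag, "n_models": n_used},
        index=est.index,
    )
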