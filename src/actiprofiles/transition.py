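"""Latent transition analysis between two timepoints with fixed profiles.

Children observed at both timepoints contribute a pair of compositions.
The measurement models (the profile sets fitted cross-sectionally at each
timepoint) are held fixed; EM estimates only the initial profile
probabilities ``alpha`` and the row-stochastic transition matrix ``tau``
with ``tau[j, k] = P(profile k at t2 | profile j at t1)``.  Movements are
classified toward lower / same / higher activity using activity rankings
of the profiles at each timepoint and an explicit profile correspondence
for "same" (profiles may be relabelled between timepoints, so identity is
never assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lpa import FitError, ProfileSet, component_loglik

T1_COLS = ["p_mvpa_wd_t1", "p_sed_wd_t1", "p_mvpa_we_t1", "p_sed_we_t1"]
T2_COLS = ["p_mvpa_wd_t2", "p_sed_wd_t2", "p_mvpa_we_t2", "p_sed_we_t2"]


@dataclass
class TransitionModel:
    initial: np.ndarray        # (K1,)
    transition: np.ndarray     # (K1, K2), rows sum to 1
    loglik: float
    n_obs: int
    converged: bool
    posteriors: np.ndarray | None = None   # (N, K1, K2) joint memberships

    @property
    def K1(self) -> int:
        return self.initial.size

    @property
    def K2(self) -> int:
        return self.transition.shape[1]


@dataclass
class MovementSummary:
    frac_lower: float
    frac_same: float
    frac_higher: float


def _pair_arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    Y1 = pairs.loc[:, T1_COLS].to_numpy(dtype=float)
    Y2 = pairs.loc[:, T2_COLS].to_numpy(dtype=float)
    if np.isnan(Y1).any() or np.isnan(Y2).any():
        raise ValueError("transition analysis uses complete pairs only")
    return Y1, Y2


def fit_transition(pairs: pd.DataFrame, profiles_t1: ProfileSet,
                   profiles_t2: ProfileSet, tol: float = 1e-8,
                   max_iter: int = 5000) -> TransitionModel:
    """Estimate initial and transition probabilities by EM.

    The log-likelihood is
    ``sum_i log sum_{j,k} alpha_j tau_jk f_j(y1_i) f_k(y2_i)`` with the
    measurement densities f fixed, so the per-profile log densities are
    precomputed once and each EM iteration is a closed-form reweighting.
    Monotonicity of the log-likelihood is checked every iteration.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs supplied")
    profiles_t1.validate()
    profiles_t2.validate()
    Y1, Y2 = _pair_arrays(pairs)
    N = Y1.shape[0]
    K1, K2 = profiles_t1.K, profiles_t2.K
    all_we = np.ones(N, dtype=bool)
    lf1 = component_loglik(Y1, all_we, profiles_t1)    # (N, K1)
    lf2 = component_loglik(Y2, all_we, profiles_t2)    # (N, K2)

    alpha = np.full(K1, 1.0 / K1)
    tau = np.full((K1, K2), 1.0 / K2)
    ll = -np.inf
    converged = False
    W = None
    for it in range(1, max_iter + 1):
        # E-step: joint posterior over (j, k)
        logw = (np.log(np.maximum(alpha, 1e-300))[None, :, None]
                + np.log(np.maximum(tau, 1e-300))[None, :, :]
                + lf1[:, :, None] + lf2[:, None, :])
        m = logw.max(axis=(1, 2), keepdims=True)
        w = np.exp(logw - m)
        tot = w.sum(axis=(1, 2), keepdims=True)
        ll_new = float((m.ravel() + np.log(tot.ravel())).sum())
        W = w / tot
        if ll_new < ll - 1e-8 * (1.0 + abs(ll)):
            raise FitError(f"transition EM log-likelihood decreased at {it}")
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll_new)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
        # M-step
        alpha = W.sum(axis=(0, 2)) / N
        alpha = np.maximum(alpha, 1e-12)
        alpha /= alpha.sum()
        num = W.sum(axis=0)
        tau = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-300)
        tau = np.maximum(tau, 0.0)
        tau /= tau.sum(axis=1, keepdims=True)
    return TransitionModel(initial=alpha, transition=tau, loglik=ll,
                           n_obs=N, converged=converged, posteriors=W)


def movement_summary(model: TransitionModel, rank_t1, rank_t2,
                     same_map: dict[int, int] | None = None,
                     mode: str = "expected") -> MovementSummary:
    """Fractions of children moving to lower / same / higher activity.

    ``rank_t1``/``rank_t2`` rank every profile by activity (1 = most
    active).  "Same" requires matched profile identity across timepoints
    via ``same_map`` (t1 index -> corresponding t2 index; default the
    identity map when K1 == K2); transitions to a non-corresponding profile
    are classified by rank.  ``mode="expected"`` uses the model-implied
    flows ``alpha_j * tau_jk``; ``mode="posterior"`` averages each child's
    joint posterior membership.
    """
    K1, K2 = model.K1, model.K2
    rank_t1 = np.asarray(rank_t1)
    rank_t2 = np.asarray(rank_t2)
    if rank_t1.size != K1 or rank_t2.size != K2:
        raise ValueError("need one rank per profile at each timepoint")
    if same_map is None:
        if K1 != K2:
            raise ValueError("same_map required when profile counts differ")
        same_map = {j: j for j in range(K1)}
    for j in range(K1):
        if j not in same_map:
            raise ValueError(f"no t2 correspondence for t1 profile {j}")

    if mode == "expected":
        flow = model.initial[:, None] * model.transition
    elif mode == "posterior":
        if model.posteriors is None:
            raise ValueError("model carries no posteriors")
        flow = model.posteriors.mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flow = flow / flow.sum()

    lower = same = higher = 0.0
    for j in range(K1):
        for k in range(K2):
            if same_map[j] == k:
                same += flow[j, k]
            elif rank_t2[k] > rank_t1[j]:     # larger rank = less active
                lower += flow[j, k]
            elif rank_t2[k] < rank_t1[j]:
                higher += flow[j, k]
            else:   # equal rank but not the corresponding profile
                same += flow[j, k]
    return MovementSummary(frac_lower=float(lower), frac_same=float(same),
                           frac_higher=float(higher))
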