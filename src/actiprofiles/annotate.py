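"""Profile annotation: guideline probabilities, activity ordering, and
BCH-weighted covariate comparisons.

The expected share of a profile meeting the 60-minutes-of-MVPA-per-day
guideline treats a child's guideline-weighted MVPA proportion
``P = (5 M_wd + 2 M_we) / 7`` as normal within a profile (mean
``(5 mu_Mwd + 2 mu_Mwe) / 7``, variance ``(25 + 4)/49 * s2_M`` by
cross-day-type independence) and evaluates ``P(P >= 60 / wear)`` at the
cohort's average daily wear time.  Profiles are canonically ordered by
descending guideline probability.

Covariate differences between profiles use the BCH three-step method:
children are weighted by the inverse of the modal-classification error
matrix so that per-profile covariate means are unbiased despite imperfect
class separation, and equality across profiles is tested with a Wald
statistic using a child-level sandwich variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lpa import DAY_TYPE_WEIGHTS, LPAFit, ProfileSet


@dataclass
class GuidelineEstimate:
    profile: int
    label: str | None
    prob_meeting: float


@dataclass
class BCHResult:
    covariate: str
    estimates: np.ndarray      # per-profile weighted mean / proportion
    wald_stat: float
    df: int
    p: float


def guideline_probability(profiles: ProfileSet, mean_wear: float,
                          guideline_min: float = 60.0
                          ) -> list[GuidelineEstimate]:
    """Expected proportion of each profile meeting the activity guideline.

    ``mean_wear`` is the cohort's average daily wear time in minutes; the
    child-level threshold on the weighted MVPA proportion is
    ``guideline_min / mean_wear``.  A zero-variance profile yields the
    degenerate 0/1 step.
    """
    if mean_wear <= 0:
        raise ValueError("mean_wear must be positive")
    w_wd, w_we = DAY_TYPE_WEIGHTS
    thr = guideline_min / mean_wear
    out = []
    for k in range(profiles.K):
        mean = w_wd * profiles.mu[k, 0] + w_we * profiles.mu[k, 2]
        var = (w_wd**2 + w_we**2) * profiles.var_m[k]
        if var <= 0:
            prob = 1.0 if mean >= thr else 0.0
        else:
            prob = float(stats.norm.sf((thr - mean) / np.sqrt(var)))
        label = profiles.labels[k] if profiles.labels else None
        out.append(GuidelineEstimate(profile=k, label=label,
                                     prob_meeting=prob))
    return out


def canonical_order(profiles: ProfileSet,
                    guideline: list[GuidelineEstimate]) -> np.ndarray:
    """Profile indices ordered most to least active.

    Descending guideline probability; ties broken by guideline-weighted
    MVPA mean, then by index.
    """
    if len(guideline) != profiles.K:
        raise ValueError("need one guideline estimate per profile")
    probs = np.array([g.prob_meeting for g in guideline])
    mvpa = profiles.weighted_mvpa_mean()
    return np.lexsort((np.arange(profiles.K), -mvpa, -probs))


def bch_weights(posteriors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-child BCH weights from posterior membership probabilities.

    The classification matrix D has entries
    ``d_jt = sum_i p_ij 1[modal_i = t] / sum_i p_ij`` (probability that a
    child truly in profile j is modally assigned to t).  Weights are rows
    of ``H = D^{-1}`` indexed by each child's modal class; rows of H sum to
    one because D is row-stochastic.  Raises if D is (near) singular,
    which signals entropy too low for the BCH correction.
    """
    P = np.asarray(posteriors, dtype=float)
    N, K = P.shape
    modal = np.argmax(P, axis=1)
    ind = np.zeros((N, K))
    ind[np.arange(N), modal] = 1.0
    D = P.T @ ind
    D /= np.maximum(P.sum(axis=0)[:, None], 1e-300)
    if np.linalg.cond(D) > 1e8:
        raise ValueError(
            "classification matrix is singular or near-singular: profile "
            "separation (entropy) is too low for the BCH correction")
    H = np.linalg.inv(D)
    return H[modal], modal


def bch_test(fit: LPAFit | np.ndarray, covariate) -> BCHResult:
    """BCH-weighted per-profile covariate means with a Wald equality test.

    ``fit`` may be an :class:`LPAFit` or a raw posterior matrix.
    ``covariate`` is a length-N vector (binary indicators give weighted
    proportions); children with a missing value are dropped.  The Wald
    statistic tests equality of the K per-profile means with a child-level
    sandwich variance and K-1 degrees of freedom.
    """
    P = fit.posteriors if isinstance(fit, LPAFit) else np.asarray(fit)
    y = np.asarray(covariate, dtype=float)
    if y.size != P.shape[0]:
        raise ValueError("covariate length must match the fitted sample")
    keep = ~np.isnan(y)
    P = P[keep]
    y = y[keep]
    K = P.shape[1]
    W, modal = bch_weights(P)
    if len(set(modal.tolist())) < K:
        raise ValueError("a profile has no modally assigned children with "
                         "observed covariate values")
    Wk = W.sum(axis=0)
    est = (W * y[:, None]).sum(axis=0) / Wk
    # sandwich: theta_k solves sum_i w_ik (y_i - theta_k) = 0
    U = W * (y[:, None] - est[None, :])
    S = U.T @ U
    V = S / np.outer(Wk, Wk)
    C = np.hstack([np.eye(K - 1), -np.ones((K - 1, 1))])
    diff = C @ est
    cvc = C @ V @ C.T
    try:
        stat = float(diff @ np.linalg.solve(cvc, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(cvc) @ diff)
    stat = max(stat, 0.0)
    name = getattr(covariate, "name", None) or "covariate"
    return BCHResult(covariate=str(name), estimates=est, wald_stat=stat,
                     df=K - 1, p=float(stats.chi2.sf(stat, K - 1)))


def annotate_fit(fit: LPAFit, mean_wear: float,
                 covariates: pd.DataFrame | None = None,
                 labels: list[str] | None = None) -> dict:
    """Full annotation of a fitted model: guideline probabilities, canonical
    order (applied), optional BCH comparisons for each covariate column.

    Returns a dict with the reordered profiles, per-profile guideline
    probabilities, and a tidy BCH frame shaped one row per profile per
    covariate plus a Wald p-value per covariate.
    """
    est = guideline_probability(fit.profiles, mean_wear)
    order = canonical_order(fit.profiles, est)
    profiles = fit.profiles.reorder(order)
    if labels is not None:
        profiles.labels = list(labels)
    probs = np.array([est[i].prob_meeting for i in order])
    posteriors = fit.posteriors[:, order]
    result = {
        "profiles": profiles,
        "order": order,
        "guideline_prob": probs,
        "mixing": profiles.mixing,
        "bch": None,
    }
    if covariates is not None:
        rows = []
        reordered_fit = LPAFit(profiles=profiles, loglik=fit.loglik,
                               posteriors=posteriors, n_obs=fit.n_obs,
                               converged=fit.converged)
        for col in covariates.columns:
            res = bch_test(reordered_fit, covariates[col])
            for k in range(profiles.K):
                rows.append({
                    "covariate": col, "profile": k,
                    "label": profiles.labels[k] if profiles.labels else None,
                    "estimate": res.estimates[k],
                    "wald_stat": res.wald_stat, "df": res.df, "p": res.p,
                })
        result["bch"] = pd.DataFrame(rows)
    return result
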