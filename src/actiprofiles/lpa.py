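"""Constrained latent profile analysis of 4-dimensional activity compositions.

The observed vector for a child is ``y = (M_wd, S_wd, M_we, S_we)``: the
proportions of accelerometer wear time spent in MVPA (M) and sedentary
behaviour (S) on weekdays (wd) and weekend days (we); light activity is the
simplex remainder and is not modelled directly.  A K-profile model is a
Gaussian mixture in which profile k has

* a free 4-vector of means ``mu_k``,
* a 2x2 covariance block ``B_k = [[s2M_k, c_k], [c_k, s2S_k]]`` shared by
  the weekday and weekend day-type blocks (variances equal across day types
  within a profile, free to differ between behaviours and between
  profiles), and
* zero covariance across day types given the profile (local independence).

Children with the weekend block missing as a whole contribute through the
marginal (weekday-block) density — full-information maximum likelihood
under a missing-at-random assumption.  Estimation is by EM with closed-form
constrained M-steps, k-means-based multistart, and a canonical profile
ordering (descending guideline-weighted MVPA mean) to resolve label
switching.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: columns holding the composition indicators, in model order
INDICATOR_COLS = ["p_mvpa_wd", "p_sed_wd", "p_mvpa_we", "p_sed_we"]

#: weekday/weekend weights used for "average day" quantities (5 weekdays,
#: 2 weekend days per week)
DAY_TYPE_WEIGHTS = (5.0 / 7.0, 2.0 / 7.0)

LOG_2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Raised when estimation fails (collapse, non-PD block, no valid start)."""


@dataclass
class ProfileSet:
    """Parameters of a K-profile constrained mixture.

    Attributes
    ----------
    mu : (K, 4) array
        Profile means, columns ``(M_wd, S_wd, M_we, S_we)``.
    var_m, var_s : (K,) arrays
        MVPA and sedentary variances, shared across day types.
    cov : (K,) array
        Within-day-type MVPA-sedentary covariance.
    mixing : (K,) array
        Mixing proportions, summing to one.
    labels : list of str, optional
        Descriptive profile names.
    """

    mu: np.ndarray
    var_m: np.ndarray
    var_s: np.ndarray
    cov: np.ndarray
    mixing: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.var_m = np.atleast_1d(np.asarray(self.var_m, dtype=float))
        self.var_s = np.atleast_1d(np.asarray(self.var_s, dtype=float))
        self.cov = np.atleast_1d(np.asarray(self.cov, dtype=float))
        self.mixing = np.atleast_1d(np.asarray(self.mixing, dtype=float))

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def n_free_params(self) -> int:
        """4 means + 2 variances + 1 covariance per profile, K-1 mixing."""
        return 7 * self.K + (self.K - 1)

    def validate(self) -> None:
        if self.mu.shape != (self.K, 4):
            raise ValueError("mu must be (K, 4)")
        if not np.isclose(self.mixing.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.mixing <= 0):
            raise ValueError("mixing proportions must be positive")
        bad = ~(self.cov**2 < self.var_m * self.var_s)
        bad |= (self.var_m <= 0) | (self.var_s <= 0)
        if np.any(bad):
            k = int(np.flatnonzero(bad)[0])
            raise FitError(
                f"profile {k} has a non-positive-definite day-type block "
                f"(var_m={self.var_m[k]:.3g}, var_s={self.var_s[k]:.3g}, "
                f"cov={self.cov[k]:.3g})"
            )

    def weighted_mvpa_mean(self) -> np.ndarray:
        """Guideline-weighted MVPA mean per profile, (5*M_wd + 2*M_we)/7."""
        w_wd, w_we = DAY_TYPE_WEIGHTS
        return w_wd * self.mu[:, 0] + w_we * self.mu[:, 2]

    def reorder(self, order: np.ndarray | list[int]) -> "ProfileSet":
        order = np.asarray(order)
        return ProfileSet(
            mu=self.mu[order],
            var_m=self.var_m[order],
            var_s=self.var_s[order],
            cov=self.cov[order],
            mixing=self.mixing[order],
            labels=[self.labels[i] for i in order] if self.labels else None,
        )

    def canonical_order(self) -> np.ndarray:
        """Profile order by descending weighted MVPA mean (ties: by index)."""
        m = self.weighted_mvpa_mean()
        return np.lexsort((np.arange(self.K), -m))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mu": self.mu.tolist(),
            "var_m": self.var_m.tolist(),
            "var_s": self.var_s.tolist(),
            "cov": self.cov.tolist(),
            "mixing": self.mixing.tolist(),
            "labels": self.labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileSet":
        return cls(
            mu=np.array(d["mu"]), var_m=np.array(d["var_m"]),
            var_s=np.array(d["var_s"]), cov=np.array(d["cov"]),
            mixing=np.array(d["mixing"]), labels=d.get("labels"),
        )


@dataclass
class LPAFit:
    """Result of a (multistart) EM fit."""

    profiles: ProfileSet
    loglik: float
    posteriors: np.ndarray
    n_obs: int
    converged: bool
    n_iter: int = 0
    starts_used: int = 1
    best_ll_replicated: bool = False
    start_logliks: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.profiles.n_free_params

    def modal(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)

    def to_json(self, path, seed: int | None = None) -> None:
        payload = {
            "profiles": self.profiles.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "starts_used": self.starts_used,
            "best_ll_replicated": self.best_ll_replicated,
            "seed": seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# data ingestion
# ---------------------------------------------------------------------------

def as_arrays(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (N, 4) indicator matrix and weekend-present mask.

    Rows must have the weekday block complete.  The weekend block must be
    missing jointly or present jointly; rows with any other missingness
    pattern are rejected (dropped with a logged count), matching the
    dominant observed pattern of insufficient weekend wear.
    """
    Y = data.loc[:, INDICATOR_COLS].to_numpy(dtype=float)
    wd_ok = ~np.isnan(Y[:, :2]).any(axis=1)
    we_nan = np.isnan(Y[:, 2:])
    coherent = we_nan.all(axis=1) | (~we_nan).all(axis=1)
    keep = wd_ok & coherent
    if not keep.all():
        logger.warning(
            "rejected %d rows with unsupported missingness patterns",
            int((~keep).sum()),
        )
        Y = Y[keep]
    we_present = ~np.isnan(Y[:, 2]).astype(bool)
    if Y.shape[0] == 0:
        raise ValueError("no usable rows: weekday block must be observed")
    return Y, we_present


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _block_logpdf(dm: np.ndarray, ds: np.ndarray, vm: float, vs: float,
                  c: float) -> np.ndarray:
    """Log density of a centred bivariate normal [[vm, c], [c, vs]]."""
    det = vm * vs - c * c
    if det <= 0 or vm <= 0:
        raise FitError("non-positive-definite day-type block")
    quad = (vs * dm * dm - 2.0 * c * dm * ds + vm * ds * ds) / det
    return -LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def component_loglik(Y: np.ndarray, we_present: np.ndarray,
                     profiles: ProfileSet) -> np.ndarray:
    """(N, K) matrix of per-profile log densities log f_k(y_i).

    Children without a weekend block contribute the weekday-block marginal
    only (FIML).
    """
    N = Y.shape[0]
    K = profiles.K
    out = np.empty((N, K))
    for k in range(K):
        vm, vs, c = profiles.var_m[k], profiles.var_s[k], profiles.cov[k]
        lp = _block_logpdf(Y[:, 0] - profiles.mu[k, 0],
                           Y[:, 1] - profiles.mu[k, 1], vm, vs, c)
        if we_present.any():
            lp = lp.copy()
            lp[we_present] += _block_logpdf(
                Y[we_present, 2] - profiles.mu[k, 2],
                Y[we_present, 3] - profiles.mu[k, 3], vm, vs, c)
        out[:, k] = lp
    return out


def loglik_child(comp, profiles: ProfileSet) -> float:
    """Log mixture density of a single child's composition.

    ``comp`` may be a mapping / Series with the indicator columns or a
    length-4 sequence ``(M_wd, S_wd, M_we, S_we)``; NaN weekend entries mark
    a missing weekend block.
    """
    if hasattr(comp, "get") or isinstance(comp, pd.Series):
        y = np.array([comp[c] for c in INDICATOR_COLS], dtype=float)
    else:
        y = np.asarray(comp, dtype=float)
    if np.isnan(y[:2]).any():
        raise ValueError("weekday block must be observed")
    df = pd.DataFrame([y], columns=INDICATOR_COLS)
    Y, we = as_arrays(df)
    lk = component_loglik(Y, we, profiles) + np.log(profiles.mixing)
    return float(_logsumexp_rows(lk)[0])


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))).ravel()


def posterior_probs(Y: np.ndarray, we_present: np.ndarray,
                    profiles: ProfileSet) -> tuple[np.ndarray, float]:
    """E-step: posterior membership probabilities and total log-likelihood."""
    lk = component_loglik(Y, we_present, profiles) + np.log(profiles.mixing)
    ll_rows = _logsumexp_rows(lk)
    P = np.exp(lk - ll_rows[:, None])
    P /= P.sum(axis=1, keepdims=True)
    return P, float(ll_rows.sum())


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _m_step(Y: np.ndarray, we_present: np.ndarray, P: np.ndarray,
            old: ProfileSet, pi_floor: float) -> ProfileSet:
    """Closed-form constrained M-step with FIML handling of missing weekends.

    For rows without a weekend block the conditional expectations given the
    weekday block reduce (by cross-day-type independence) to the current
    weekend means and covariance block, which enter the sufficient
    statistics in the standard EM-for-missing-data form.
    """
    N, K = P.shape
    W = P.sum(axis=0)
    if np.any(W / N < pi_floor):
        raise FitError("component collapse: mixing proportion below floor")
    mixing = W / N

    obs = we_present
    mis = ~we_present
    mu = np.empty((K, 4))
    var_m = np.empty(K)
    var_s = np.empty(K)
    cov = np.empty(K)
    for k in range(K):
        w = P[:, k]
        Wk = W[k]
        mu[k, 0] = w @ Y[:, 0] / Wk
        mu[k, 1] = w @ Y[:, 1] / Wk
        w_obs = w[obs]
        W_mis = w[mis].sum()
        # weekend means: observed values plus current-mean imputations
        for j, col in ((2, 2), (3, 3)):
            tot = (w_obs @ Y[obs, col]) + W_mis * old.mu[k, j]
            mu[k, j] = tot / Wk
        # pooled 2x2 scatter across the two day-type blocks
        dm_wd = Y[:, 0] - mu[k, 0]
        ds_wd = Y[:, 1] - mu[k, 1]
        smm = w @ (dm_wd * dm_wd)
        sss = w @ (ds_wd * ds_wd)
        sms = w @ (dm_wd * ds_wd)
        dm_we = Y[obs, 2] - mu[k, 2]
        ds_we = Y[obs, 3] - mu[k, 3]
        smm += w_obs @ (dm_we * dm_we)
        sss += w_obs @ (ds_we * ds_we)
        sms += w_obs @ (dm_we * ds_we)
        # missing weekend rows: E[(y - mu_new)(y - mu_new)'] =
        #   B_old + (mu_old - mu_new)(mu_old - mu_new)'
        dmu_m = old.mu[k, 2] - mu[k, 2]
        dmu_s = old.mu[k, 3] - mu[k, 3]
        smm += W_mis * (old.var_m[k] + dmu_m * dmu_m)
        sss += W_mis * (old.var_s[k] + dmu_s * dmu_s)
        sms += W_mis * (old.cov[k] + dmu_m * dmu_s)
        var_m[k] = smm / (2.0 * Wk)
        var_s[k] = sss / (2.0 * Wk)
        cov[k] = sms / (2.0 * Wk)
    new = ProfileSet(mu=mu, var_m=var_m, var_s=var_s, cov=cov, mixing=mixing)
    new.validate()
    return new


def fit_em(data: pd.DataFrame | tuple, K: int, init: ProfileSet,
           tol: float = 1e-6, max_iter: int = 1000,
           update_measurement: bool = True) -> LPAFit:
    """Run EM from a given initialisation.

    Parameters
    ----------
    data : DataFrame with the indicator columns, or a pre-built (Y, mask)
        pair from :func:`as_arrays`.
    K : number of profiles (must match ``init``).
    init : starting :class:`ProfileSet`.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap.
    update_measurement : if False, means/variances/covariances stay fixed
        and only the mixing proportions are estimated (used when fitting
        with a profile structure carried over from another sample).

    The log-likelihood is checked to be non-decreasing at every iteration.
    """
    if isinstance(data, tuple):
        Y, we_present = data
    else:
        Y, we_present = as_arrays(data)
    N = Y.shape[0]
    if N <= K:
        raise ValueError("need more observations than profiles")
    if init.K != K:
        raise ValueError("init has wrong number of profiles")
    pi_floor = 1.0 / (2.0 * N)

    profiles = init
    profiles.validate()
    P, ll = posterior_probs(Y, we_present, profiles)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if update_measurement:
            profiles = _m_step(Y, we_present, P, profiles, pi_floor)
        else:
            mixing = P.mean(axis=0)
            if np.any(mixing < pi_floor):
                mixing = np.maximum(mixing, pi_floor)
                mixing /= mixing.sum()
            profiles = replace(profiles, mixing=mixing)
        P, ll_new = posterior_probs(Y, we_present, profiles)
        if ll_new < ll - 1e-8 * (1.0 + abs(ll)):
            raise FitError(
                f"log-likelihood decreased at iteration {it}: {ll} -> {ll_new}"
            )
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return LPAFit(profiles=profiles, loglik=ll, posteriors=P, n_obs=N,
                  converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# initialisation and multistart
# ---------------------------------------------------------------------------

def _init_from_assignment(Y: np.ndarray, we_present: np.ndarray,
                          assign: np.ndarray, K: int,
                          rng: np.random.Generator,
                          jitter: float = 0.0) -> ProfileSet:
    """Build a ProfileSet from a hard assignment of rows to K clusters."""
    N = Y.shape[0]
    mu = np.empty((K, 4))
    counts = np.empty(K)
    # global fallbacks for empty clusters / all-missing weekends
    gmu_wd = Y[:, :2].mean(axis=0)
    gmu_we = (np.nanmean(Y[:, 2:], axis=0) if we_present.any() else gmu_wd)
    for k in range(K):
        idx = assign == k
        counts[k] = idx.sum()
        if counts[k] == 0:
            mu[k, :2] = gmu_wd + rng.normal(0, 0.02, 2)
            mu[k, 2:] = gmu_we + rng.normal(0, 0.02, 2)
            counts[k] = 1.0
            continue
        mu[k, :2] = Y[idx, :2].mean(axis=0)
        both = idx & we_present
        mu[k, 2:] = Y[both, 2:].mean(axis=0) if both.any() else mu[k, :2]
    # pooled within-cluster residual moments, shared across day types
    dm = Y[:, 0] - mu[assign, 0]
    ds = Y[:, 1] - mu[assign, 1]
    vm = float(np.mean(dm * dm))
    vs = float(np.mean(ds * ds))
    cms = float(np.mean(dm * ds))
    vm = max(vm, 1e-6)
    vs = max(vs, 1e-6)
    cms = float(np.clip(cms, -0.8 * np.sqrt(vm * vs), 0.8 * np.sqrt(vm * vs)))
    if jitter > 0:
        mu = mu + rng.normal(0.0, jitter * np.sqrt([vm, vs, vm, vs]), mu.shape)
    mixing = np.maximum(counts / counts.sum(), 1.0 / (2.0 * N))
    mixing /= mixing.sum()
    return ProfileSet(mu=mu, var_m=np.full(K, vm), var_s=np.full(K, vs),
                      cov=np.full(K, cms), mixing=mixing)


def make_start(Y: np.ndarray, we_present: np.ndarray, K: int,
               rng: np.random.Generator, kind: str = "kmeans",
               jitter: float = 0.0) -> ProfileSet:
    """One multistart initialisation: jittered k-means or random assignment."""
    Z = Y.copy()
    if we_present.any():
        col_means = np.nanmean(Z[:, 2:], axis=0)
    else:
        col_means = Z[:, :2].mean(axis=0)
    for j in (2, 3):
        Z[np.isnan(Z[:, j]), j] = col_means[j - 2]
    if kind == "kmeans":
        # standardise columns so sedentary's larger scale does not dominate
        Zs = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        assign = km.fit_predict(Zs)
    else:
        assign = rng.integers(0, K, Y.shape[0])
    return _init_from_assignment(Y, we_present, assign, K, rng, jitter=jitter)


def multistart_fit(data: pd.DataFrame | tuple, K: int, n_starts: int = 50,
                   seed: int | None = None, tol: float = 1e-6,
                   max_iter: int = 1000,
                   replication_tol: float = 1e-4) -> LPAFit:
    """Fit by EM from many initialisations and keep the best log-likelihood.

    The first start is plain k-means; subsequent starts alternate jittered
    k-means and random assignments.  ``best_ll_replicated`` records whether
    at least two starts reached the best log-likelihood within
    ``replication_tol`` — the standard check that the reported maximum is
    not a one-off local optimum.  Profiles are returned in canonical order
    (descending guideline-weighted MVPA mean).
    """
    if n_starts < 2:
        raise ValueError("n_starts must be at least 2")
    if isinstance(data, tuple):
        Y, we_present = data
    else:
        Y, we_present = as_arrays(data)
    rng = np.random.default_rng(seed)
    best: LPAFit | None = None
    lls: list[float] = []
    failures: list[str] = []
    for s in range(n_starts):
        kind = "kmeans" if (s == 0 or s % 3 != 0) else "random"
        jitter = 0.0 if s == 0 else 0.5
        try:
            init = make_start(Y, we_present, K, rng, kind=kind, jitter=jitter)
            fit = fit_em((Y, we_present), K, init, tol=tol, max_iter=max_iter)
        except (FitError, ValueError) as exc:   # collapsed start
            failures.append(f"start {s}: {exc}")
            continue
        lls.append(fit.loglik)
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError("all starts failed: " + "; ".join(failures[:5]))
    n_at_best = sum(1 for v in lls if v >= best.loglik - replication_tol)
    order = best.profiles.canonical_order()
    best.profiles = best.profiles.reorder(order)
    best.posteriors = best.posteriors[:, order]
    best.starts_used = n_starts
    best.best_ll_replicated = n_at_best >= 2
    best.start_logliks = lls
    if not best.best_ll_replicated:
        logger.info("best log-likelihood reached by a single start only")
    return best


def fit_with_fixed_profiles(data: pd.DataFrame | tuple, profiles: ProfileSet,
                            tol: float = 1e-8,
                            max_iter: int = 2000) -> LPAFit:
    """Estimate mixing proportions (and posteriors) with the measurement
    model fixed — the carried-over-profile analysis used when a sample is
    scored against profiles estimated elsewhere."""
    profiles.validate()
    init = replace(profiles, mixing=np.full(profiles.K, 1.0 / profiles.K))
    return fit_em(data, profiles.K, init, tol=tol, max_iter=max_iter,
                  update_measurement=False)


def posteriors_to_frame(fit: LPAFit, ids=None) -> pd.DataFrame:
    cols = [f"p_profile_{k + 1}" for k in range(fit.profiles.K)]
    df = pd.DataFrame(fit.posteriors, columns=cols)
    if ids is not None:
        df.insert(0, "child_id", np.asarray(ids))
    df["modal"] = fit.modal()
    return df
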