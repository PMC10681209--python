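"""Model-fit battery for choosing the number of profiles.

For each candidate K the battery reports the Bayesian Information Criterion
(BIC) and its sample-size-adjusted variant (saBIC; lower is better for
both), the normalised classification entropy (higher means better-separated
profiles), an adjusted Lo-Mendell-Rubin likelihood-ratio approximation
(advisory — an analytic approximation whose null is only approximate), a
parametric bootstrapped likelihood-ratio test (BLRT) of K-1 vs K profiles,
and the smallest modal class share.  Statistical criteria inform but do not
decide the choice: interpretability and avoidance of tiny classes carry
weight in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lpa import LPAFit, FitError, as_arrays, multistart_fit

logger = logging.getLogger(__name__)


@dataclass
class FitIndices:
    K: int
    loglik: float
    bic: float
    sabic: float
    entropy: float | None
    almr_p: float | None
    blrt_p: float | None
    smallest_class: float
    note: str = ""


def bic(fit: LPAFit) -> float:
    """-2*loglik + n_params*ln(N)."""
    return -2.0 * fit.loglik + fit.n_params * np.log(fit.n_obs)


def sabic(fit: LPAFit) -> float:
    """BIC with ln(N) replaced by ln((N + 2) / 24)."""
    return -2.0 * fit.loglik + fit.n_params * np.log((fit.n_obs + 2) / 24.0)


def entropy(fit: LPAFit) -> float:
    """Normalised classification entropy, 1 - sum(-p log p) / (N ln K).

    1 means perfectly separated (degenerate) posteriors, 0 means uniform
    posteriors.  Undefined for a single profile.
    """
    K = fit.profiles.K
    if K < 2:
        raise ValueError("entropy is undefined for K=1")
    P = np.clip(fit.posteriors, 1e-300, 1.0)
    H = float(-(P * np.log(P)).sum())
    return 1.0 - H / (fit.n_obs * np.log(K))


def almr(fit_k: LPAFit, fit_km1: LPAFit, adjusted: bool = True
         ) -> float | None:
    """Adjusted Lo-Mendell-Rubin-style likelihood-ratio approximation.

    Scales the likelihood-ratio statistic 2*(LL_K - LL_{K-1}) by
    ``1 / (1 + 1/(d ln N))`` with d the difference in free parameters, and
    refers it to a chi-square with d degrees of freedom.  This is an
    analytic approximation to a non-standard null distribution and is
    reported as advisory; ``adjusted=False`` skips the scaling.  Returns
    None when the approximation's conditions fail (non-positive LR or
    degenerate d), mirroring a "no convergence" entry.
    """
    if fit_k.profiles.K != fit_km1.profiles.K + 1:
        raise ValueError("fits must differ by exactly one profile")
    if fit_k.n_obs != fit_km1.n_obs:
        raise ValueError("fits must be on the same data")
    lr = 2.0 * (fit_k.loglik - fit_km1.loglik)
    d = fit_k.n_params - fit_km1.n_params
    if d <= 0:
        return None
    if lr < 0:
        return None
    if adjusted:
        lr = lr / (1.0 + 1.0 / (d * np.log(fit_k.n_obs)))
    return float(stats.chi2.sf(lr, d))


def blrt(data: pd.DataFrame | tuple, K: int, n_boot: int = 100,
         seed: int | None = None, n_starts: int = 10,
         n_starts_boot: int = 4, max_redraws: int = 20,
         fit_k: LPAFit | None = None, fit_km1: LPAFit | None = None
         ) -> float:
    """Parametric bootstrapped likelihood-ratio test of K-1 vs K profiles.

    The observed statistic is 2*(LL_K - LL_{K-1}).  Bootstrap replicates
    are drawn from the fitted (K-1)-profile model at the observed sample
    size and weekend-missingness rate, both models are refitted with a
    reduced multistart, and the p-value is
    ``(1 + #{LR_b >= LR_obs}) / (n_boot + 1)``.  Failed replicate fits are
    redrawn up to ``max_redraws`` times in total.
    """
    from .synth import sample_compositions   # local import: cycle avoidance

    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if K < 2:
        raise ValueError("K must be at least 2")
    Y, we = as_arrays(data) if not isinstance(data, tuple) else data
    rng = np.random.default_rng(seed)
    ss = lambda: int(rng.integers(2**31 - 1))
    if fit_km1 is None:
        fit_km1 = multistart_fit((Y, we), K - 1, n_starts=max(n_starts, 2),
                                 seed=ss())
    if fit_k is None:
        fit_k = multistart_fit((Y, we), K, n_starts=max(n_starts, 2),
                               seed=ss())
    lr_obs = 2.0 * (fit_k.loglik - fit_km1.loglik)
    miss_rate = float(1.0 - we.mean())
    n = Y.shape[0]

    lr_boot = []
    redraws = 0
    while len(lr_boot) < n_boot:
        frame, _ = sample_compositions(fit_km1.profiles, n, rng,
                                       weekend_missing_rate=miss_rate)
        try:
            b_km1 = multistart_fit(frame, K - 1,
                                   n_starts=max(n_starts_boot, 2), seed=ss())
            b_k = multistart_fit(frame, K,
                                 n_starts=max(n_starts_boot, 2), seed=ss())
        except FitError as exc:
            redraws += 1
            if redraws > max_redraws:
                raise FitError(
                    f"bootstrap fit failures exhausted redraw budget: {exc}")
            logger.info("bootstrap replicate redrawn: %s", exc)
            continue
        lr_boot.append(2.0 * (b_k.loglik - b_km1.loglik))
    lr_boot = np.array(lr_boot)
    return float((1 + (lr_boot >= lr_obs).sum()) / (n_boot + 1))


def selection_table(data: pd.DataFrame, k_range=range(2, 11),
                    n_starts: int = 50, n_boot: int = 100,
                    seed: int | None = None,
                    run_blrt: bool = True) -> pd.DataFrame:
    """Fit indices for each K in ``k_range`` as a tidy comparison table.

    Per-K failures are propagated as annotated rows rather than aborting
    the whole ladder.  Deterministic given ``seed``.
    """
    Y, we = as_arrays(data)
    rng = np.random.default_rng(seed)
    rows: list[FitIndices] = []
    fits: dict[int, LPAFit] = {}
    k_list = sorted(set(k_range))
    for K in [k_list[0] - 1] + k_list if k_list[0] > 1 else k_list:
        try:
            fits[K] = multistart_fit((Y, we), K, n_starts=max(n_starts, 2),
                                     seed=int(rng.integers(2**31 - 1)))
        except (FitError, ValueError) as exc:
            if K in k_list:
                rows.append(FitIndices(K, np.nan, np.nan, np.nan, None, None,
                                       None, np.nan, note=str(exc)))
    for K in k_list:
        if K not in fits:
            continue
        fit = fits[K]
        modal_share = np.bincount(fit.modal(), minlength=K) / fit.n_obs
        almr_p = (almr(fit, fits[K - 1]) if (K - 1) in fits else None)
        blrt_p = None
        if run_blrt and (K - 1) in fits:
            blrt_p = blrt((Y, we), K, n_boot=n_boot,
                          seed=int(rng.integers(2**31 - 1)),
                          fit_k=fit, fit_km1=fits[K - 1])
        rows.append(FitIndices(
            K=K, loglik=fit.loglik, bic=bic(fit), sabic=sabic(fit),
            entropy=entropy(fit) if K >= 2 else None,
            almr_p=almr_p, blrt_p=blrt_p,
            smallest_class=float(modal_share.min()),
            note="" if fit.best_ll_replicated else "best LL not replicated",
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
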