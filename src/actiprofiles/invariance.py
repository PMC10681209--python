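"""Multiple-group latent profile models and measurement-invariance tests.

A multigroup model assigns each group (e.g. survey waves of the same age
band) a measurement model — a :class:`~actiprofiles.lpa.ProfileSet` either
fixed in advance, shared with other groups, or free — while mixing
proportions are always group-specific.  Nested models are compared by
likelihood-ratio tests, and the invariance ladder runs the standard
four-model comparison for one reference group (profiles fixed from a prior
fit) and two new waves:

* Model 1 — each wave has its own free profiles (least restricted);
* Model 2 — both waves fixed to the reference profiles (full invariance);
* Model 3 — "recovery": the second wave equals the reference, the first
  wave free;
* Model 4 — "pre/post change": the two waves share one free profile set
  that may differ from the reference.

The selected model is the most restricted one not rejected against
Model 1 at the chosen alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lpa import (FitError, LPAFit, ProfileSet, as_arrays, fit_em,
                  fit_with_fixed_profiles, make_start, multistart_fit,
                  posterior_probs)

logger = logging.getLogger(__name__)


@dataclass
class GroupModelSpec:
    """Measurement-equality structure across groups.

    ``sharing`` partitions the group labels into measurement-equality sets;
    groups in the same set share one profile set.  ``fixed`` maps a set
    (identified by its frozenset of labels) to a ProfileSet whose
    measurement parameters are fixed in advance and contribute no free
    parameters.  Mixing proportions are free per group in all cases.
    """

    groups: list[str]
    sharing: list[frozenset]
    fixed: dict[frozenset, ProfileSet] = field(default_factory=dict)

    def __post_init__(self):
        self.sharing = [frozenset(s) for s in self.sharing]
        self.fixed = {frozenset(k): v for k, v in self.fixed.items()}
        covered = set().union(*self.sharing) if self.sharing else set()
        if covered != set(self.groups):
            raise ValueError("sharing partition must cover all groups")
        if sum(len(s) for s in self.sharing) != len(covered):
            raise ValueError("sharing sets must be disjoint")
        for s in self.fixed:
            if s not in self.sharing:
                raise ValueError(f"fixed set {set(s)} not in the partition")

    def set_of(self, group: str) -> frozenset:
        for s in self.sharing:
            if group in s:
                return s
        raise KeyError(group)

    def n_free_params(self, K: int) -> int:
        free_sets = [s for s in self.sharing if s not in self.fixed]
        return 7 * K * len(free_sets) + (K - 1) * len(self.groups)


@dataclass
class MultigroupFit:
    spec: GroupModelSpec
    K: int
    profile_sets: dict[frozenset, ProfileSet]   # includes group mixing? no
    mixing: dict[str, np.ndarray]
    loglik: float
    n_obs: int
    converged: bool
    posteriors: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.spec.n_free_params(self.K)

    def group_profiles(self, group: str) -> ProfileSet:
        ps = self.profile_sets[self.spec.set_of(group)]
        return replace(ps, mixing=self.mixing[group])


@dataclass
class LRTResult:
    ll_general: float
    ll_restricted: float
    df: int
    statistic: float
    p: float


def _em_multigroup(arrays: dict[str, tuple], spec: GroupModelSpec, K: int,
                   init_sets: dict[frozenset, ProfileSet],
                   tol: float = 1e-6, max_iter: int = 1000) -> MultigroupFit:
    """EM over pooled groups with per-set measurement and per-group mixing."""
    from .lpa import _m_step   # shared closed-form M-step machinery

    sets = {s: init_sets[s] for s in spec.sharing}
    for ps in sets.values():
        ps.validate()
    mixing = {g: sets[spec.set_of(g)].mixing.copy() for g in spec.groups}
    N_total = sum(arrays[g][0].shape[0] for g in spec.groups)

    def e_step():
        ll = 0.0
        post = {}
        for g in spec.groups:
            ps = replace(sets[spec.set_of(g)], mixing=mixing[g])
            P, ll_g = posterior_probs(arrays[g][0], arrays[g][1], ps)
            post[g] = P
            ll += ll_g
        return post, ll

    post, ll = e_step()
    converged = False
    for it in range(1, max_iter + 1):
        # measurement update per free set, pooled over member groups
        for s in spec.sharing:
            if s in spec.fixed:
                continue
            members = [g for g in spec.groups if g in s]
            Y = np.vstack([arrays[g][0] for g in members])
            we = np.concatenate([arrays[g][1] for g in members])
            P = np.vstack([post[g] for g in members])
            pi_floor = 1.0 / (2.0 * Y.shape[0])
            new = _m_step(Y, we, P, sets[s], pi_floor)
            sets[s] = new
        for g in spec.groups:
            m = post[g].mean(axis=0)
            floor = 1.0 / (2.0 * post[g].shape[0])
            m = np.maximum(m, floor)
            mixing[g] = m / m.sum()
        post, ll_new = e_step()
        if ll_new < ll - 1e-8 * (1.0 + abs(ll)):
            raise FitError(f"multigroup EM log-likelihood decreased at {it}")
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return MultigroupFit(spec=spec, K=K, profile_sets=dict(sets),
                         mixing=mixing, loglik=ll, n_obs=N_total,
                         converged=converged, posteriors=post)


def fit_multigroup(data_by_group: dict[str, pd.DataFrame],
                   spec: GroupModelSpec, K: int, n_starts: int = 10,
                   seed: int | None = None, tol: float = 1e-6,
                   max_iter: int = 1000) -> MultigroupFit:
    """Fit the multigroup model with multistart over the free sets.

    Free measurement sets are initialised from multistart cross-sectional
    fits on their pooled data (plus jittered re-inits on later starts);
    fixed sets use the supplied parameters throughout.
    """
    for g, df in data_by_group.items():
        if len(df) == 0:
            raise ValueError(f"group {g!r} is empty")
    for g in spec.groups:
        if g not in data_by_group:
            raise ValueError(f"missing data for group {g!r}")
        if g not in {x for s in spec.fixed for x in s}:
            if len(data_by_group[g]) < K:
                raise ValueError(
                    f"group {g!r} has fewer rows than profiles and free "
                    "measurement")
    arrays = {g: as_arrays(data_by_group[g]) for g in spec.groups}
    rng = np.random.default_rng(seed)
    best: MultigroupFit | None = None
    failures = []
    for s_idx in range(max(n_starts, 1)):
        init_sets: dict[frozenset, ProfileSet] = {}
        try:
            for s in spec.sharing:
                if s in spec.fixed:
                    init_sets[s] = spec.fixed[s]
                    continue
                members = [g for g in spec.groups if g in s]
                Y = np.vstack([arrays[g][0] for g in members])
                we = np.concatenate([arrays[g][1] for g in members])
                if s_idx == 0:
                    pooled = multistart_fit(
                        (Y, we), K, n_starts=4,
                        seed=int(rng.integers(2**31 - 1)))
                    init_sets[s] = pooled.profiles
                else:
                    kind = "kmeans" if s_idx % 2 else "random"
                    init_sets[s] = make_start(Y, we, K, rng, kind=kind,
                                              jitter=0.5)
            fit = _em_multigroup(arrays, spec, K, init_sets, tol=tol,
                                 max_iter=max_iter)
        except (FitError, ValueError) as exc:
            failures.append(str(exc))
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError("all multigroup starts failed: "
                       + "; ".join(failures[:3]))
    return best


def lrt(general: MultigroupFit, restricted: MultigroupFit) -> LRTResult:
    """Chi-square likelihood-ratio test of a nested restriction."""
    df = general.n_params - restricted.n_params
    if df <= 0:
        raise ValueError("restricted model must have fewer free parameters")
    stat = 2.0 * (general.loglik - restricted.loglik)
    if stat < -1e-6 * (1.0 + abs(general.loglik)):
        raise ValueError("restricted model fits better than the general "
                         "model: models are not nested or fits failed")
    stat = max(stat, 0.0)
    return LRTResult(ll_general=general.loglik,
                     ll_restricted=restricted.loglik, df=df,
                     statistic=stat, p=float(stats.chi2.sf(stat, df)))


def invariance_ladder(data_ref: pd.DataFrame, data_w1: pd.DataFrame,
                      data_w2: pd.DataFrame, ref_profiles: ProfileSet,
                      K: int | None = None, alpha: float = 0.05,
                      n_starts: int = 10, seed: int | None = None,
                      labels: tuple[str, str, str] = ("Y6", "Y6-W1", "Y6-W2")
                      ) -> dict:
    """Run the four-model measurement-invariance ladder.

    ``ref_profiles`` is the reference group's fitted profile structure,
    held fixed (zero free measurement parameters) in every model.  Returns
    a dict with the four fits, the Model-2/3/4 LRTs against Model 1, the
    selected model number and a tidy report frame.
    """
    for name, df in zip(labels, (data_ref, data_w1, data_w2)):
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
    K = K or ref_profiles.K
    ref, w1, w2 = labels
    data = {ref: data_ref, w1: data_w1, w2: data_w2}
    rng = np.random.default_rng(seed)
    ss = lambda: int(rng.integers(2**31 - 1))

    spec1 = GroupModelSpec(list(labels),
                           [{ref}, {w1}, {w2}],
                           fixed={frozenset({ref}): ref_profiles})
    spec2 = GroupModelSpec(list(labels), [{ref, w1, w2}],
                           fixed={frozenset({ref, w1, w2}): ref_profiles})
    spec3 = GroupModelSpec(list(labels), [{ref, w2}, {w1}],
                           fixed={frozenset({ref, w2}): ref_profiles})
    spec4 = GroupModelSpec(list(labels), [{ref}, {w1, w2}],
                           fixed={frozenset({ref}): ref_profiles})
    fits = {}
    for num, spec in ((1, spec1), (2, spec2), (3, spec3), (4, spec4)):
        fits[num] = fit_multigroup(data, spec, K, n_starts=n_starts,
                                   seed=ss())
    tests = {num: lrt(fits[1], fits[num]) for num in (2, 3, 4)}

    # most restricted not rejected: Model 2 first, then 3/4 (equal df,
    # higher log-likelihood breaks the tie), else the general Model 1
    selected = 1
    if tests[2].p >= alpha:
        selected = 2
    else:
        cands = [n for n in (3, 4) if tests[n].p >= alpha]
        if cands:
            selected = max(cands, key=lambda n: fits[n].loglik)

    descriptions = {
        1: "Different profiles for each wave",
        2: "Same profiles across all waves",
        3: f"Recovery model ({ref} = {w2})",
        4: f"Pre/post change model ({w1} = {w2})",
    }
    rows = []
    for num in (1, 2, 3, 4):
        warn = "" if fits[num].converged else "not converged"
        rows.append({
            "model": num, "description": descriptions[num],
            "loglik": fits[num].loglik, "df": fits[num].n_params,
            "lrt_df": tests[num].df if num in tests else np.nan,
            "p_vs_model1": tests[num].p if num in tests else np.nan,
            "selected": num == selected, "note": warn,
        })
    return {"fits": fits, "tests": tests, "selected": selected,
            "report": pd.DataFrame(rows)}
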