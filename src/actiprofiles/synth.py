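"""Synthetic cohort generation with citable, table-anchored truth.

Generates children whose activity compositions follow the constrained
profile mixture the analysis assumes: within a profile, the weekday and
weekend (MVPA, sedentary) pairs are independent draws from a bivariate
normal with the profile's means, shared variances and covariance.  Draws
violating the composition simplex (negative proportions or MVPA+sedentary
above one) are rejected and redrawn so within-profile means are preserved.

Covariates are drawn per profile: gender and household education as
Bernoulli, the structured/unstructured activity-day scores from a scaled
Beta on [0, 6] with the profile's mean and a common SD (a bounded family
avoids the mean inflation that clipping a normal at zero would cause).
Weekend blocks are blanked missing-at-random.  Optional extras: paired
two-timepoint cohorts driven by a transition matrix, and epoch-level count
streams that round-trip through the accelerometer processing rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .accel import CutPoints, DEFAULT_EPOCH_S
from .lpa import ProfileSet, DAY_TYPE_WEIGHTS


def _check_sampleable(profiles: ProfileSet) -> None:
    """Sampling needs positive semi-definite blocks and proper mixing;
    degenerate (zero-variance) profiles are allowed, unlike estimation."""
    if not np.isclose(profiles.mixing.sum(), 1.0):
        raise ValueError("mixing proportions must sum to 1")
    bad = profiles.cov**2 > profiles.var_m * profiles.var_s
    bad |= (profiles.var_m < 0) | (profiles.var_s < 0)
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(f"profile {k} covariance block is not positive "
                         "semi-definite")


@dataclass
class CovariateModel:
    """Profile-conditional covariate distributions (one entry per profile)."""

    female_prob: np.ndarray
    no_degree_prob: np.ndarray
    structured_mean: np.ndarray
    unstructured_mean: np.ndarray
    structured_sd: float = 1.4
    unstructured_sd: float = 1.6


@dataclass
class CohortConfig:
    """Generator truth for one cross-sectional synthetic cohort."""

    n: int
    group: str
    profiles: ProfileSet
    covariates: CovariateModel | None = None
    weekend_missing_rate: float = presets.WEEKEND_MISSING_RATE
    wear_mean: float = presets.WEAR_MEAN_MIN
    wear_sd: float = presets.WEAR_SD_MIN

    def __post_init__(self):
        _check_sampleable(self.profiles)
        if not 0.0 <= self.weekend_missing_rate < 1.0:
            raise ValueError("weekend_missing_rate must be in [0, 1)")


def preset_profiles(period: str, wave: str = "W2",
                    sd_targets: tuple[float, float] | None = None
                    ) -> ProfileSet:
    """The published 6-profile structure as a :class:`ProfileSet`.

    ``period`` is ``"pre_covid"`` or ``"post_lockdown"``; post-lockdown
    mixing proportions differ by survey ``wave`` ("W1" or "W2") while the
    profile means are shared.  Within-profile variances are moment-matched
    to the published overall weekday SDs (overridable via ``sd_targets``),
    with covariance ``-0.5 * sd_M * sd_S`` (a negative MVPA-sedentary
    association; the published model constrains it non-zero but prints no
    value).
    """
    if period == "pre_covid":
        mu = presets.PRE_COVID_MEANS
        mixing = cal_mixing = presets.PRE_COVID_MIXING
        labels = presets.PRE_COVID_LABELS
        targets = sd_targets or presets.PRE_COVID_SD_TARGETS
    elif period == "post_lockdown":
        mu = presets.POST_LOCKDOWN_MEANS
        mixing = presets.W1_MIXING if wave == "W1" else presets.W2_MIXING
        # one shared measurement model for both waves: variances calibrated
        # against the W2 overall-SD column regardless of the wave whose
        # mixing is requested (the waves share profiles, not proportions)
        cal_mixing = presets.W2_MIXING
        labels = presets.POST_LOCKDOWN_LABELS
        targets = sd_targets or presets.POST_LOCKDOWN_SD_TARGETS
    else:
        raise ValueError(f"unknown period {period!r}")
    mixing = mixing / mixing.sum()
    cal_mixing = cal_mixing / cal_mixing.sum()
    vm = presets.matched_within_variance(mu[:, 0], cal_mixing, targets[0])
    vs = presets.matched_within_variance(mu[:, 1], cal_mixing, targets[1])
    # activity-scaled allocation of the (pinned) mean within-variance
    w_wd, w_we = DAY_TYPE_WEIGHTS
    act = w_wd * mu[:, 0] + w_we * mu[:, 2]
    z = (act - cal_mixing @ act) / act.std()
    s = np.exp(presets.SD_ACTIVITY_SCALING_GAMMA * z)
    s = s / (cal_mixing @ s)
    var_m = vm * s
    var_s = vs * s
    cov = -0.5 * np.sqrt(var_m * var_s)
    return ProfileSet(mu=mu.copy(), var_m=var_m, var_s=var_s, cov=cov,
                      mixing=mixing, labels=list(labels))


def preset_covariates(group: str) -> CovariateModel:
    """Covariate truth for a sample group ("Y6", "Y6-W1" or "Y6-W2")."""
    if group not in presets.FEMALE_PROB:
        raise ValueError(f"no covariate preset for group {group!r}")
    mixing = {"Y6": presets.PRE_COVID_MIXING,
              "Y6-W1": presets.W1_MIXING,
              "Y6-W2": presets.W2_MIXING}[group]
    mixing = mixing / mixing.sum()
    s_sd = np.sqrt(presets.matched_within_variance(
        presets.STRUCTURED_MEAN[group], mixing, presets.STRUCTURED_SD[group]))
    u_sd = np.sqrt(presets.matched_within_variance(
        presets.UNSTRUCTURED_MEAN[group], mixing,
        presets.UNSTRUCTURED_SD[group]))
    return CovariateModel(
        female_prob=presets.FEMALE_PROB[group].copy(),
        no_degree_prob=presets.NO_DEGREE_PROB[group].copy(),
        structured_mean=presets.STRUCTURED_MEAN[group].copy(),
        unstructured_mean=presets.UNSTRUCTURED_MEAN[group].copy(),
        structured_sd=float(s_sd), unstructured_sd=float(u_sd),
    )


def pre_covid_config(n: int = 1296) -> CohortConfig:
    return CohortConfig(n=n, group="Y6", profiles=preset_profiles("pre_covid"),
                        covariates=preset_covariates("Y6"))


def post_lockdown_config(n: int, wave: str = "W1") -> CohortConfig:
    group = f"Y6-{wave}"
    return CohortConfig(n=n, group=group,
                        profiles=preset_profiles("post_lockdown", wave=wave),
                        covariates=preset_covariates(group))


# ---------------------------------------------------------------------------
# composition sampling
# ---------------------------------------------------------------------------

def _sample_pairs(n: int, mu_m: float, mu_s: float, vm: float, vs: float,
                  c: float, rng: np.random.Generator) -> np.ndarray:
    """n (MVPA, SED) pairs from one day-type block, simplex-rejected."""
    if vm == 0 and vs == 0:   # degenerate profile: point mass at the means
        return np.tile([mu_m, mu_s], (n, 1))
    cov = np.array([[vm, c], [c, vs]])
    L = np.linalg.cholesky(cov)
    out = np.empty((n, 2))
    todo = np.arange(n)
    tries = 0
    while todo.size:
        z = rng.standard_normal((todo.size, 2)) @ L.T
        z[:, 0] += mu_m
        z[:, 1] += mu_s
        ok = (z[:, 0] >= 0) & (z[:, 1] >= 0) & (z.sum(axis=1) <= 1.0)
        out[todo[ok]] = z[ok]
        todo = todo[~ok]
        tries += 1
        if tries > 1000:
            raise RuntimeError("simplex rejection sampling failed to converge")
    return out


def sample_compositions(profiles: ProfileSet, n: int,
                        rng: np.random.Generator,
                        weekend_missing_rate: float = 0.0
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw n compositions from a profile mixture.

    Returns ``(frame, true_profile)`` where the frame has the four
    indicator columns (weekend columns NaN for blanked blocks).  Used both
    by the cohort generator and by the parametric bootstrap.  Unlike
    estimation, sampling tolerates degenerate (zero-variance) profiles.
    """
    _check_sampleable(profiles)
    z = rng.choice(profiles.K, size=n, p=profiles.mixing)
    Y = np.empty((n, 4))
    for k in range(profiles.K):
        idx = np.flatnonzero(z == k)
        if idx.size == 0:
            continue
        vm, vs, c = profiles.var_m[k], profiles.var_s[k], profiles.cov[k]
        Y[idx, 0:2] = _sample_pairs(idx.size, profiles.mu[k, 0],
                                    profiles.mu[k, 1], vm, vs, c, rng)
        Y[idx, 2:4] = _sample_pairs(idx.size, profiles.mu[k, 2],
                                    profiles.mu[k, 3], vm, vs, c, rng)
    if weekend_missing_rate > 0:
        miss = rng.random(n) < weekend_missing_rate
        Y[miss, 2:4] = np.nan
    frame = pd.DataFrame(Y, columns=["p_mvpa_wd", "p_sed_wd",
                                     "p_mvpa_we", "p_sed_we"])
    return frame, z


def _beta_scores(mean: np.ndarray, sd: float, lo: float, hi: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-element draws from a Beta scaled to [lo, hi] with given means."""
    m = (np.asarray(mean, dtype=float) - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    # cap the variance below the Bernoulli bound so alpha, beta stay positive
    v = np.minimum(v, 0.95 * m * (1 - m))
    nu = m * (1 - m) / v - 1.0
    a = m * nu
    b = (1 - m) * nu
    return lo + (hi - lo) * rng.beta(a, b)


def generate_cohort(config: CohortConfig,
                    seed: int | np.random.Generator | None = None
                    ) -> pd.DataFrame:
    """Generate one cross-sectional synthetic cohort.

    Returns a frame with one row per child: composition indicators, wear
    times, covariates, the guideline flag and the true profile index
    (``true_profile``, for recovery scoring).  Deterministic given the seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    comp, z = sample_compositions(config.profiles, config.n, rng,
                                  config.weekend_missing_rate)
    df = comp.copy()
    df.insert(0, "child_id", [f"{config.group}-{i:06d}"
                              for i in range(config.n)])
    df.insert(1, "group", config.group)
    df["true_profile"] = z
    df["wear_wd"] = np.clip(rng.normal(config.wear_mean, config.wear_sd,
                                       config.n), 500, 1080)
    df["wear_we"] = np.clip(rng.normal(config.wear_mean, config.wear_sd,
                                       config.n), 500, 1080)
    df.loc[df["p_mvpa_we"].isna(), "wear_we"] = np.nan
    wk = (5.0 * df["p_mvpa_wd"] * df["wear_wd"]
          + 2.0 * df["p_mvpa_we"] * df["wear_we"]) / 7.0
    df["meets_guidelines"] = np.where(
        wk.isna(), np.nan,
        (wk >= presets.GUIDELINE_MIN_PER_DAY).astype(float))

    cm = config.covariates
    if cm is not None:
        df["female"] = (rng.random(config.n) < cm.female_prob[z]).astype(int)
        df["no_degree"] = (rng.random(config.n)
                           < cm.no_degree_prob[z]).astype(int)
        df["structured_days"] = _beta_scores(cm.structured_mean[z],
                                             cm.structured_sd, 0.0, 6.0, rng)
        df["unstructured_days"] = _beta_scores(cm.unstructured_mean[z],
                                               cm.unstructured_sd, 0.0, 6.0,
                                               rng)
    return df


# ---------------------------------------------------------------------------
# paired (two-timepoint) cohorts
# ---------------------------------------------------------------------------

@dataclass
class TransitionTruth:
    """Generator truth for paired timepoints."""

    initial: np.ndarray
    transition: np.ndarray     # rows: t1 profile -> t2 profile probabilities

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")


def generate_paired_cohort(n: int, profiles_t1: ProfileSet,
                           profiles_t2: ProfileSet, truth: TransitionTruth,
                           seed: int | np.random.Generator | None = None,
                           ) -> pd.DataFrame:
    """Children observed at two timepoints with latent profile transitions.

    Returns one row per child with ``*_t1`` / ``*_t2`` indicator columns and
    the true profile indices at both timepoints.
    """
    if truth.initial.size != profiles_t1.K:
        raise ValueError("initial probabilities do not match t1 profiles")
    if truth.transition.shape != (profiles_t1.K, profiles_t2.K):
        raise ValueError("transition matrix does not match profile counts")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z1 = rng.choice(profiles_t1.K, size=n, p=truth.initial)
    z2 = np.array([rng.choice(profiles_t2.K, p=truth.transition[j])
                   for j in z1])
    rows = {}
    for tp, prof, z in (("t1", profiles_t1, z1), ("t2", profiles_t2, z2)):
        Y = np.empty((n, 4))
        for k in range(prof.K):
            idx = np.flatnonzero(z == k)
            if idx.size == 0:
                continue
            vm, vs, c = prof.var_m[k], prof.var_s[k], prof.cov[k]
            Y[idx, 0:2] = _sample_pairs(idx.size, prof.mu[k, 0],
                                        prof.mu[k, 1], vm, vs, c, rng)
            Y[idx, 2:4] = _sample_pairs(idx.size, prof.mu[k, 2],
                                        prof.mu[k, 3], vm, vs, c, rng)
        for j, col in enumerate(["p_mvpa_wd", "p_sed_wd",
                                 "p_mvpa_we", "p_sed_we"]):
            rows[f"{col}_{tp}"] = Y[:, j]
        rows[f"true_profile_{tp}"] = z
    df = pd.DataFrame(rows)
    df.insert(0, "child_id", [f"pair-{i:06d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# epoch-level count streams (round-trip fixtures for the accel rules)
# ---------------------------------------------------------------------------

def generate_epoch_streams(children: pd.DataFrame,
                           dates: list | None = None,
                           wear_minutes: float = 600.0,
                           nonwear_runs_min: tuple[float, ...] = (),
                           cutpoints: CutPoints = CutPoints(),
                           epoch_s: int = DEFAULT_EPOCH_S,
                           seed: int | np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Emit epoch-level count streams realising each child's composition.

    For each child row and each date, wear epochs are laid down from 06:00
    with per-epoch counts whose class mix matches the child's target
    weekday or weekend proportions (rounded to whole epochs); remaining
    in-window epochs are zero, and ``nonwear_runs_min`` inserts explicit
    zero runs inside the wear block.  The 00:00-06:00 block is always zero.
    Processing the result with the default accelerometer rules recovers
    each child's composition to within epoch rounding.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if dates is None:
        # Mon-Fri + Sat-Sun of one ISO week
        dates = pd.date_range("2022-05-02", periods=7, freq="D")
    ep_per_min = 60 // epoch_s
    day_ep = 18 * 60 * ep_per_min          # 06:00-24:00
    wear_ep = int(round(wear_minutes * ep_per_min))
    nonwear_ep = [int(round(m * ep_per_min)) for m in nonwear_runs_min]
    if wear_ep + sum(nonwear_ep) > day_ep:
        raise ValueError("wear plus injected non-wear exceeds the day window")
    if wear_ep < 1:
        raise ValueError("wear_minutes must cover at least one epoch")

    lpa_counts = (cutpoints.sed_max + cutpoints.mvpa_min) // 2
    frames = []
    for _, child in children.iterrows():
        all_ts, all_counts = [], []
        for date in dates:
            date = pd.Timestamp(date)
            weekend = date.dayofweek >= 5
            p_m = child["p_mvpa_we" if weekend else "p_mvpa_wd"]
            p_s = child["p_sed_we" if weekend else "p_sed_wd"]
            if np.isnan(p_m):
                continue
            n_m = int(round(p_m * wear_ep))
            n_s = int(round(p_s * wear_ep))
            if n_m + n_s > wear_ep:
                raise ValueError("target proportions exceed the simplex")
            n_l = wear_ep - n_m - n_s
            wear_counts = np.concatenate([
                rng.integers(cutpoints.mvpa_min, cutpoints.mvpa_min + 500,
                             n_m),
                rng.integers(1, cutpoints.sed_max + 1, n_s),
                np.full(n_l, lpa_counts, dtype=np.int64),
            ])
            rng.shuffle(wear_counts)
            # layout from 06:00: wear segments interleaved with injected
            # zero runs; the remainder of the window is zero (trailing
            # non-wear) and the 00:00-06:00 block is zero throughout
            day_counts = np.zeros(24 * 60 * ep_per_min, dtype=np.int64)
            pos = 6 * 60 * ep_per_min
            segments = np.array_split(wear_counts, len(nonwear_ep) + 1)
            for i, seg in enumerate(segments):
                day_counts[pos:pos + seg.size] = seg
                pos += seg.size
                if i < len(nonwear_ep):
                    pos += nonwear_ep[i]   # leave an explicit zero run
            ts = pd.date_range(date, periods=day_counts.size,
                               freq=f"{epoch_s}s")
            all_ts.append(ts)
            all_counts.append(day_counts)
        if not all_ts:
            continue
        frames.append(pd.DataFrame({
            "child_id": child["child_id"],
            "timestamp": pd.DatetimeIndex(np.concatenate(
                [t.asi8 for t in all_ts]).view("datetime64[ns]")),
            "counts": np.concatenate(all_counts),
        }))
    if not frames:
        raise ValueError("no streams generated (all weekend blocks missing?)")
    return pd.concat(frames, ignore_index=True)
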