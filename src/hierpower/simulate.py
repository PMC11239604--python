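"""Monte-Carlo oracle: simulate multilevel trials, run the aligned tests.

The data-generating process is the additive random-effects realization
of the three-level exchangeable model: for participant l of provider k
of clinic j of hospital i,

    y_ijkl = mu_cell + h_i + c_ij + p_ijk + e_ijkl,

with component variances (rho_hospital, rho_clinic, rho_provider,
rho_residual) * sigma2 per outcome and the outcome covariance Sigma
applied to every component (the Kronecker model).  Components are drawn
in the fixed order hospital -> clinic -> provider -> residual.

``analyze_trial`` applies the cluster-mean test aligned with each
scenario — exactly the reduction of :mod:`hierpower.reduce` — whose
decision equals the Kenward–Roger mixed-model Wald test under balance.

``empirical_power`` estimates power by batched simulation.  By default
it draws, per replicate, the full-resolution hospital/clinic/provider
effects plus residual *means over provider half-groups*: the aligned
tests depend on the data only through these cluster means, so this is
distribution-identical to simulating all participants while keeping
10,000-replicate runs cheap.  ``use_full_trials=True`` instead loops
``simulate_trial``/``analyze_trial`` per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import EffectSpec, HierarchicalDesign, InvalidDesignError, VarianceModel
from .scenarios import Scenario

__all__ = ["TestResult", "SimResult", "simulate_trial", "analyze_trial",
           "empirical_power", "simulate_isu_means", "DegenerateDataError"]


class DegenerateDataError(ValueError):
    """The dataset has zero error variance; the test is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Decision of one aligned test on one dataset."""

    reject: bool
    statistic: float  # on the F scale
    ndf: int
    ddf: int
    pvalue: float


@dataclass(frozen=True)
class SimResult:
    """Empirical power estimate from repeated simulated trials."""

    reps: int
    rejections: int
    power: float
    se: float
    seed: int

    @classmethod
    def from_counts(cls, rejections: int, reps: int, seed: int) -> "SimResult":
        p = rejections / reps
        return cls(reps=reps, rejections=int(rejections), power=p,
                   se=float(np.sqrt(p * (1 - p) / reps)), seed=seed)


# ---------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------

def _component_drawer(rng: np.random.Generator, vm: VarianceModel):
    L = np.linalg.cholesky(vm.Sigma)
    identity = np.array_equal(vm.Sigma, np.eye(vm.m))

    def draw(shape: tuple, var: float) -> np.ndarray:
        z = rng.standard_normal(shape + (vm.m,))
        return np.sqrt(var) * z if identity else np.sqrt(var) * (z @ L.T)

    return draw


def _participant_arm(design: HierarchicalDesign) -> np.ndarray:
    """Treated indicator per participant, shape (H, C, P, S)."""
    H, C, P, S = (design.n_hospitals, design.n_clinics, design.n_providers,
                  design.n_participants)
    if design.randomization_level == "hospital":
        arms = design.hospital_arms()
        return np.broadcast_to(arms[:, None, None, None],
                               (H, C, P, S)).astype(bool)
    mask = design.within_treated_mask()
    return np.broadcast_to(mask[None], (H, C, P, S))


def simulate_trial(design: HierarchicalDesign, vm: VarianceModel,
                   effect: EffectSpec, seed: int) -> pd.DataFrame:
    """One full trial in long format, one row per participant.

    Columns: hospital, clinic, provider, participant (0-based ids), arm
    ("intervention"/"control"), subgroup (label or ""), y1..ym.
    Identical (design, vm, effect, seed) gives an identical dataset.
    """
    if effect.m != vm.m:
        raise InvalidDesignError("effect dimension does not match Sigma")
    H, C, P, S, m = (design.n_hospitals, design.n_clinics,
                     design.n_providers, design.n_participants, vm.m)
    rng = np.random.default_rng(seed)
    draw = _component_drawer(rng, vm)
    s2 = vm.sigma2
    h = draw((H,), vm.rho_hospital * s2)
    c = draw((H, C), vm.rho_clinic * s2)
    p = draw((H, C, P), vm.rho_provider * s2)
    e = draw((H, C, P, S), vm.rho_residual * s2)
    y = (h[:, None, None, None, :] + c[:, :, None, None, :]
         + p[:, :, :, None, :] + e)
    treated = _participant_arm(design)
    y = y + treated[..., None] * effect.delta

    idx = np.indices((H, C, P, S)).reshape(4, -1)
    labels = (np.asarray(design.subgroup_labels)
              if design.subgroup_labels is not None
              else np.full(H, "", dtype=object))
    df = pd.DataFrame({
        "hospital": idx[0], "clinic": idx[1], "provider": idx[2],
        "participant": idx[3],
        "arm": np.where(treated.reshape(-1), "intervention", "control"),
        "subgroup": labels[idx[0]],
    })
    for j in range(m):
        df[f"y{j + 1}"] = y[..., j].reshape(-1)
    return df


def simulate_isu_means(design: HierarchicalDesign, vm: VarianceModel,
                       reps: int, seed: int) -> np.ndarray:
    """ISU grand mean vectors for ``reps`` null trials, shape (reps, H, m)."""
    rng = np.random.default_rng(seed)
    Y = _draw_half_means(rng, reps, design, vm)
    return Y.mean(axis=(2, 3, 4))


def _draw_half_means(rng: np.random.Generator, reps: int,
                     design: HierarchicalDesign,
                     vm: VarianceModel) -> np.ndarray:
    """Cluster-mean sufficient statistics for ``reps`` null trials.

    Returns means over provider half-groups, shape
    (reps, H, C, P, n_half, m) with n_half = 2 when the participants per
    provider divide evenly (1 otherwise, which forbids participant-level
    randomization but suffices for all other analyses).
    """
    H, C, P, S = (design.n_hospitals, design.n_clinics, design.n_providers,
                  design.n_participants)
    n_half = 2 if S % 2 == 0 else 1
    draw = _component_drawer(rng, vm)
    s2 = vm.sigma2
    h = draw((reps, H), vm.rho_hospital * s2)
    c = draw((reps, H, C), vm.rho_clinic * s2)
    p = draw((reps, H, C, P), vm.rho_provider * s2)
    e = draw((reps, H, C, P, n_half), vm.rho_residual * s2 / (S / n_half))
    return (h[:, :, None, None, None, :] + c[:, :, :, None, None, :]
            + p[:, :, :, :, None, :] + e)


def _half_treated_mask(design: HierarchicalDesign, n_half: int) -> np.ndarray:
    """Treated mask at half-provider resolution, shape (C, P, n_half)."""
    C, P, S = design.n_clinics, design.n_providers, design.n_participants
    mask = np.zeros((C, P, n_half), dtype=bool)
    if design.randomization_level == "clinic":
        mask[: C // 2] = True
    elif design.randomization_level == "provider":
        mask[:, : P // 2] = True
    elif design.randomization_level == "participant":
        if n_half != 2:
            raise InvalidDesignError("participant-level randomization needs "
                                     "an even number of participants per "
                                     "provider")
        mask[:, :, 0] = True
    else:
        raise InvalidDesignError("no within-ISU mask for hospital-level "
                                 "randomization")
    return mask


# ---------------------------------------------------------------------
# aligned cluster-mean tests (vectorized over a leading batch axis)
# ---------------------------------------------------------------------

def _two_sample_t_f(xt: np.ndarray, xc: np.ndarray):
    """Squared two-sample t (F(1, n1+n2-2) scale) along the last axis."""
    n1, n2 = xt.shape[-1], xc.shape[-1]
    nu = n1 + n2 - 2
    d = xt.mean(-1) - xc.mean(-1)
    ss = (((xt - xt.mean(-1, keepdims=True)) ** 2).sum(-1)
          + ((xc - xc.mean(-1, keepdims=True)) ** 2).sum(-1))
    var_d = (ss / nu) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # 0/0 on degenerate data; surfaced as DegenerateDataError upstream
        return d * d / var_d, 1, nu


def _one_sample_t_f(x: np.ndarray):
    """Squared one-sample t (F(1, n-1) scale) along the last axis."""
    n = x.shape[-1]
    m = x.mean(-1)
    s2 = ((x - m[..., None]) ** 2).sum(-1) / (n - 1)
    return n * m * m / s2, 1, n - 1


def _scatter(Y: np.ndarray) -> np.ndarray:
    Yc = Y - Y.mean(-2, keepdims=True)
    return np.einsum("...ni,...nj->...ij", Yc, Yc)


def _two_sample_t2_f(Yt: np.ndarray, Yc: np.ndarray):
    """Two-sample Hotelling T^2 on (..., n, m), on the F(m, nu-m+1) scale."""
    n1, n2, m = Yt.shape[-2], Yc.shape[-2], Yt.shape[-1]
    nu = n1 + n2 - 2
    S = (_scatter(Yt) + _scatter(Yc)) / nu
    d = Yt.mean(-2) - Yc.mean(-2)
    t2 = (n1 * n2 / (n1 + n2)) * np.einsum(
        "...i,...i->...", d, np.linalg.solve(S, d[..., None])[..., 0])
    return t2 * (nu - m + 1) / (nu * m), m, nu - m + 1


def _one_sample_t2_f(D: np.ndarray):
    """One-sample Hotelling T^2 on (..., n, m), on the F(m, n-m) scale."""
    n, m = D.shape[-2], D.shape[-1]
    nu = n - 1
    S = _scatter(D) / nu
    d = D.mean(-2)
    t2 = n * np.einsum("...i,...i->...", d,
                       np.linalg.solve(S, d[..., None])[..., 0])
    return t2 * (nu - m + 1) / (nu * m), m, nu - m + 1


def _four_cell_contrast_f(cells: list[np.ndarray], coefs: np.ndarray):
    """Contrast F test in a balanced cell-means model.

    ``cells`` is a list of (..., n_g) arrays; the contrast estimate is
    sum(coef_g * cell mean), tested against the pooled within-cell MSE
    with N - q error df.
    """
    q = len(cells)
    ns = [c.shape[-1] for c in cells]
    nu = sum(ns) - q
    est = sum(co * c.mean(-1) for co, c in zip(coefs, cells))
    sse = sum(((c - c.mean(-1, keepdims=True)) ** 2).sum(-1) for c in cells)
    var_est = (sse / nu) * sum(co * co / n for co, n in zip(coefs, ns))
    return est * est / var_est, 1, nu


# ---------------------------------------------------------------------
# single-trial analysis
# ---------------------------------------------------------------------

def _isu_summaries(df: pd.DataFrame, m: int):
    ycols = [f"y{j + 1}" for j in range(m)]
    g = df.groupby("hospital", sort=True)
    isu_means = g[ycols].mean().to_numpy()
    arm_per_isu = g["arm"].first().to_numpy()
    sub_per_isu = g["subgroup"].first().to_numpy()
    return isu_means, arm_per_isu, sub_per_isu, ycols


def analyze_trial(df: pd.DataFrame, scenario: Scenario) -> TestResult:
    """Apply the scenario's aligned cluster-mean test to one dataset.

    The reduction mirrors :mod:`hierpower.reduce` exactly: ISU grand
    means for hospital-level randomization (two-sample t on the
    composite or two-sample Hotelling T^2 on the outcome vector),
    per-ISU arm differences for within-ISU randomization (one-sample t
    or T^2), the four-cell contrast for the pooled subgroup model, and
    the per-stratum two-sample t for the stratified model (first
    subgroup in sorted order; strata are exchangeable under the
    symmetric alternative).
    """
    vm, design = scenario.vm, scenario.design
    w = vm.composite_weights
    isu_means, arm_per_isu, sub_per_isu, ycols = _isu_summaries(df, vm.m)
    lvl = design.randomization_level

    if scenario.analysis == "simple" and lvl == "hospital":
        t_idx = arm_per_isu == "intervention"
        if scenario.outcome_mode == "composite":
            x = isu_means @ w
            stat, ndf, ddf = _two_sample_t_f(x[t_idx][None, :],
                                             x[~t_idx][None, :])
        else:
            stat, ndf, ddf = _two_sample_t2_f(isu_means[t_idx][None],
                                              isu_means[~t_idx][None])
    elif scenario.analysis == "simple":
        g = df.groupby(["hospital", "arm"], sort=True)[ycols].mean()
        diff = (g.xs("intervention", level="arm")[ycols].to_numpy()
                - g.xs("control", level="arm")[ycols].to_numpy())
        if scenario.outcome_mode == "composite":
            stat, ndf, ddf = _one_sample_t_f((diff @ w)[None, :])
        else:
            stat, ndf, ddf = _one_sample_t2_f(diff[None])
    elif scenario.analysis == "pooled":
        x = isu_means @ w
        cells = [x[(sub_per_isu == gname) & (arm_per_isu == a)][None, :]
                 for gname in sorted(set(sub_per_isu))
                 for a in ("intervention", "control")]
        coefs = 0.5 * np.array([1.0, -1.0, 1.0, -1.0])
        stat, ndf, ddf = _four_cell_contrast_f(cells, coefs)
    elif scenario.analysis == "stratified":
        x = isu_means @ w
        g0 = sorted(set(sub_per_isu))[0]
        in_g = sub_per_isu == g0
        stat, ndf, ddf = _two_sample_t_f(
            x[in_g & (arm_per_isu == "intervention")][None, :],
            x[in_g & (arm_per_isu == "control")][None, :])
    else:  # pragma: no cover - Scenario validates analysis
        raise InvalidDesignError(f"unknown analysis {scenario.analysis!r}")

    stat = float(np.asarray(stat).reshape(-1)[0])
    if not np.isfinite(stat):
        raise DegenerateDataError("zero error variance in the reduced data")
    pvalue = float(stats.f.sf(stat, ndf, ddf))
    return TestResult(reject=pvalue < scenario.alpha, statistic=stat,
                      ndf=ndf, ddf=ddf, pvalue=pvalue)


# ---------------------------------------------------------------------
# empirical power
# ---------------------------------------------------------------------

def _batched_rejections(scenario: Scenario, delta: float, Y: np.ndarray,
                        crit_cache: dict) -> np.ndarray:
    """Rejection indicators for one batch of half-mean arrays Y."""
    vm, design = scenario.vm, scenario.design
    w = vm.composite_weights
    delta_vec = scenario.effect(delta).delta
    lvl = design.randomization_level
    n_half = Y.shape[4]

    if lvl == "hospital":
        arms = design.hospital_arms().astype(bool)
        if delta:
            Y = Y + (arms[None, :, None, None, None, None]
                     * delta_vec)
        isu = Y.mean(axis=(2, 3, 4))
        if scenario.analysis == "simple":
            if scenario.outcome_mode == "composite":
                x = isu @ w
                stat, ndf, ddf = _two_sample_t_f(x[:, arms], x[:, ~arms])
            else:
                stat, ndf, ddf = _two_sample_t2_f(isu[:, arms], isu[:, ~arms])
        elif scenario.analysis == "pooled":
            x = isu @ w
            labels = np.asarray(design.subgroup_labels)
            cells = [x[:, (labels == gname) & (arms == tr)]
                     for gname in design.subgroups for tr in (True, False)]
            stat, ndf, ddf = _four_cell_contrast_f(
                cells, 0.5 * np.array([1.0, -1.0, 1.0, -1.0]))
        else:  # stratified
            x = isu @ w
            labels = np.asarray(design.subgroup_labels)
            in_g = labels == design.subgroups[0]
            stat, ndf, ddf = _two_sample_t_f(x[:, in_g & arms],
                                             x[:, in_g & ~arms])
    else:
        mask = _half_treated_mask(design, n_half).reshape(-1)
        R, H = Y.shape[:2]
        Yf = Y.reshape(R, H, -1, vm.m)
        if delta:
            Yf = Yf.copy()
            Yf[:, :, mask, :] += delta_vec
        diff = Yf[:, :, mask].mean(2) - Yf[:, :, ~mask].mean(2)
        if scenario.outcome_mode == "composite":
            stat, ndf, ddf = _one_sample_t_f(diff @ w)
        else:
            stat, ndf, ddf = _one_sample_t2_f(diff)

    key = (ndf, ddf)
    if key not in crit_cache:
        crit_cache[key] = stats.f.isf(scenario.alpha, ndf, ddf)
    return stat > crit_cache[key]


def empirical_power(scenario: Scenario, delta: float, reps: int, seed: int,
                    batch_size: int = 1000,
                    use_full_trials: bool = False) -> SimResult:
    """Monte-Carlo power of the scenario's aligned test at effect ``delta``.

    Reproducible given (scenario, delta, reps, seed).  ``reps >= 100``
    is required for a meaningful binomial standard error.
    """
    if reps < 100:
        raise InvalidDesignError("use at least 100 replicates")
    if use_full_trials:
        rng = np.random.default_rng(seed)
        trial_seeds = rng.integers(0, 2 ** 31 - 1, size=reps)
        eff = scenario.effect(delta)
        rej = 0
        for s in trial_seeds:
            df = simulate_trial(scenario.design, scenario.vm, eff, int(s))
            rej += analyze_trial(df, scenario).reject
        return SimResult.from_counts(rej, reps, seed)

    rng = np.random.default_rng(seed)
    crit_cache: dict = {}
    rej = 0
    done = 0
    while done < reps:
        b = min(batch_size, reps - done)
        Y = _draw_half_means(rng, b, scenario.design, scenario.vm)
        rej += int(_batched_rejections(scenario, delta, Y, crit_cache).sum())
        done += b
    return SimResult.from_counts(rej, reps, seed)
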