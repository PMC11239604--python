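"""The three design comparisons, assembled as runnable scenarios.

Each :class:`Scenario` bundles a design, a variance model, an outcome
mode and an analysis style, and knows how to produce its
power-equivalent reduced model for any effect magnitude.  The three
comparison runners evaluate curve families on a shared grid and compute
the qualitative conclusion (which design wins, pointwise) from the
curves themselves:

1. level of randomization (composite outcome, one affected outcome);
2. composite vs multivariate outcome (hospital-level randomization);
3. pooled vs stratified subgroup analysis (composite outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (EffectSpec, HierarchicalDesign, InvalidDesignError,
                     VarianceModel)
from .power import PowerCurve, PowerResult, default_grid, hlt_mckeon_power, power_curve
from .reduce import ReducedGLM, reduce_between, reduce_subgroup, reduce_within

__all__ = ["Scenario", "default_design", "default_variance",
           "default_scenarios", "run_randomization_comparison",
           "run_outcome_comparison", "run_subgroup_comparison",
           "ComparisonResult"]


def default_design(randomization_level: str = "hospital",
                   with_subgroups: bool = False) -> HierarchicalDesign:
    """The reference design: 20 hospitals x 8 clinics x 6 providers x 6
    participants, optionally split into 10 rural + 10 urban hospitals."""
    labels = ("rural",) * 10 + ("urban",) * 10 if with_subgroups else None
    return HierarchicalDesign(20, 8, 6, 6,
                              randomization_level=randomization_level,
                              subgroup_labels=labels)


def default_variance(m: int = 8) -> VarianceModel:
    """ICCs 0.05 (provider), 0.01 (clinic), 0.01 (hospital); unit total
    variance; independent outcomes; equal composite weights."""
    return VarianceModel(rho_provider=0.05, rho_clinic=0.01,
                         rho_hospital=0.01, sigma2=1.0, Sigma=np.eye(m))


@dataclass(frozen=True)
class Scenario:
    """One analyzable trial configuration.

    ``analysis`` is ``"simple"`` (intervention effect only),
    ``"pooled"`` or ``"stratified"`` (subgroup question; composite
    outcome, hospital-level randomization).  ``affected_outcome`` is the
    0-based index of the single outcome the intervention shifts.
    """

    name: str
    design: HierarchicalDesign
    vm: VarianceModel
    outcome_mode: str = "composite"
    analysis: str = "simple"
    affected_outcome: int = 0
    alpha: float = 0.05
    stratified_pooled_variance: bool = False

    def __post_init__(self):
        if self.outcome_mode not in ("composite", "multivariate"):
            raise InvalidDesignError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.analysis not in ("simple", "pooled", "stratified"):
            raise InvalidDesignError(f"unknown analysis {self.analysis!r}")
        if self.analysis != "simple":
            if self.design.subgroup_labels is None:
                raise InvalidDesignError("subgroup analysis needs subgroup labels")
            if self.outcome_mode != "composite":
                raise InvalidDesignError("subgroup comparison uses the "
                                         "composite outcome")
        if not (0 < self.alpha < 1):
            raise InvalidDesignError("alpha must lie in (0, 1)")

    def effect(self, delta: float) -> EffectSpec:
        return EffectSpec.single_outcome(delta, self.affected_outcome,
                                         m=self.vm.m)

    def reduced_glms(self, delta: float) -> list[ReducedGLM]:
        """All reduced models for effect magnitude ``delta`` (two for the
        stratified analysis, one otherwise)."""
        eff = self.effect(delta)
        if self.analysis == "simple":
            if self.design.randomization_level == "hospital":
                glm = reduce_between(self.design, self.vm, eff,
                                     self.outcome_mode)
            else:
                glm = reduce_within(self.design, self.vm, eff,
                                    self.outcome_mode)
            return [glm]
        glms = reduce_subgroup(
            self.design, self.vm, eff, analysis=self.analysis,
            stratified_pooled_variance=self.stratified_pooled_variance)
        return glms if isinstance(glms, list) else [glms]

    def reduced_glm(self, delta: float) -> ReducedGLM:
        """The representative reduced model (first stratum if stratified;
        strata are exchangeable under the symmetric alternative)."""
        return self.reduced_glms(delta)[0]

    def power(self, delta: float) -> PowerResult:
        return hlt_mckeon_power(self.reduced_glm(delta), alpha=self.alpha)

    def curve(self, grid=None) -> PowerCurve:
        grid = default_grid() if grid is None else grid
        return power_curve(self.reduced_glm, grid, alpha=self.alpha,
                           scenario=self.name)


def default_scenarios(alpha: float = 0.05) -> dict[str, Scenario]:
    """The six scenario families of the reference configuration."""
    vm = default_variance()
    out: dict[str, Scenario] = {}
    for lvl in ("hospital", "clinic", "provider", "participant"):
        out[f"composite-{lvl}"] = Scenario(
            name=f"composite-{lvl}", design=default_design(lvl), vm=vm,
            outcome_mode="composite", alpha=alpha)
    out["multivariate-hospital"] = Scenario(
        name="multivariate-hospital", design=default_design("hospital"),
        vm=vm, outcome_mode="multivariate", alpha=alpha)
    sub = default_design("hospital", with_subgroups=True)
    out["subgroup-pooled"] = Scenario(
        name="subgroup-pooled", design=sub, vm=vm, analysis="pooled",
        alpha=alpha)
    out["subgroup-stratified"] = Scenario(
        name="subgroup-stratified", design=sub, vm=vm, analysis="stratified",
        alpha=alpha)
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Curve family plus the conclusion computed from it."""

    question: str
    curves: dict
    #: name of the pointwise-dominant curve, or None if no curve dominates
    winner: str | None
    #: curve names sorted by pointwise dominance (best first) when a full
    #: ordering exists, else sorted by mean power
    ordering: tuple

    def to_frame(self):
        return pd.concat([c.to_frame() for c in self.curves.values()],
                         ignore_index=True)


def _conclude(question: str, curves: dict) -> ComparisonResult:
    names = list(curves)
    P = {k: curves[k].powers for k in names}
    tol = 1e-12

    def dominates(x, y):
        return bool(np.all(P[x] >= P[y] - tol))

    order = sorted(names, key=lambda k: -P[k].mean())
    winner = order[0] if all(dominates(order[0], k) for k in order[1:]) else None
    return ComparisonResult(question=question, curves=curves, winner=winner,
                            ordering=tuple(order))


def run_randomization_comparison(design: HierarchicalDesign | None = None,
                                 vm: VarianceModel | None = None,
                                 grid=None, alpha: float = 0.05,
                                 affected_outcome: int = 0) -> ComparisonResult:
    """Composite-outcome power at each of the four randomization levels."""
    base = default_design() if design is None else design
    vm = default_variance() if vm is None else vm
    grid = default_grid() if grid is None else grid
    curves = {}
    for lvl in ("participant", "provider", "clinic", "hospital"):
        sc = Scenario(name=lvl, design=base.with_randomization(lvl), vm=vm,
                      outcome_mode="composite", alpha=alpha,
                      affected_outcome=affected_outcome)
        curves[lvl] = sc.curve(grid)
    return _conclude("randomization_level", curves)


def run_outcome_comparison(design: HierarchicalDesign | None = None,
                           vm: VarianceModel | None = None,
                           grid=None, alpha: float = 0.05,
                           affected_outcome: int = 0) -> ComparisonResult:
    """Composite vs multivariate outcome under hospital-level
    randomization, one affected outcome."""
    base = default_design() if design is None else design
    if base.randomization_level != "hospital":
        raise InvalidDesignError("outcome comparison assumes hospital-level "
                                 "randomization")
    vm = default_variance() if vm is None else vm
    grid = default_grid() if grid is None else grid
    curves = {}
    for mode in ("multivariate", "composite"):
        sc = Scenario(name=mode, design=base, vm=vm, outcome_mode=mode,
                      alpha=alpha, affected_outcome=affected_outcome)
        curves[mode] = sc.curve(grid)
    return _conclude("composite_vs_multivariate", curves)


def run_subgroup_comparison(design: HierarchicalDesign | None = None,
                            vm: VarianceModel | None = None,
                            grid=None, alpha: float = 0.05,
                            affected_outcome: int = 0,
                            stratified_pooled_variance: bool = False
                            ) -> ComparisonResult:
    """Pooled vs stratified subgroup analysis, composite outcome, equal
    intervention effect in both subgroups (zero interaction)."""
    base = (default_design("hospital", with_subgroups=True)
            if design is None else design)
    vm = default_variance() if vm is None else vm
    grid = default_grid() if grid is None else grid
    curves = {}
    for analysis in ("pooled", "stratified"):
        sc = Scenario(name=analysis, design=base, vm=vm, analysis=analysis,
                      alpha=alpha, affected_outcome=affected_outcome,
                      stratified_pooled_variance=stratified_pooled_variance)
        curves[analysis] = sc.curve(grid)
    return _conclude("pooled_vs_stratified", curves)
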