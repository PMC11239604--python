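"""Power-equivalent reduction to an ISU-level multivariate linear model.

Under balance (equal cluster sizes at every level, no missing data, no
time-varying predictors), the Wald test of the multilevel mixed model
with Kenward–Roger degrees of freedom has exactly the power of a
multivariate general linear hypothesis on independent ISU-level
summaries.  These reducers construct that ISU-level model for each
scenario:

* hospital-level randomization -> each ISU contributes its grand mean
  vector; two-sample (cell-means) design;
* within-ISU randomization     -> each ISU contributes the pair
  (intervention arm mean, control arm mean) per outcome; one-cell
  design with the arm difference carried by the within-ISU contrast;
* subgroup analysis            -> pooled four-cell (arm x subgroup)
  design, or one two-cell design per stratum.

All designs use cell-means coding; hypotheses live entirely in the
between-ISU contrast C and within-ISU contrast U of H0: C B U = Theta0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .covariance import arm_mean_moments, isu_mean_variance
from .design import (EffectSpec, HierarchicalDesign, InvalidDesignError,
                     VarianceModel)

__all__ = ["ReducedGLM", "reduce_between", "reduce_within", "reduce_subgroup"]


@dataclass(frozen=True)
class ReducedGLM:
    """ISU-level multivariate linear model with a general linear hypothesis.

    Attributes
    ----------
    cell_counts : array of int, shape (q,)
        ISUs per design cell; the design matrix is the cell-indicator
        (cell-means) matrix, so X'X = diag(cell_counts).
    B : (q, p) array
        Population cell means on the reduced scale.
    SigmaStar : (p, p) array
        Error covariance of a single ISU row.
    C : (a, q) array
        Between-ISU contrast (full row rank).
    U : (p, b) array
        Within-ISU contrast (full column rank).
    Theta0 : (a, b) array
        Null-value matrix (zero in every scenario here).
    error_df_override : int or None
        Replaces the default error df N - q (used by the pooled-variance
        variant of the stratified analysis).
    """

    cell_counts: np.ndarray
    B: np.ndarray
    SigmaStar: np.ndarray
    C: np.ndarray
    U: np.ndarray
    Theta0: np.ndarray
    label: str = ""
    error_df_override: int | None = None

    def __post_init__(self):
        counts = np.asarray(self.cell_counts, dtype=int)
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        S = np.atleast_2d(np.asarray(self.SigmaStar, dtype=float))
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        U = np.atleast_2d(np.asarray(self.U, dtype=float))
        T = np.atleast_2d(np.asarray(self.Theta0, dtype=float))
        q, p = B.shape
        if counts.shape != (q,) or np.any(counts < 1):
            raise InvalidDesignError("cell_counts must be positive, one per row of B")
        if S.shape != (p, p):
            raise InvalidDesignError("SigmaStar must be p x p")
        if C.shape[1] != q or U.shape[0] != p:
            raise InvalidDesignError("contrast dimensions do not match B")
        a, b = C.shape[0], U.shape[1]
        if np.linalg.matrix_rank(C) != a:
            raise InvalidDesignError("C must have full row rank")
        if np.linalg.matrix_rank(U) != b:
            raise InvalidDesignError("U must have full column rank")
        if T.shape != (a, b):
            raise InvalidDesignError("Theta0 must be a x b")
        for name, v in (("cell_counts", counts), ("B", B), ("SigmaStar", S),
                        ("C", C), ("U", U), ("Theta0", T)):
            object.__setattr__(self, name, v)
        if self.error_df() < 1:
            raise InvalidDesignError("no positive error degrees of freedom")

    # -- derived dimensions -------------------------------------------
    @property
    def n_rows(self) -> int:
        return int(self.cell_counts.sum())

    @property
    def rank_r(self) -> int:
        """Rank of the ISU-level design (model degrees of freedom)."""
        return len(self.cell_counts)

    @property
    def a(self) -> int:
        return self.C.shape[0]

    @property
    def b(self) -> int:
        return self.U.shape[1]

    def error_df(self) -> int:
        if self.error_df_override is not None:
            return int(self.error_df_override)
        return self.n_rows - len(np.atleast_1d(self.cell_counts))

    def effect_matrix(self) -> np.ndarray:
        """C B U - Theta0, the tested departure from the null."""
        return self.C @ self.B @ self.U - self.Theta0

    def to_report(self) -> str:
        """Plain-text dump of all matrices for audit."""
        out = StringIO()
        out.write(f"ReducedGLM: {self.label or '(unnamed)'}\n")
        out.write(f"N = {self.n_rows}  rank = {self.rank_r}  "
                  f"error df = {self.error_df()}  a = {self.a}  b = {self.b}\n")
        for name, mat in (("cell_counts", self.cell_counts[None, :]),
                          ("B", self.B), ("SigmaStar", self.SigmaStar),
                          ("C", self.C), ("U", self.U), ("Theta0", self.Theta0)):
            out.write(f"{name}:\n")
            for row in np.atleast_2d(mat):
                out.write("  " + "  ".join(f"{v:.10g}" for v in row) + "\n")
        return out.getvalue()


def _check_effect(vm: VarianceModel, effect: EffectSpec) -> None:
    if effect.m != vm.m:
        raise InvalidDesignError("effect dimension does not match Sigma")


def reduce_between(design: HierarchicalDesign, vm: VarianceModel,
                   effect: EffectSpec,
                   outcome_mode: str = "composite") -> ReducedGLM:
    """Reduction for hospital-level (between-ISU) randomization.

    Each ISU contributes its grand mean vector; the error covariance is
    ``vbar * Sigma`` with ``vbar`` the variance of one ISU mean.  In
    composite mode the outcome axis is pre-collapsed by the composite
    weights, so p = 1.
    """
    if design.randomization_level != "hospital":
        raise InvalidDesignError("reduce_between requires hospital-level "
                                 "randomization")
    _check_effect(vm, effect)
    H = design.n_hospitals
    counts = np.array([H // 2, H // 2])
    vbar = isu_mean_variance(design, vm)
    if outcome_mode == "multivariate":
        B = np.vstack([effect.delta, np.zeros(vm.m)])
        SigmaStar = vbar * vm.Sigma
        U = np.eye(vm.m)
    elif outcome_mode == "composite":
        B = np.array([[effect.composite_effect(vm)], [0.0]])
        SigmaStar = np.array([[vbar * vm.composite_variance]])
        U = np.array([[1.0]])
    else:
        raise InvalidDesignError(f"unknown outcome_mode {outcome_mode!r}")
    C = np.array([[1.0, -1.0]])
    Theta0 = np.zeros((1, U.shape[1]))
    return ReducedGLM(counts, B, SigmaStar, C, U, Theta0,
                      label=f"between/{outcome_mode}")


def reduce_within(design: HierarchicalDesign, vm: VarianceModel,
                  effect: EffectSpec,
                  outcome_mode: str = "composite") -> ReducedGLM:
    """Reduction for within-ISU (clinic/provider/participant) randomization.

    Each ISU contributes the pair (intervention arm mean, control arm
    mean) per outcome, arm-major, so p = 2m (or 2 in composite mode).
    The single-cell design has rank 1; the arm difference is carried by
    the within-ISU contrast, which cancels every variance component the
    two arms share (in particular the hospital component always drops).
    """
    _check_effect(vm, effect)
    var, cov = arm_mean_moments(design, vm)  # validates the level
    H = design.n_hospitals
    M2 = np.array([[var, cov], [cov, var]])
    if outcome_mode == "multivariate":
        B = np.hstack([effect.delta, np.zeros(vm.m)])[None, :]
        SigmaStar = np.kron(M2, vm.Sigma)
        U = np.vstack([np.eye(vm.m), -np.eye(vm.m)])
    elif outcome_mode == "composite":
        de = effect.composite_effect(vm)
        B = np.array([[de, 0.0]])
        SigmaStar = M2 * vm.composite_variance
        U = np.array([[1.0], [-1.0]])
    else:
        raise InvalidDesignError(f"unknown outcome_mode {outcome_mode!r}")
    counts = np.array([H])
    C = np.array([[1.0]])
    Theta0 = np.zeros((1, U.shape[1]))
    return ReducedGLM(counts, B, SigmaStar, C, U, Theta0,
                      label=f"within-{design.randomization_level}/{outcome_mode}")


def reduce_subgroup(design: HierarchicalDesign, vm: VarianceModel,
                    effect: EffectSpec, analysis: str = "pooled",
                    effect_second_subgroup: EffectSpec | None = None,
                    stratified_pooled_variance: bool = False):
    """Reduction for the subgroup question (composite outcome).

    Pooled: one four-cell model (arm x subgroup, cell-means coding).
    The intervention main effect averaged over subgroup is tested via
    C = (1, -1, 1, -1)/2; the interaction parameter is present in the
    cell-means model (rank 4, so it charges one error df) but its
    population value is zero under the symmetric alternative, making
    the pooled df accounting deliberately conservative.

    Stratified: one two-cell model per stratum on half the ISUs each,
    returned as a list ordered by sorted subgroup label.  By default
    each stratum uses its own error df (N/2 - 2); with
    ``stratified_pooled_variance=True`` the error df of the full
    four-cell model (N - 4) is charged instead, mimicking a variance
    estimated in the entire sample.
    """
    if design.randomization_level != "hospital":
        raise InvalidDesignError("subgroup analyses assume hospital-level "
                                 "randomization")
    if design.subgroup_labels is None:
        raise InvalidDesignError("design has no subgroup labels")
    groups = design.subgroups
    if len(groups) != 2:
        raise InvalidDesignError("exactly two subgroups are supported")
    _check_effect(vm, effect)
    eff2 = effect if effect_second_subgroup is None else effect_second_subgroup
    _check_effect(vm, eff2)
    labels = np.asarray(design.subgroup_labels)
    sizes = [int((labels == g).sum()) for g in groups]
    vbar = isu_mean_variance(design, vm)
    s2 = np.array([[vbar * vm.composite_variance]])
    d = [effect.composite_effect(vm), eff2.composite_effect(vm)]
    U = np.array([[1.0]])
    if analysis == "pooled":
        counts = np.array([sizes[0] // 2, sizes[0] // 2,
                           sizes[1] // 2, sizes[1] // 2])
        B = np.array([[d[0]], [0.0], [d[1]], [0.0]])
        C = 0.5 * np.array([[1.0, -1.0, 1.0, -1.0]])
        return ReducedGLM(counts, B, s2, C, U, np.zeros((1, 1)),
                          label="subgroup/pooled")
    if analysis == "stratified":
        glms = []
        for g, size, dg in zip(groups, sizes, d):
            counts = np.array([size // 2, size // 2])
            B = np.array([[dg], [0.0]])
            C = np.array([[1.0, -1.0]])
            override = design.n_hospitals - 4 if stratified_pooled_variance else None
            glms.append(ReducedGLM(counts, B, s2, C, U, np.zeros((1, 1)),
                                   label=f"subgroup/stratified-{g}",
                                   error_df_override=override))
        return glms
    raise InvalidDesignError(f"unknown analysis {analysis!r}")
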