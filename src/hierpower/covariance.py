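"""Exchangeable three-level cluster covariance and contrast variances.

Two routes to the same quantities are deliberately kept separate:

* :func:`build_isu_covariance` materializes the full within-ISU
  covariance matrix (participants x outcomes) — intended for small
  designs, audits and test oracles;
* :func:`contrast_variance` evaluates quadratic forms a'Va by counting
  shared variance components, never building the matrix, so it scales
  to arbitrarily large balanced designs.

Their agreement on small designs is a core invariant of the package.
"""

from __future__ import annotations

import numpy as np

from .design import HierarchicalDesign, InvalidDesignError, VarianceModel

__all__ = [
    "participant_covariance",
    "build_isu_covariance",
    "contrast_variance",
    "isu_mean_variance",
    "arm_mean_moments",
    "write_matrix_csv",
]


def participant_covariance(design: HierarchicalDesign,
                           vm: VarianceModel) -> np.ndarray:
    """Single-outcome covariance among the participants of one ISU.

    Returns the (C*P*S) x (C*P*S) matrix V with diagonal ``sigma2`` and
    off-diagonal ``sigma2 * (rho_hospital + rho_clinic*[same clinic] +
    rho_provider*[same provider])``.  Rows are ordered clinic-major,
    then provider, then participant.
    """
    if vm.rho_residual <= 0:
        raise InvalidDesignError("residual variance share must be positive")
    C, P, S = design.n_clinics, design.n_providers, design.n_participants
    n = C * P * S
    V = vm.rho_hospital * np.ones((n, n))
    V += vm.rho_clinic * np.kron(np.eye(C), np.ones((P * S, P * S)))
    V += vm.rho_provider * np.kron(np.eye(C * P), np.ones((S, S)))
    V += vm.rho_residual * np.eye(n)
    return vm.sigma2 * V


def build_isu_covariance(design: HierarchicalDesign,
                         vm: VarianceModel) -> np.ndarray:
    """Full within-ISU covariance, V (participants) Kronecker Sigma (outcomes)."""
    return np.kron(participant_covariance(design, vm), vm.Sigma)


def contrast_variance(design: HierarchicalDesign, vm: VarianceModel,
                      coefficients, outcome_weights=None) -> float:
    """Variance of a weighted combination of one ISU's observations.

    Computes ``a' V a * (w' Sigma w)`` by summing squared coefficient
    totals within each cluster, without materializing V.  ``coefficients``
    has length C*P*S in the clinic-major ordering of
    :func:`participant_covariance`; ``outcome_weights`` defaults to a
    single-outcome scale factor of 1.
    """
    if vm.rho_residual <= 0:
        raise InvalidDesignError("residual variance share must be positive")
    C, P, S = design.n_clinics, design.n_providers, design.n_participants
    a = np.asarray(coefficients, dtype=float)
    if a.shape != (C * P * S,):
        raise InvalidDesignError(
            f"coefficient vector must have length {C * P * S}, got {a.shape}"
        )
    A = a.reshape(C, P, S)
    quad = (
        vm.rho_hospital * A.sum() ** 2
        + vm.rho_clinic * (A.sum(axis=(1, 2)) ** 2).sum()
        + vm.rho_provider * (A.sum(axis=2) ** 2).sum()
        + vm.rho_residual * (A ** 2).sum()
    )
    quad *= vm.sigma2
    if outcome_weights is None:
        scale = 1.0
    else:
        w = np.asarray(outcome_weights, dtype=float)
        if w.shape != (vm.m,):
            raise InvalidDesignError("outcome_weights must have length m")
        scale = float(w @ vm.Sigma @ w)
    return float(quad * scale)


def isu_mean_variance(design: HierarchicalDesign, vm: VarianceModel) -> float:
    """Variance of the grand mean of one ISU, single-outcome scale.

    Closed form: ``sigma2 * (rho_h + rho_c/C + rho_p/(C P) + rho_e/(C P S))``.
    """
    C, P, S = design.n_clinics, design.n_providers, design.n_participants
    return vm.sigma2 * (
        vm.rho_hospital
        + vm.rho_clinic / C
        + vm.rho_provider / (C * P)
        + vm.rho_residual / (C * P * S)
    )


def arm_mean_moments(design: HierarchicalDesign,
                     vm: VarianceModel) -> tuple[float, float]:
    """(variance, covariance) of the two within-ISU arm means, per outcome.

    Requires within-ISU randomization (clinic, provider or participant
    level) with the balanced split of :meth:`HierarchicalDesign.
    within_treated_mask`.  The variance applies to either arm mean; the
    covariance collects the variance components shared by both arms
    (those at and above the parent of the randomized level, averaged
    over the clusters both arms span).
    """
    lvl = design.randomization_level
    if lvl == "hospital":
        raise InvalidDesignError(
            "arm_mean_moments requires within-ISU randomization"
        )
    C, P, S = design.n_clinics, design.n_providers, design.n_participants
    rh, rc, rp, re = (vm.rho_hospital, vm.rho_clinic, vm.rho_provider,
                      vm.rho_residual)
    if lvl == "clinic":
        var = rh + rc / (C // 2) + rp / ((C // 2) * P) + re / ((C // 2) * P * S)
        cov = rh
    elif lvl == "provider":
        var = rh + rc / C + rp / (C * (P // 2)) + re / (C * (P // 2) * S)
        cov = rh + rc / C
    else:  # participant
        var = rh + rc / C + rp / (C * P) + re / (C * P * (S // 2))
        cov = rh + rc / C + rp / (C * P)
    return vm.sigma2 * var, vm.sigma2 * cov


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    """Write a covariance matrix to CSV for inspection."""
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.12g")
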