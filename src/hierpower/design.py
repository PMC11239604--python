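"""Balanced multilevel trial designs and their variance models.

The design emulated throughout is a four-level Gaussian hierarchy:
participants are treated by providers, providers work in clinics, and
clinics sit inside hospitals.  Hospitals are the independent sampling
units (ISUs); everything below them is correlated through additive
random effects.  Randomization can happen at any of the four levels,
always with equal allocation inside the immediate parent unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEVELS",
    "HierarchicalDesign",
    "VarianceModel",
    "EffectSpec",
    "InvalidDesignError",
]

#: Randomization levels, outermost first.
LEVELS = ("hospital", "clinic", "provider", "participant")


class InvalidDesignError(ValueError):
    """A design or variance model violates a structural requirement."""


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidDesignError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class HierarchicalDesign:
    """Balanced four-level nesting structure with a randomization level.

    Parameters
    ----------
    n_hospitals : int
        Number of independent sampling units (ISUs).
    n_clinics : int
        Clinics per hospital.
    n_providers : int
        Providers per clinic.
    n_participants : int
        Participants per provider.
    randomization_level : str
        One of ``"hospital"``, ``"clinic"``, ``"provider"``,
        ``"participant"``.  Randomization below the hospital level is
        *within* ISUs, split equally inside the immediate parent unit
        (e.g. 3 of 6 providers per clinic).
    subgroup_labels : tuple of str, optional
        One label per hospital (e.g. ``"rural"``/``"urban"``).  Only
        meaningful for hospital-level randomization, where arms are
        balanced within each subgroup.
    """

    n_hospitals: int = 20
    n_clinics: int = 8
    n_providers: int = 6
    n_participants: int = 6
    randomization_level: str = "hospital"
    subgroup_labels: tuple | None = None

    def __post_init__(self):
        for name in ("n_hospitals", "n_clinics", "n_providers", "n_participants"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise InvalidDesignError(f"{name} must be an integer >= 1, got {v!r}")
        if self.randomization_level not in LEVELS:
            raise InvalidDesignError(
                f"randomization_level must be one of {LEVELS}, "
                f"got {self.randomization_level!r}"
            )
        # Equal allocation requires an even count at the randomized level
        # within its immediate parent; approximate balance is rejected
        # because the power-equivalent reduction requires exact balance.
        n_at_level = {
            "hospital": self.n_hospitals,
            "clinic": self.n_clinics,
            "provider": self.n_providers,
            "participant": self.n_participants,
        }[self.randomization_level]
        if n_at_level % 2:
            raise InvalidDesignError(
                f"{self.randomization_level} count ({n_at_level}) must be even "
                "for equal allocation"
            )
        if self.subgroup_labels is not None:
            labels = tuple(self.subgroup_labels)
            if len(labels) != self.n_hospitals:
                raise InvalidDesignError(
                    "subgroup_labels must have one entry per hospital"
                )
            for g in sorted(set(labels)):
                cnt = labels.count(g)
                if cnt % 2:
                    raise InvalidDesignError(
                        f"subgroup {g!r} has {cnt} hospitals; an even count is "
                        "required for equal allocation"
                    )
                if cnt < 4:
                    raise InvalidDesignError(
                        f"subgroup {g!r} needs at least 2 hospitals per arm"
                    )
            object.__setattr__(self, "subgroup_labels", labels)

    # -- size helpers -------------------------------------------------
    @property
    def n_isu(self) -> int:
        return self.n_hospitals

    @property
    def participants_per_isu(self) -> int:
        return self.n_clinics * self.n_providers * self.n_participants

    @property
    def n_total_participants(self) -> int:
        return self.n_hospitals * self.participants_per_isu

    @property
    def subgroups(self) -> tuple:
        if self.subgroup_labels is None:
            return ()
        return tuple(sorted(set(self.subgroup_labels)))

    # -- allocation ---------------------------------------------------
    def hospital_arms(self) -> np.ndarray:
        """Arm indicator per hospital (1 intervention, 0 control).

        Only meaningful for hospital-level randomization.  Without
        subgroups the first half of the hospitals is assigned to
        intervention; with subgroups the split is balanced within each
        subgroup.  The assignment is a fixed representative of the
        (exchangeable) randomization distribution.
        """
        arms = np.zeros(self.n_hospitals, dtype=int)
        if self.subgroup_labels is None:
            arms[: self.n_hospitals // 2] = 1
            return arms
        labels = np.asarray(self.subgroup_labels)
        for g in self.subgroups:
            idx = np.flatnonzero(labels == g)
            arms[idx[: len(idx) // 2]] = 1
        return arms

    def within_treated_mask(self) -> np.ndarray:
        """Boolean treated mask of shape (clinics, providers, participants).

        Valid for within-ISU randomization; the same pattern applies in
        every hospital (balance inside the immediate parent).
        """
        if self.randomization_level == "hospital":
            raise InvalidDesignError(
                "within_treated_mask undefined for hospital-level randomization"
            )
        C, P, S = self.n_clinics, self.n_providers, self.n_participants
        mask = np.zeros((C, P, S), dtype=bool)
        if self.randomization_level == "clinic":
            mask[: C // 2] = True
        elif self.randomization_level == "provider":
            mask[:, : P // 2] = True
        else:  # participant
            mask[:, :, : S // 2] = True
        return mask

    def with_randomization(self, level: str) -> "HierarchicalDesign":
        return HierarchicalDesign(
            self.n_hospitals,
            self.n_clinics,
            self.n_providers,
            self.n_participants,
            randomization_level=level,
            subgroup_labels=self.subgroup_labels,
        )


@dataclass(frozen=True)
class VarianceModel:
    """Three-level exchangeable covariance plus an outcome covariance.

    Total variance of one outcome on one participant is ``sigma2``;
    intraclass correlations ``rho_provider``, ``rho_clinic`` and
    ``rho_hospital`` partition it into additive random-effect components,
    leaving a residual share ``rho_residual = 1 - sum(rho)`` which must
    be positive.  Under the Kronecker model every variance component
    carries the same m x m outcome covariance ``Sigma``.
    """

    rho_provider: float = 0.05
    rho_clinic: float = 0.01
    rho_hospital: float = 0.01
    sigma2: float = 1.0
    Sigma: np.ndarray = None
    composite_weights: np.ndarray = None

    def __post_init__(self):
        for name in ("rho_provider", "rho_clinic", "rho_hospital"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise InvalidDesignError(f"{name} must lie in [0, 1), got {r}")
        if self.rho_provider + self.rho_clinic + self.rho_hospital >= 1.0:
            raise InvalidDesignError(
                "ICCs must sum to < 1 (positive residual variance required)"
            )
        if not self.sigma2 > 0:
            raise InvalidDesignError("sigma2 must be positive")
        Sigma = np.eye(8) if self.Sigma is None else _as_array(self.Sigma, "Sigma")
        if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
            raise InvalidDesignError("Sigma must be a square matrix")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10):
            raise InvalidDesignError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as exc:
            raise InvalidDesignError("Sigma must be positive definite") from exc
        m = Sigma.shape[0]
        if self.composite_weights is None:
            w = np.full(m, 1.0 / m)
        else:
            w = _as_array(self.composite_weights, "composite_weights")
        if w.shape != (m,):
            raise InvalidDesignError("composite_weights must have length m")
        if abs(w.sum() - 1.0) > 1e-8:
            raise InvalidDesignError(
                "composite_weights must sum to 1 (unweighted average uses 1/m)"
            )
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "composite_weights", w)

    @property
    def rho_residual(self) -> float:
        return 1.0 - self.rho_provider - self.rho_clinic - self.rho_hospital

    @property
    def m(self) -> int:
        """Number of outcomes."""
        return self.Sigma.shape[0]

    @property
    def composite_variance(self) -> float:
        """Variance scale of the weighted composite, w' Sigma w."""
        w = self.composite_weights
        return float(w @ self.Sigma @ w)


@dataclass(frozen=True)
class EffectSpec:
    """Intervention-minus-control mean differences per outcome (SD units)."""

    delta: np.ndarray

    def __post_init__(self):
        d = _as_array(self.delta, "delta")
        if d.ndim != 1:
            raise InvalidDesignError("delta must be a vector")
        object.__setattr__(self, "delta", d)

    @classmethod
    def single_outcome(cls, magnitude: float, affected_outcome: int = 0,
                       m: int = 8) -> "EffectSpec":
        """Effect shifting exactly one outcome's mean by ``magnitude`` SDs."""
        if not 0 <= affected_outcome < m:
            raise InvalidDesignError("affected_outcome out of range")
        d = np.zeros(m)
        d[affected_outcome] = magnitude
        return cls(d)

    @property
    def m(self) -> int:
        return self.delta.shape[0]

    def composite_effect(self, vm: VarianceModel) -> float:
        """Effect on the weighted composite, w' delta."""
        if self.m != vm.m:
            raise InvalidDesignError("effect dimension does not match Sigma")
        return float(vm.composite_weights @ self.delta)
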