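"""Noncentrality and power for the general linear hypothesis.

Power is computed for H0: C B U = Theta0 on a :class:`ReducedGLM`.
When either contrast rank is 1 the Hotelling–Lawley trace reduces to
Hotelling's T-squared (or a univariate F) and the noncentral-F power is
exact.  Otherwise the McKeon F approximation to the trace statistic is
used; its denominator df formula reduces algebraically to the exact
T-squared df whenever the between-contrast rank is 1, so every scenario
considered in this package is in the exact regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import InvalidDesignError
from .reduce import ReducedGLM

__all__ = ["PowerResult", "PowerCurve", "glh_noncentrality", "f_power",
           "hlt_mckeon_power", "power_curve", "default_grid", "mckeon_ddf",
           "SingularHypothesisError"]


class SingularHypothesisError(np.linalg.LinAlgError):
    """U' SigmaStar U is singular, or the hypothesis is not estimable."""


@dataclass(frozen=True)
class PowerResult:
    """Power of one general linear hypothesis test.

    ``ndf = a*b`` is the numerator df; ``ddf`` the denominator df
    (exact for min(a, b) = 1, McKeon's otherwise); ``noncentrality`` is
    the trace of the noncentrality matrix; ``approximate`` flags the
    a > 1, b > 1 regime where McKeon's formula is not exact.
    """

    alpha: float
    a: int
    b: int
    ndf: int
    ddf: float
    noncentrality: float
    power: float
    approximate: bool = False


@dataclass(frozen=True)
class PowerCurve:
    """Power along an ascending grid of effect magnitudes."""

    scenario: str
    grid: np.ndarray
    results: tuple

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) < 0):
            raise InvalidDesignError("grid must be nonempty and ascending")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "results", tuple(self.results))

    @property
    def powers(self) -> np.ndarray:
        return np.array([r.power for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": self.scenario,
            "effect": self.grid,
            "ndf": [r.ndf for r in self.results],
            "ddf": [r.ddf for r in self.results],
            "noncentrality": [r.noncentrality for r in self.results],
            "power": self.powers,
        })


def glh_noncentrality(glm: ReducedGLM) -> tuple[np.ndarray, float]:
    """Noncentrality matrix Omega and its trace lambda.

    Omega = (CBU - Theta0)' [C (X'X)^- C']^{-1} (CBU - Theta0)
            (U' SigmaStar U)^{-1},
    with X'X = diag(cell_counts) under cell-means coding.  lambda is
    invariant to nonsingular rescaling of the rows of C and the columns
    of U.
    """
    M = (glm.C / glm.cell_counts) @ glm.C.T
    Delta = glm.effect_matrix()
    E = glm.U.T @ glm.SigmaStar @ glm.U
    try:
        Minv_Delta = np.linalg.solve(M, Delta)
        Einv = np.linalg.inv(E)
    except np.linalg.LinAlgError as exc:
        raise SingularHypothesisError(str(exc)) from exc
    Omega = Delta.T @ Minv_Delta @ Einv
    lam = float(np.trace(Omega))
    if lam < -1e-8:
        raise SingularHypothesisError("negative noncentrality; U'SigmaStar U "
                                      "is not positive definite")
    return Omega, max(lam, 0.0)


def f_power(noncentrality: float, ndf: float, ddf: float,
            alpha: float) -> float:
    """P[F'(ndf, ddf, lambda) > F_crit(alpha; ndf, ddf)]."""
    if not (0.0 < alpha < 1.0):
        raise InvalidDesignError("alpha must lie in (0, 1)")
    if ndf <= 0 or ddf <= 0:
        raise InvalidDesignError("degrees of freedom must be positive")
    if noncentrality < 0:
        raise InvalidDesignError("noncentrality must be nonnegative")
    crit = stats.f.isf(alpha, ndf, ddf)
    return float(1.0 - special.ncfdtr(ndf, ddf, noncentrality, crit))


def mckeon_ddf(a: int, b: int, nu: int) -> float:
    """McKeon denominator df for the Hotelling–Lawley trace F approximation.

    df2 = 4 + (ab + 2) g with
    g = [nu^2 - nu(2b + 3) + b(b + 3)] / [nu(a + b + 1) - (a + 2b + b^2 - 1)].
    For a = 1 this equals nu - b + 1 exactly (the T-squared conversion).
    """
    den = nu * (a + b + 1) - (a + 2 * b + b * b - 1)
    if den <= 0:
        raise InvalidDesignError(
            f"error df nu={nu} too small for the McKeon approximation"
        )
    g = (nu * nu - nu * (2 * b + 3) + b * (b + 3)) / den
    return 4.0 + (a * b + 2.0) * g


def hlt_mckeon_power(glm: ReducedGLM, alpha: float = 0.05,
                     force_mckeon: bool = False) -> PowerResult:
    """Power of the Hotelling–Lawley trace test of H0: C B U = Theta0.

    Exact noncentral-F power when min(a, b) = 1 (ddf = nu for b = 1,
    nu - b + 1 for a = 1); the McKeon denominator df otherwise.
    ``force_mckeon`` routes the min(a, b) = 1 case through the general
    formula, which must agree with the exact branch.
    """
    a, b, nu = glm.a, glm.b, glm.error_df()
    _, lam = glh_noncentrality(glm)
    ndf = a * b
    approximate = False
    if min(a, b) == 1 and not force_mckeon:
        ddf = float(nu) if b == 1 else float(nu - b + 1)
    else:
        ddf = mckeon_ddf(a, b, nu)
        approximate = min(a, b) > 1
    if ddf <= 0:
        raise InvalidDesignError(
            f"nonpositive denominator df (nu={nu}, b={b})"
        )
    power = f_power(lam, ndf, ddf, alpha)
    return PowerResult(alpha=alpha, a=a, b=b, ndf=ndf, ddf=ddf,
                       noncentrality=lam, power=power,
                       approximate=approximate)


def power_curve(glm_factory, grid, alpha: float = 0.05,
                scenario: str = "") -> PowerCurve:
    """Evaluate power over a grid of effect magnitudes.

    ``glm_factory(delta)`` must return the ReducedGLM for effect
    magnitude ``delta``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidDesignError("effect grid must be nonempty")
    if np.any(grid < 0):
        raise InvalidDesignError("effect grid must be nonnegative")
    results = [hlt_mckeon_power(glm_factory(d), alpha=alpha) for d in grid]
    return PowerCurve(scenario=scenario, grid=grid, results=results)


def default_grid(delta_max: float = 1.0, n_points: int = 100) -> np.ndarray:
    """Evenly spaced effect grid [0, delta_max], 100 points by default."""
    if delta_max <= 0 or n_points < 1:
        raise InvalidDesignError("delta_max must be > 0 and n_points >= 1")
    return np.linspace(0.0, delta_max, n_points)
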