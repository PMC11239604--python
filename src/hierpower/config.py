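"""YAML/JSON configuration for designs, variance models and runs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .design import HierarchicalDesign, InvalidDesignError, VarianceModel

__all__ = ["default_config", "load_config", "save_config",
           "design_from_config", "variance_from_config"]


def default_config() -> dict:
    """The reference configuration: 20/8/6/6 hospitals, ICCs
    0.05/0.01/0.01, 8 independent unit-variance outcomes, alpha 0.05,
    10 rural + 10 urban hospitals, 100-point effect grid on [0, 1]."""
    return {
        "design": {
            "n_hospitals": 20,
            "n_clinics": 8,
            "n_providers": 6,
            "n_participants": 6,
            "randomization_level": "hospital",
            "subgroups": {"rural": 10, "urban": 10},
        },
        "variance": {
            "icc_provider": 0.05,
            "icc_clinic": 0.01,
            "icc_hospital": 0.01,
            "sigma2": 1.0,
            "n_outcomes": 8,
            "outcome_covariance": "identity",
            "composite_weights": "equal",
        },
        "effect": {"affected_outcome": 1},  # 1-based; outcome 1 is "diet"
        "alpha": 0.05,
        "grid": {"delta_max": 1.0, "n_points": 100},
    }


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def design_from_config(config: dict,
                       randomization_level: str | None = None
                       ) -> HierarchicalDesign:
    d = config.get("design", {})
    subgroups = d.get("subgroups")
    labels = None
    if subgroups:
        labels = tuple(g for g, n in subgroups.items() for _ in range(int(n)))
    return HierarchicalDesign(
        n_hospitals=int(d.get("n_hospitals", 20)),
        n_clinics=int(d.get("n_clinics", 8)),
        n_providers=int(d.get("n_providers", 6)),
        n_participants=int(d.get("n_participants", 6)),
        randomization_level=(randomization_level
                             or d.get("randomization_level", "hospital")),
        subgroup_labels=labels,
    )


def variance_from_config(config: dict) -> VarianceModel:
    v = config.get("variance", {})
    m = int(v.get("n_outcomes", 8))
    cov = v.get("outcome_covariance", "identity")
    Sigma = np.eye(m) if (cov is None or cov == "identity") \
        else np.asarray(cov, dtype=float)
    wspec = v.get("composite_weights", "equal")
    weights = None if (wspec is None or wspec == "equal") \
        else np.asarray(wspec, dtype=float)
    return VarianceModel(
        rho_provider=float(v.get("icc_provider", 0.05)),
        rho_clinic=float(v.get("icc_clinic", 0.01)),
        rho_hospital=float(v.get("icc_hospital", 0.01)),
        sigma2=float(v.get("sigma2", 1.0)),
        Sigma=Sigma,
        composite_weights=weights,
    )


def affected_outcome_from_config(config: dict) -> int:
    """0-based index of the shifted outcome (stored 1-based in config)."""
    idx = int(config.get("effect", {}).get("affected_outcome", 1)) - 1
    if idx < 0:
        raise InvalidDesignError("affected_outcome is 1-based")
    return idx
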