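"""Configuration parsing, validation, fixtures and result serialization.

The YAML/JSON config dialect describes a stack of rings; every physical
quantity carries an explicit unit suffix in its key name so that a config
file is unambiguous about the lambda/Gamma0 unit system:

.. code-block:: yaml

    rings:
      - N: 9
        R_over_lambda: 0.05      # or d_over_lambda (exactly one of the two)
        z_over_lambda: 0.0
        delta_rad: 0.0
        theta_rad: 0.0
        phi_rad: 0.0
        detuning_Gamma0: 0.0
        label: ring1

Unknown keys are rejected.  Named fixtures reproduce the parameter sets of
the reference geometries used throughout the analyses (small and large
single rings, stacked identical rings, rotated/unequal double rings and the
approximate LH2 motif).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ringexciton.geometry import (
    EmitterArray,
    RingSpec,
    StackSpec,
    build_stack,
    lh2_default_params,
    polarization_angles,
)

__all__ = [
    "RunConfig",
    "load_config",
    "parse_config",
    "serialize_config",
    "save_config",
    "fixture",
    "fixture_names",
    "export_geometry",
]

logger = logging.getLogger("ringexciton")

_RING_KEYS = {
    "N",
    "R_over_lambda",
    "d_over_lambda",
    "z_over_lambda",
    "delta_rad",
    "theta_rad",
    "phi_rad",
    "detuning_Gamma0",
    "label",
}
_RING_DEFAULTS = {
    "z_over_lambda": 0.0,
    "delta_rad": 0.0,
    "theta_rad": 0.0,
    "phi_rad": 0.0,
    "detuning_Gamma0": 0.0,
}
_TOP_KEYS = {"rings", "experiment", "name"}


@dataclass
class RunConfig:
    """Validated geometry plus optional experiment parameters."""

    stack: StackSpec
    experiment: dict = field(default_factory=dict)
    name: str = ""

    def build(self) -> EmitterArray:
        return build_stack(self.stack)


def _parse_ring(entry: dict, idx: int, errors: list[str]) -> RingSpec | None:
    unknown = set(entry) - _RING_KEYS
    if unknown:
        errors.append(f"rings[{idx}]: unknown keys {sorted(unknown)}")
    if "N" not in entry:
        errors.append(f"rings[{idx}]: missing required key 'N'")
    has_r = "R_over_lambda" in entry
    has_d = "d_over_lambda" in entry
    if has_r and has_d:
        errors.append(
            f"rings[{idx}]: both R_over_lambda and d_over_lambda given (ambiguous)"
        )
    if not (has_r or has_d):
        errors.append(f"rings[{idx}]: one of R_over_lambda or d_over_lambda required")
    if errors:
        return None
    vals = {**_RING_DEFAULTS, **entry}
    try:
        common = dict(
            z=float(vals["z_over_lambda"]),
            delta=float(vals["delta_rad"]),
            theta=float(vals["theta_rad"]),
            phi=float(vals["phi_rad"]),
            detuning=float(vals["detuning_Gamma0"]),
        )
        if has_r:
            spec = RingSpec(N=int(vals["N"]), R=float(vals["R_over_lambda"]), **common)
        else:
            spec = RingSpec.from_lattice_constant(
                N=int(vals["N"]), d=float(vals["d_over_lambda"]), **common
            )
    except (ValueError, TypeError) as exc:
        errors.append(f"rings[{idx}]: {exc}")
        return None
    return spec


def parse_config(raw: dict) -> RunConfig:
    """Validate a config mapping, raising one error listing every problem."""
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")
    rings_raw = raw.get("rings")
    if not rings_raw:
        errors.append("config must define a non-empty 'rings' list")
        raise ValueError("invalid config: " + "; ".join(errors))
    specs = []
    labels = []
    for idx, entry in enumerate(rings_raw):
        ring_errors: list[str] = []
        spec = _parse_ring(dict(entry), idx, ring_errors)
        errors.extend(ring_errors)
        if spec is not None:
            specs.append(spec)
            labels.append(entry.get("label", f"ring{idx + 1}"))
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    try:
        stack = StackSpec(rings=tuple(specs), labels=tuple(labels))
    except ValueError as exc:
        raise ValueError(f"invalid config: {exc}") from None
    cfg = RunConfig(
        stack=stack,
        experiment=dict(raw.get("experiment") or {}),
        name=str(raw.get("name", "")),
    )
    for spec, label in zip(stack.rings, stack.labels):
        logger.info(
            "ring %s: N=%d R/lambda=%.6g d/lambda=%.6g z/lambda=%.6g delta=%.6g "
            "theta=%.6g phi=%.6g detuning=%.6g",
            label, spec.N, spec.R, spec.d, spec.z, spec.delta, spec.theta,
            spec.phi, spec.detuning,
        )
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON, a YAML subset) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def serialize_config(cfg: RunConfig) -> dict:
    """Round-trippable mapping: parse_config(serialize_config(c)) == c."""
    rings = []
    for spec, label in zip(cfg.stack.rings, cfg.stack.labels):
        rings.append(
            {
                "N": spec.N,
                "R_over_lambda": spec.R,
                "z_over_lambda": spec.z,
                "delta_rad": spec.delta,
                "theta_rad": spec.theta,
                "phi_rad": spec.phi,
                "detuning_Gamma0": spec.detuning,
                "label": label,
            }
        )
    out: dict = {"rings": rings}
    if cfg.experiment:
        out["experiment"] = dict(cfg.experiment)
    if cfg.name:
        out["name"] = cfg.name
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_config(cfg), fh, sort_keys=False)


def export_geometry(array: EmitterArray, path: str | Path) -> None:
    """Write the built geometry as CSV (x, y, z, px, py, pz, detuning, cell, component)."""
    df = pd.DataFrame(array.positions, columns=["x", "y", "z"])
    df[["px", "py", "pz"]] = array.dipoles
    df["detuning"] = array.detunings
    df["cell"] = array.cell_index
    df["component"] = array.component_index
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Named fixtures for the reference geometries
# --------------------------------------------------------------------------

def _ring_entry(N, *, R=None, d=None, z=0.0, delta=0.0, pol="transverse",
                theta=None, phi=None, detuning=0.0, label=None) -> dict:
    if theta is None or phi is None:
        theta, phi = polarization_angles(pol)
    e = {
        "N": N,
        "z_over_lambda": z,
        "delta_rad": delta,
        "theta_rad": theta,
        "phi_rad": phi,
        "detuning_Gamma0": detuning,
    }
    if R is not None:
        e["R_over_lambda"] = R
    else:
        e["d_over_lambda"] = d
    if label:
        e["label"] = label
    return e


def _double(N, R, z, pol, delta2=0.0, R2=None):
    return [
        _ring_entry(N, R=R, pol=pol, label="ring1"),
        _ring_entry(N, R=R2 if R2 is not None else R, z=z, delta=delta2,
                    pol=pol, label="ring2"),
    ]


def _fixture_registry() -> dict[str, dict]:
    pi = math.pi
    reg: dict[str, dict] = {}
    # large dense ring: quasi-linear chain regime, light line m0 = N d/lambda
    reg["fig2_large"] = {"rings": [_ring_entry(100, d=1 / 3, pol="radial")]}
    # small ring, Dicke regime: R = 0.05 lambda (one bright mode at m=0 for
    # transverse polarization at ~N*Gamma0, two at m=+-1 for in-plane)
    reg["fig2_dicke"] = {"rings": [_ring_entry(20, R=0.05, pol="transverse")]}
    for pol in ("transverse", "radial", "tangential"):
        reg[f"fig3_{pol}"] = {"rings": _double(9, 0.05, 0.025, pol)}
    reg["fig3"] = reg["fig3_transverse"]
    reg["fig4"] = {
        "rings": _double(9, (1 / 3) / (2 * math.sin(pi / 9)), 0.009, "transverse"),
        "experiment": {
            "name": "scaling",
            "d_over_lambda": 1 / 3,
            "z_over_lambda": 0.009,
            "polarization": "transverse",
            "N_list": [6, 8, 10, 12, 14],
        },
    }
    reg["fig5"] = {
        "rings": _double(9, 0.05 / (2 * math.sin(pi / 9)), 0.05, "transverse"),
        "experiment": {
            "name": "landscape",
            "N": 9,
            "polarization": "transverse",
            "d_min": 0.08, "d_max": 1.0, "z_min": 0.08, "z_max": 1.0,
            "points": 25,
        },
    }
    reg["fig6_7"] = {
        "rings": _double(9, 0.1 / (2 * math.sin(pi / 9)), 0.2, "tangential")
    }
    reg["fig8_top"] = {
        "rings": _double(9, 0.05, 0.005, "transverse"),
        "experiment": {"name": "delta-sweep", "m": 4},
    }
    reg["fig8_bottom"] = {
        "rings": _double(9, 0.05, 0.0, "tangential", R2=0.045),
        "experiment": {"name": "delta-sweep", "m": 4},
    }
    lh2 = lh2_default_params()
    reg["lh2_fixture"] = {
        "rings": [
            _ring_entry(
                lh2["N"],
                R=c["R"], z=c["z"], delta=c["delta"],
                theta=c["theta"], phi=c["phi"], detuning=c["detuning"],
                label=label,
            )
            for c, label in (
                (lh2["b850a"], "B850a"),
                (lh2["b850b"], "B850b"),
                (lh2["b800"], "B800"),
            )
        ]
    }
    return reg


_FIXTURES = _fixture_registry()


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str) -> RunConfig:
    """Return the named reference geometry as a validated RunConfig."""
    try:
        raw = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    cfg = parse_config({**raw, "name": name})
    return cfg
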