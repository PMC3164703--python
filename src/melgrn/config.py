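"""Run configuration: structured-text (YAML) loading, strict validation,
reproducibility metadata.

A configuration resolves to the model variant, the full parameter set,
the genotype, the integration grid, the detection thresholds, a seed and
an output directory, plus an optional free-form ``scenario`` block whose
keys are validated by the command that consumes it.  Unknown keys are
rejected at every level, and every run emits the resolved configuration
with a content hash next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .core import Genotype, RegulatoryParameters
from .reference import (
    DEFAULT_DT,
    DEFAULT_T0,
    DEFAULT_T1,
    R_MIN,
    T_LATE,
    THETA_DET,
    reference_parameters,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "write_json_atomic",
           "write_text_atomic", "GENOTYPE_PRESETS"]


class ConfigError(ValueError):
    """A configuration failed schema validation (message names the field)."""


GENOTYPE_PRESETS: Dict[str, Genotype] = {
    "wt": Genotype.wild_type(),
    "wild_type": Genotype.wild_type(),
    "mitfa_null": Genotype.mitfa_null(),
    "sox10_null": Genotype.sox10_null(),
    "double_null": Genotype.double_null(),
}

_TOP_KEYS = {"variant", "params", "genotype", "integration", "thresholds",
             "scenario", "seed", "output_dir"}
_INTEGRATION_KEYS = {"t0", "t1", "dt"}
_THRESHOLD_KEYS = {"theta_det", "r_min", "t_late"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    variant: str = "C"
    params: RegulatoryParameters = field(default_factory=reference_parameters)
    genotype: Genotype = field(default_factory=Genotype.wild_type)
    t0: float = DEFAULT_T0
    t1: float = DEFAULT_T1
    dt: float = DEFAULT_DT
    theta_det: float = THETA_DET
    r_min: float = R_MIN
    t_late: float = T_LATE
    scenario: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "melgrn_out"

    def to_dict(self) -> dict:
        """Resolved configuration content (excludes the output location,
        so reruns into different directories hash identically)."""
        return {
            "variant": self.variant,
            "params": self.params.to_dict(),
            "genotype": self.genotype.to_dict(),
            "integration": {"t0": self.t0, "t1": self.t1, "dt": self.dt},
            "thresholds": {"theta_det": self.theta_det, "r_min": self.r_min,
                           "t_late": self.t_late},
            "scenario": self.scenario,
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: Optional[str] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Load and validate a YAML configuration (missing blocks -> defaults)."""
    data: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    _reject_unknown(data, _TOP_KEYS, "configuration")

    variant = str(data.get("variant", "C"))
    if variant not in ("A", "B", "C"):
        raise ConfigError(f"variant must be A, B or C, got {variant!r}")

    params_block = data.get("params")
    if params_block is None:
        params = reference_parameters()
    else:
        base = reference_parameters().to_dict()
        _reject_unknown(params_block, set(base), "params")
        base.update(params_block)
        try:
            params = RegulatoryParameters.from_dict(base)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"params: {exc}") from exc

    genotype_block = data.get("genotype", "wt")
    if isinstance(genotype_block, str):
        try:
            genotype = GENOTYPE_PRESETS[genotype_block]
        except KeyError:
            raise ConfigError(
                f"unknown genotype preset {genotype_block!r}; "
                f"choose from {sorted(GENOTYPE_PRESETS)}") from None
    else:
        try:
            genotype = Genotype.from_dict(genotype_block)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"genotype: {exc}") from exc

    integration = dict(data.get("integration", {}))
    _reject_unknown(integration, _INTEGRATION_KEYS, "integration")
    thresholds = dict(data.get("thresholds", {}))
    _reject_unknown(thresholds, _THRESHOLD_KEYS, "thresholds")

    scenario = data.get("scenario", {})
    if not isinstance(scenario, dict):
        raise ConfigError("scenario must be a mapping")

    return RunConfig(
        variant=variant,
        params=params,
        genotype=genotype,
        t0=float(integration.get("t0", DEFAULT_T0)),
        t1=float(integration.get("t1", DEFAULT_T1)),
        dt=float(integration.get("dt", DEFAULT_DT)),
        theta_det=float(thresholds.get("theta_det", THETA_DET)),
        r_min=float(thresholds.get("r_min", R_MIN)),
        t_late=float(thresholds.get("t_late", T_LATE)),
        scenario=scenario,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "melgrn_out")),
    )


def write_text_atomic(path, text: str) -> None:
    """Write a text artifact atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(path, obj) -> None:
    write_text_atomic(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
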