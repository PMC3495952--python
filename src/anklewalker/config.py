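"""Run configuration: YAML/JSON parsing with strict validation.

A config file has up to four blocks::

    model:     {m, L, l, g, alpha, mu, k}          # defaults = standard set
    numerics:  {tol, eps_cap, max_samples, strict_grf}
    pulse:     {amplitude or amplitude_fraction, width, period, offset,
                perturbed_leg, gating_policy}
    experiment: {kind: simulate|stepmap|entrain|scan|vphase, ...}

Unknown keys are rejected with field-level messages.  Every run embeds
the fully-resolved configuration in its output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import Leg, NumericsConfig
from .entrainment import GatingPolicy, PulseTrain
from .params import WalkerParams

__all__ = ["RunConfig", "load_config", "resolved_dict", "config_hash"]

_NUMERICS_KEYS = {"tol", "eps_cap", "max_samples", "strict_grf"}
_PULSE_KEYS = {
    "amplitude",
    "amplitude_fraction",
    "width",
    "period",
    "offset",
    "perturbed_leg",
    "gating_policy",
}
_TOP_KEYS = {"model", "numerics", "pulse", "experiment", "output"}

_POLICIES = {
    "truncate": GatingPolicy.TRUNCATE_AT_MU,
    "truncate_at_mu": GatingPolicy.TRUNCATE_AT_MU,
    "extend": GatingPolicy.EXTEND_WHILE_POSITIVE,
    "extend_while_positive": GatingPolicy.EXTEND_WHILE_POSITIVE,
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    model: WalkerParams
    numerics: NumericsConfig
    pulse: PulseTrain | None
    experiment: dict[str, Any]
    output: dict[str, Any]


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{where}' block: {sorted(unknown)}")


def parse_policy(value: Any) -> GatingPolicy:
    if isinstance(value, GatingPolicy):
        return value
    try:
        return _POLICIES[str(value).lower()]
    except KeyError:
        raise ValueError(
            f"gating_policy must be one of {sorted(_POLICIES)}, got {value!r}"
        ) from None


def _build_pulse(block: Mapping[str, Any], model: WalkerParams) -> PulseTrain:
    _check_keys(block, _PULSE_KEYS, "pulse")
    if "amplitude" in block and "amplitude_fraction" in block:
        raise ValueError("give either pulse.amplitude or pulse.amplitude_fraction")
    if "amplitude" in block:
        amplitude = float(block["amplitude"])
    else:
        amplitude = float(block.get("amplitude_fraction", 0.1)) * model.peak_spring_torque
    leg = block.get("perturbed_leg", "LEG_A")
    leg = Leg[leg] if isinstance(leg, str) else Leg(leg)
    return PulseTrain(
        amplitude=amplitude,
        width=float(block.get("width", 0.1)),
        period=float(block.get("period", 2.0)),
        offset=float(block.get("offset", 0.0)),
        perturbed_leg=leg,
        gating_policy=parse_policy(block.get("gating_policy", "truncate")),
    )


def from_mapping(data: Mapping[str, Any]) -> RunConfig:
    _check_keys(data, _TOP_KEYS, "top-level")
    model = WalkerParams.from_mapping(data.get("model"))
    num_block = dict(data.get("numerics") or {})
    _check_keys(num_block, _NUMERICS_KEYS, "numerics")
    numerics = NumericsConfig(**num_block)
    pulse = None
    if data.get("pulse"):
        pulse = _build_pulse(data["pulse"], model)
    return RunConfig(
        model=model,
        numerics=numerics,
        pulse=pulse,
        experiment=dict(data.get("experiment") or {}),
        output=dict(data.get("output") or {}),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return from_mapping(data)


def resolved_dict(config: RunConfig) -> dict[str, Any]:
    """Fully-resolved configuration as plain JSON-serialisable data."""
    out: dict[str, Any] = {
        "model": dataclasses.asdict(config.model),
        "numerics": dataclasses.asdict(config.numerics),
        "experiment": config.experiment,
        "output": config.output,
    }
    if config.pulse is not None:
        p = dataclasses.asdict(config.pulse)
        p["perturbed_leg"] = config.pulse.perturbed_leg.name
        p["gating_policy"] = config.pulse.gating_policy.name
        out["pulse"] = p
    else:
        out["pulse"] = None
    return out


def config_hash(config: RunConfig) -> str:
    """Short deterministic hash of the resolved configuration."""
    blob = json.dumps(resolved_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
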