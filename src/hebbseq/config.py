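"""Validated experiment configuration.

A single YAML file specifies an experiment: transfer function family and
parameters, network connectivity, plasticity rules with enable flags,
stimulation protocol, and integration settings.  Unknown keys are
rejected, invalid parameter combinations are reported with the path of
the offending key, and every value not present in the file is filled
from the defaults and recorded in the provenance list.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .dynamics import NetworkConfig
from .plasticity import HebbianParams, HomeostaticParams
from .protocol import SequentialStimulation
from .transfer import TransferFunction, from_config

__all__ = ["ExperimentConfig", "load_config", "dump_config", "ConfigError"]

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class TransferBlock(_Block):
    family: Literal["sigmoid", "pl", "pnl"] = "pl"
    a: float | None = None
    b: float | None = None
    nu: float | None = None
    theta: float | None = None
    u_c: float | None = None
    nu_t: float | None = None
    theta_t: float | None = None
    u_ct: float | None = None

    def build(self) -> TransferFunction:
        params = {
            k: v
            for k, v in self.model_dump().items()
            if k != "family" and v is not None
        }
        try:
            return from_config(self.family, **params)
        except ValueError as e:
            raise ConfigError(f"transfer: {e}") from e


class NetworkBlock(_Block):
    n: int = 10
    tau: float = 10.0
    tau_I: float = 1.0
    w: float = 0.0
    s: float = 0.0
    w_I: float | None = None
    w_EI: float | None = None
    w_IE: float | None = None
    variant: Literal["excitatory", "full_inhibition", "reduced_inhibition"] = (
        "reduced_inhibition"
    )

    def build(self) -> NetworkConfig:
        try:
            return NetworkConfig(**self.model_dump())
        except ValueError as e:
            raise ConfigError(f"network: {e}") from e


class HebbianBlock(_Block):
    enabled: bool = True
    w_max: float = 3.0
    D: float = 12.0
    T_w: float = 2000.0
    r_w: float = 0.4
    a_pre: float = 10.0
    b_pre: float = 0.5
    a_post: float = 10.0
    b_post: float = 0.5

    def build(self) -> HebbianParams | None:
        if not self.enabled:
            return None
        try:
            return HebbianParams(**self.model_dump(exclude={"enabled"}))
        except ValueError as e:
            raise ConfigError(f"plasticity.hebbian: {e}") from e


class NormalizationBlock(_Block):
    enabled: bool = False
    C: float = 3.0  # conserved row sum of the initial weight matrix


class HomeostaticBlock(_Block):
    enabled: bool = False
    tau_H: float = 20000.0
    r_0: float = 0.08

    def build(self) -> HomeostaticParams | None:
        if not self.enabled:
            return None
        try:
            return HomeostaticParams(tau_H=self.tau_H, r_0=self.r_0)
        except ValueError as e:
            raise ConfigError(f"plasticity.homeostatic: {e}") from e


class NoiseBlock(_Block):
    sigma: float = Field(0.0, ge=0.0)


class PlasticityBlock(_Block):
    hebbian: HebbianBlock = HebbianBlock()
    normalization: NormalizationBlock = NormalizationBlock()
    homeostatic: HomeostaticBlock = HomeostaticBlock()
    noise: NoiseBlock = NoiseBlock()


class ProtocolBlock(_Block):
    T: float = 19.0
    Delta: float = 10.0
    I_amp: float = 6.0
    k: int = 100
    gap: float = 100.0
    u_bg: float = 0.0

    def build(self) -> SequentialStimulation:
        try:
            return SequentialStimulation(**self.model_dump())
        except ValueError as e:
            raise ConfigError(f"protocol: {e}") from e


class IntegrationBlock(_Block):
    dt: float = Field(0.1, gt=0.0)
    duration: float = Field(1000.0, gt=0.0)
    stride: int = Field(10, ge=1)


class ExperimentConfig(_Block):
    """Top-level validated configuration with provenance tracking."""

    schema_version: str = SCHEMA_VERSION
    seed: int = 0
    transfer: TransferBlock = TransferBlock()
    network: NetworkBlock = NetworkBlock()
    plasticity: PlasticityBlock = PlasticityBlock()
    protocol: ProtocolBlock = ProtocolBlock()
    integration: IntegrationBlock = IntegrationBlock()

    @model_validator(mode="after")
    def _check_version(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        return self

    def content_hash(self) -> str:
        """Stable hash of the normalized configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _defaulted_keys(model: BaseModel, prefix: str = "") -> list[str]:
    out = []
    for name, field in type(model).model_fields.items():
        path = f"{prefix}{name}"
        value = getattr(model, name)
        if isinstance(value, BaseModel):
            if name in model.model_fields_set:
                out.extend(_defaulted_keys(value, path + "."))
            else:
                out.append(path)
        elif name not in model.model_fields_set:
            out.append(path)
    return out


def load_config(path: str | Path) -> tuple[ExperimentConfig, list[str]]:
    """Load and validate a YAML experiment configuration.

    Returns the validated config and the list of keys that were filled
    from defaults (provenance).  Schema violations raise ``ConfigError``
    naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = ExperimentConfig.model_validate(raw)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"{path}: {loc}: {first['msg']}") from e
    # building the domain objects surfaces cross-field violations
    cfg.transfer.build()
    cfg.network.build()
    cfg.plasticity.hebbian.build()
    cfg.plasticity.homeostatic.build()
    cfg.protocol.build()
    return cfg, _defaulted_keys(cfg)


def dump_config(cfg: ExperimentConfig, path: str | Path | None = None) -> str:
    """Serialize a config (all defaults made explicit) to YAML."""
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
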