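"""Run configuration (YAML + CLI overrides) and JSON report writing.

Configuration is a flat-ish YAML document with one nesting level; CLI flags
override file values. Every run can write its fully-resolved configuration
into the JSON report so results are reproducible from the report alone.
All randomness flows from the single top-level ``seed`` through numpy
SeedSequence spawning.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .errors import ConfigError
from .observables import DCParameters, TensorParameters
from .restraints import RestraintConfig, FORCE_CONSTANT_TABLE
from .structures import PentamerBlueprint, PLN_SEQUENCE

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TensorSection(_Section):
    delta11: float = 64.0
    delta22: float = 76.0
    delta33: float = 216.9
    delta11_gly: float = 46.5
    delta22_gly: float = 66.3
    delta33_gly: float = 211.6
    pas_tilt_deg: float = 17.0
    zeta_dc: float = 10.52


class RestraintSection(_Section):
    alpha_csa: Optional[float] = None   # None -> calibration-table default
    alpha_dc: Optional[float] = None
    averaging: str = "replica_internal"
    replicas: int = 16
    ramp_steps: int = 0
    signed_dc: bool = True


class DomainSection(_Section):
    Ia: tuple[int, int] = (1, 16)
    Ib: tuple[int, int] = (17, 30)
    II: tuple[int, int] = (31, 52)


class BlueprintSection(_Section):
    protomers: int = 5
    sequence: str = PLN_SEQUENCE
    first_index: int = 1
    tm_range: tuple[int, int] = (31, 52)
    cyto_range: Optional[tuple[int, int]] = (1, 30)
    tau_deg: float = 12.8
    theta_deg: float = 98.8
    bundle_radius: float = 8.0


class SamplerSection(_Section):
    n_steps: int = 500
    kT: float = 2494.0
    record_every: int = 10


class RunConfig(_Section):
    seed: int = 0
    log_level: str = "INFO"
    tensor: TensorSection = TensorSection()
    restraints: RestraintSection = RestraintSection()
    domains: DomainSection = DomainSection()
    blueprint: BlueprintSection = BlueprintSection()
    sampler: SamplerSection = SamplerSection()

    # -- factories for the domain objects ----------------------------------
    def tensor_parameters(self) -> TensorParameters:
        t = self.tensor
        return TensorParameters(
            delta11=t.delta11, delta22=t.delta22, delta33=t.delta33,
            delta11_gly=t.delta11_gly, delta22_gly=t.delta22_gly,
            delta33_gly=t.delta33_gly, pas_tilt_deg=t.pas_tilt_deg)

    def dc_parameters(self) -> DCParameters:
        return DCParameters(zeta_dc=self.tensor.zeta_dc)

    def restraint_config(self) -> RestraintConfig:
        r = self.restraints
        base = RestraintConfig.from_table(r.replicas, r.averaging, r.ramp_steps)
        return RestraintConfig(
            alpha_csa=base.alpha_csa if r.alpha_csa is None else r.alpha_csa,
            alpha_dc=base.alpha_dc if r.alpha_dc is None else r.alpha_dc,
            averaging=r.averaging, M=r.replicas, ramp_steps=r.ramp_steps)

    def pentamer_blueprint(self, seed: Optional[int] = None) -> PentamerBlueprint:
        b = self.blueprint
        return PentamerBlueprint(
            n_protomers=b.protomers, sequence=b.sequence,
            first_index=b.first_index, tm_range=tuple(b.tm_range),
            cyto_range=None if b.cyto_range is None else tuple(b.cyto_range),
            tau_deg=b.tau_deg, theta_deg=b.theta_deg,
            bundle_radius=b.bundle_radius,
            seed=self.seed if seed is None else seed)

    def domain_dict(self) -> dict:
        return {"Ia": tuple(self.domains.Ia), "Ib": tuple(self.domains.Ib),
                "II": tuple(self.domains.II)}

    def spawn_seed(self, stream: int) -> int:
        """Derive a sub-stream seed (< 2^31) from the top-level seed."""
        child = np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        return int(child.generate_state(1)[0] % (2 ** 31))


def _merge(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if value is None:
            continue
        if "." in key:
            head, rest = key.split(".", 1)
            out[head] = _merge(out.get(head, {}) or {}, {rest: value})
        elif isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load, merge and validate a run configuration.

    ``overrides`` may use dotted keys ("restraints.alpha_csa"). Unknown keys
    raise ConfigError naming the offending key.
    """
    data: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
    if overrides:
        data = _merge(data, overrides)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors())
        raise ConfigError(f"invalid configuration: {details}") from exc


def run_report(results: dict, path, config: Optional[RunConfig] = None,
               make_parents: bool = True) -> dict:
    """Write a schema-versioned JSON report; returns the written payload."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "tool": "oligorient",
        "version": __version__,
        "config": None if config is None else config.model_dump(),
        "results": results,
    }
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        if make_parents:
            os.makedirs(parent, exist_ok=True)
        else:
            raise ConfigError(f"parent directory does not exist: {parent}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)
        fh.write("\n")
    return payload


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
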