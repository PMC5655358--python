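"""Default parameter set and configuration file handling.

The configuration dialect is flat INI-style key-value text with explicit
units in key names, grouped into sections ``[morphology]``, ``[release]``,
``[receptors]``, ``[uptake]``, ``[membrane]``, ``[pumpglia]``, ``[rest]``,
``[protocol]``, ``[solver]``, ``[events]``.  A packaged defaults file
reproduces the model's standard configuration; user files override
individual keys.
"""

from __future__ import annotations

import configparser
import hashlib
import io
from dataclasses import dataclass, field, fields
from pathlib import Path

from .glutamate import ReceptorParams, ReleaseParams, UptakeParams
from .ions import PumpGliaParams
from .model import MembraneParams, RestingComposition, SDModel, default_morphology
from .morphology import Morphology, cleft_geometry
from .protocols import Protocol, impaired_uptake, ogd_protocol, perfusion_protocol

#: R_max (fmol/ms per synapse) frozen from the one-AP release calibration
#: (integral of the release flux over one simulated action potential equals
#: 3,000 molecules); see simulation.calibrated_release.
R_MAX_DEFAULT = 8.513526e-06


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


def default_release() -> ReleaseParams:
    return ReleaseParams(R_max=R_MAX_DEFAULT)


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol_scale: float = 1e-10
    sample_dt_ms: float = 10.0
    method: str = "LSODA"


@dataclass(frozen=True)
class EventSettings:
    baseline_window_ms: float = 5_000.0
    depol_threshold_mv: float = -30.0
    persistence_ms: float = 5_000.0
    repol_tolerance_mv: float = 2.0


@dataclass(frozen=True)
class ProtocolSettings:
    kind: str = "perfusion"  # perfusion | ogd | baseline
    k_bath_high_mm: float = 15.0
    k_bath_rest_mm: float = 4.0
    t_on_ms: float = 0.0
    ogd_t_start_ms: float = 10_000.0
    ogd_ramp_ms: float = 15_000.0
    ogd_hold_ms: float = 40_000.0
    ogd_shape: str = "linear"
    uptake_fraction: float = 1.0
    t_end_ms: float = 300_000.0

    def __post_init__(self) -> None:
        if self.kind not in ("perfusion", "ogd", "baseline"):
            raise ConfigError(f"protocol.kind must be perfusion|ogd|baseline, got {self.kind!r}")
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ConfigError(
                f"protocol.uptake_fraction out of [0, 1]: {self.uptake_fraction}"
            )

    def build(self) -> Protocol:
        if self.kind == "perfusion":
            base = perfusion_protocol(self.k_bath_high_mm, self.t_on_ms, self.k_bath_rest_mm)
        elif self.kind == "ogd":
            base = ogd_protocol(
                self.ogd_t_start_ms, self.ogd_ramp_ms, self.ogd_hold_ms,
                self.k_bath_rest_mm, self.ogd_shape,
            )
        else:
            from .protocols import baseline_protocol

            base = baseline_protocol(self.k_bath_rest_mm)
        return impaired_uptake(base, self.uptake_fraction)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    morphology_r_um: float = 0.2
    morphology_h_um: float = 0.0  # 0 -> derived from the envelope calibration
    release: ReleaseParams = field(default_factory=default_release)
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    pumpglia: PumpGliaParams = field(default_factory=PumpGliaParams)
    rest: RestingComposition = field(default_factory=RestingComposition)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    events: EventSettings = field(default_factory=EventSettings)
    literal_recycling: bool = False

    def morphology(self) -> Morphology:
        if self.morphology_h_um > 0.0:
            return cleft_geometry(self.morphology_r_um, self.morphology_h_um)
        from .glutamate import envelope_volume_for_increment, height_for_envelope

        h = height_for_envelope(envelope_volume_for_increment(), self.morphology_r_um)
        return cleft_geometry(self.morphology_r_um, h)

    def build_model(self) -> SDModel:
        return SDModel(
            morph=self.morphology(),
            membrane=self.membrane,
            pumpglia=self.pumpglia,
            release=self.release,
            receptors=self.receptors,
            uptake=self.uptake,
            rest=self.rest,
            literal_recycling=self.literal_recycling,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SECTIONS = {
    "release": ("release", ReleaseParams),
    "receptors": ("receptors", ReceptorParams),
    "uptake": ("uptake", UptakeParams),
    "membrane": ("membrane", MembraneParams),
    "pumpglia": ("pumpglia", PumpGliaParams),
    "rest": ("rest", RestingComposition),
    "protocol": ("protocol", ProtocolSettings),
    "solver": ("solver", SolverSettings),
    "events": ("events", EventSettings),
}


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to the INI dialect (lossless round-trip)."""
    cp = configparser.ConfigParser()
    cp["morphology"] = {
        "r_um": repr(cfg.morphology_r_um),
        "h_um": repr(cfg.morphology_h_um),
    }
    cp["model"] = {"literal_recycling": str(cfg.literal_recycling)}
    for section, (attr, _) in _SECTIONS.items():
        obj = getattr(cfg, attr)
        cp[section] = {
            f.name: repr(getattr(obj, f.name)) for f in fields(obj)
        }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def _parse_value(raw: str, target_type):
    raw = raw.strip()
    if target_type is bool:
        if raw in ("True", "true", "1"):
            return True
        if raw in ("False", "false", "0"):
            return False
        raise ConfigError(f"invalid boolean {raw!r}")
    if target_type is str:
        return raw.strip("'\"")
    return target_type(raw)


def loads_config(text: str) -> RunConfig:
    """Parse the INI dialect; unknown keys or invalid values are rejected."""
    cp = configparser.ConfigParser()
    cp.read_string(text)
    kwargs = {}
    if cp.has_section("morphology"):
        sec = cp["morphology"]
        for key in sec:
            if key not in ("r_um", "h_um"):
                raise ConfigError(f"unknown key morphology.{key}")
        kwargs["morphology_r_um"] = float(sec.get("r_um", "0.2"))
        kwargs["morphology_h_um"] = float(sec.get("h_um", "0.0"))
    if cp.has_section("model"):
        sec = cp["model"]
        for key in sec:
            if key != "literal_recycling":
                raise ConfigError(f"unknown key model.{key}")
        kwargs["literal_recycling"] = _parse_value(sec["literal_recycling"], bool)
    for section, (attr, cls) in _SECTIONS.items():
        if not cp.has_section(section):
            continue
        # configparser lowercases keys; match field names case-insensitively
        valid = {f.name.lower(): f for f in fields(cls)}
        values = {}
        for key, raw in cp[section].items():
            if key not in valid:
                raise ConfigError(f"unknown key {section}.{key}")
            fld = valid[key]
            target = {"float": float, "int": int, "bool": bool, "str": str}.get(
                str(fld.type), float
            )
            try:
                values[fld.name] = _parse_value(raw, target)
            except (TypeError, ValueError) as err:
                raise ConfigError(f"invalid value for {section}.{key}: {raw!r} ({err})")
        try:
            kwargs[attr] = cls(**values)
        except ValueError as err:
            raise ConfigError(f"section [{section}]: {err}")
    try:
        return RunConfig(**kwargs)
    except ValueError as err:
        raise ConfigError(str(err))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a config file (defaults merged); ``None`` gives pure defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    return loads_config(path.read_text())


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(dump_config(cfg))


def packaged_defaults_path() -> Path:
    """Path of the packaged defaults file (the standard configuration)."""
    return Path(__file__).parent / "data" / "defaults.ini"
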