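"""Configuration schema, defaults, validation and (de)serialization.

A simulation run is fully specified by a :class:`Config`: no external data is
read.  The defaults reproduce the reference parameterization — a community of
200 citizens on a 32×32 toroidal grid split into four meteorologically
independent quadrants, the Valtellina di Tirano event frequency triple
(77.91% light / 17.44% medium / 4.65% critical), citizen perception sd 0.7,
authority forecast sd 0.5, capitals 100 / 20,000, investments 1 / 0.5,
damages 10 / 5, a fine of 1 detected 20% of the time, incentives at 50% of
the investment, and 100 events per run averaged over 100 replicate runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PROFILES = ("random", "ap", "apc", "es", "esc", "free_rider")
POLICIES = ("punitive", "encouraging", "punitive_and_encouraging")
SCENARIOS = ("independent", "interdependent")

#: Severity codes, in increasing order of severity.
LIGHT, MEDIUM_EVENT, CRITICAL = 1, 2, 3


class ConfigError(ValueError):
    """A configuration violates a schema invariant."""


@dataclass
class EventDistribution:
    """Prior probabilities of the three event severities."""

    p_light: float = 0.7791
    p_medium: float = 0.1744
    p_critical: float = 0.0465

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_light, self.p_medium, self.p_critical)

    def validate(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 for p in probs):
            raise ConfigError(f"event probabilities must be non-negative: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"event distribution must sum to 1: {probs}")


@dataclass
class EconomicParams:
    """Investment costs, damages and the authority's monetary instruments.

    The full incentive equals ``incentive_rate * max_investment``; a medium
    investment earns half of it.
    """

    max_investment: float = 1.0
    med_investment: float = 0.5
    max_damage: float = 10.0
    med_damage: float = 5.0
    fine_amount: float = 1.0
    fine_probability: float = 0.2
    incentive_rate: float = 0.5

    def validate(self) -> None:
        for name in ("max_investment", "med_investment", "max_damage",
                     "med_damage", "fine_amount"):
            if getattr(self, name) < 0:
                raise ConfigError(f"econ.{name} must be non-negative")
        for name in ("fine_probability", "incentive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"econ.{name} must be in [0, 1], got {v}")


@dataclass
class Config:
    world_width: int = 32
    world_height: int = 32
    quadrants: int = 4
    n_citizens: int = 200
    citizen_sd: float = 0.7
    authority_sd: float = 0.5
    citizen_capital0: float = 100.0
    authority_capital0: float = 20_000.0
    econ: EconomicParams = field(default_factory=EconomicParams)
    events: EventDistribution = field(default_factory=EventDistribution)
    profile_mix: dict[str, float] = field(default_factory=lambda: {"esc": 1.0})
    policy: str = "encouraging"
    scenario: str = "independent"
    n_events: int = 100
    n_runs: int = 100
    social_radius: float = 3.0
    seed: int = 0
    #: Fraction of the citizens' total incurred damage that the authority
    #: bears per event (relief, reconstruction, hospitalization).
    authority_damage_coeff: float = 0.5

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config() -> Config:
    """The reference parameterization (see module docstring)."""
    return validate_config(Config())


def validate_config(cfg: Config) -> Config:
    """Check every schema invariant; return ``cfg`` unchanged if all hold."""
    if cfg.world_width <= 0 or cfg.world_height <= 0:
        raise ConfigError("world dimensions must be positive")
    if cfg.quadrants != 4:
        raise ConfigError("the world is divided into exactly 4 quadrants")
    if cfg.world_width % 2 or cfg.world_height % 2:
        raise ConfigError("world dimensions must be even to form 4 equal quadrants")
    if cfg.n_citizens <= 0:
        raise ConfigError(f"n_citizens must be positive, got {cfg.n_citizens}")
    for name in ("citizen_sd", "authority_sd"):
        if getattr(cfg, name) <= 0:
            raise ConfigError(f"{name} must be positive")
    cfg.econ.validate()
    cfg.events.validate()
    if cfg.policy not in POLICIES:
        raise ConfigError(f"policy must be one of {POLICIES}, got {cfg.policy!r}")
    if cfg.scenario not in SCENARIOS:
        raise ConfigError(f"scenario must be one of {SCENARIOS}, got {cfg.scenario!r}")
    if not cfg.profile_mix:
        raise ConfigError("profile_mix must not be empty")
    for profile, frac in cfg.profile_mix.items():
        if profile not in PROFILES:
            raise ConfigError(f"unknown profile {profile!r}")
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"profile_mix[{profile!r}] must be in [0, 1]")
    if abs(sum(cfg.profile_mix.values()) - 1.0) > 1e-9:
        raise ConfigError("profile_mix fractions must sum to 1")
    if cfg.profile_mix.get("free_rider", 0.0) > 0 and cfg.scenario != "interdependent":
        raise ConfigError(
            "free_rider profiles exist only under the interdependent scenario"
        )
    if cfg.n_events < 0 or cfg.n_runs < 1:
        raise ConfigError("n_events must be >= 0 and n_runs >= 1")
    if cfg.social_radius < 0:
        raise ConfigError("social_radius must be non-negative")
    if not 0.0 <= cfg.authority_damage_coeff <= 1.0:
        raise ConfigError("authority_damage_coeff must be in [0, 1]")
    return cfg


def profile_counts(cfg: Config) -> dict[str, int]:
    """Integer head-counts per profile.

    Each profile gets ``floor(fraction * n)``; any remainder goes to the last
    listed profile so the counts always total ``n_citizens``.
    """
    items = list(cfg.profile_mix.items())
    counts = {p: int(frac * cfg.n_citizens) for p, frac in items}
    counts[items[-1][0]] += cfg.n_citizens - sum(counts.values())
    return counts


# -- file I/O ---------------------------------------------------------------

_NESTED = {"econ": EconomicParams, "events": EventDistribution}


def _overlay(cfg: Config, data: dict) -> Config:
    known = {f.name for f in dataclasses.fields(Config)}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _NESTED:
            sub = getattr(cfg, key)
            sub_known = {f.name for f in dataclasses.fields(_NESTED[key])}
            if not isinstance(value, dict):
                raise ConfigError(f"{key!r} must be a mapping")
            for sk, sv in value.items():
                if sk not in sub_known:
                    raise ConfigError(f"unknown config key {key}.{sk!r}")
                setattr(sub, sk, sv)
        else:
            setattr(cfg, key, value)
    return cfg


def load_config(path) -> Config:
    """Read a YAML (or JSON) config file, overlay it on the defaults, validate.

    Keys match the :class:`Config` field names; ``econ`` and ``events`` are
    nested mappings.  Unknown keys are errors.  An empty file yields the
    default configuration.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return validate_config(_overlay(Config(), data))


def loads_config(text: str) -> Config:
    """As :func:`load_config`, from a string (used by tests and the CLI)."""
    data = yaml.safe_load(text) or {}
    return validate_config(_overlay(Config(), data))


def config_to_json(cfg: Config) -> str:
    return json.dumps(cfg.to_dict(), indent=2)
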