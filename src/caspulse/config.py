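"""Configuration files, tabular output, and reproducibility metadata.

Config files are flat TOML key-value tables.  Keys are the field names of
KineticParameters and FateParameters plus a small set of run controls;
unknown keys are rejected by name.  A fully-defaulted config reproduces the
published parameter set.  Output tables are round-trip-safe CSV, and every
run can emit a sidecar recording the effective config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from .dde import IntegratorOptions
from .errors import ConfigurationError, InvalidArgumentError
from .params import FateParameters, KineticParameters

__all__ = ["RunConfig", "load_config", "write_table", "parse_duration"]

_KINETIC_KEYS = {f.name for f in fields(KineticParameters)}
_FATE_KEYS = {f.name for f in fields(FateParameters)}
_RUN_KEYS = {"rtol", "atol", "seed", "time_unit"}


def parse_duration(text: str | float) -> float:
    """Duration in seconds; accepts plain numbers (s) or an ``h`` suffix."""
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().lower()
    try:
        if s.endswith("h"):
            return float(s[:-1]) * 3600.0
        if s.endswith("s"):
            return float(s[:-1])
        return float(s)
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse duration {text!r}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one run (defaults = published values)."""

    kinetic: KineticParameters = field(default_factory=KineticParameters)
    fate: FateParameters = field(default_factory=FateParameters)
    options: IntegratorOptions = field(default_factory=IntegratorOptions)
    seed: int = 0
    time_unit: str = "s"        # unit used on I/O surfaces ("s" or "h")

    def digest(self) -> str:
        """Stable short hash of the effective configuration."""
        payload = {
            "kinetic": asdict(self.kinetic),
            "fate": asdict(self.fate),
            "rtol": self.options.rtol,
            "atol": self.options.atol,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def echo(self) -> str:
        """Flat TOML text of the effective configuration."""
        lines = [f"# caspulse effective config (digest {self.digest()})"]
        for name, value in {**asdict(self.kinetic), **asdict(self.fate)}.items():
            lines.append(f"{name} = {value!r}")
        lines += [f"rtol = {self.options.rtol!r}", f"atol = {self.options.atol!r}",
                  f"seed = {self.seed}", f'time_unit = "{self.time_unit}"']
        return "\n".join(lines) + "\n"


def load_config(path: str | Path | None) -> RunConfig:
    """Flat TOML over defaults; unknown keys and invariant violations raise.

    An absent path or empty file yields the full published defaults.
    """
    data: dict = {}
    if path is not None:
        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except FileNotFoundError:
            raise ConfigurationError(f"config file not found: {path}")
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc

    unknown = set(data) - _KINETIC_KEYS - _FATE_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in data.items():
        if key == "time_unit":
            if value not in ("s", "h"):
                raise ConfigurationError(f"time_unit must be 's' or 'h', got {value!r}")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigurationError(f"config key {key!r} must be numeric, got {value!r}")

    try:
        kinetic = KineticParameters(**{k: float(v) for k, v in data.items() if k in _KINETIC_KEYS})
        fate = FateParameters(**{k: float(v) for k, v in data.items() if k in _FATE_KEYS})
    except InvalidArgumentError as exc:
        raise ConfigurationError(str(exc)) from exc
    options = IntegratorOptions(
        rtol=float(data.get("rtol", IntegratorOptions.rtol)),
        atol=float(data.get("atol", IntegratorOptions.atol)),
    )
    return RunConfig(kinetic=kinetic, fate=fate, options=options,
                     seed=int(data.get("seed", 0)),
                     time_unit=data.get("time_unit", "s"))


def write_table(
    records: pd.DataFrame | list[dict],
    path: str | Path,
    schema: list[str] | None = None,
    config: RunConfig | None = None,
) -> None:
    """Deterministic, round-trip-safe CSV with a declared column schema.

    Full float precision, UTF-8, newline-terminated.  When ``config`` is
    given, a ``<path>.meta.json`` sidecar records the config digest and
    seed for reproducibility.
    """
    frame = pd.DataFrame(records)
    if schema is not None and frame.empty and len(frame.columns) == 0:
        frame = pd.DataFrame(columns=schema)
    if schema is not None:
        missing = [c for c in schema if c not in frame.columns]
        extra = [c for c in frame.columns if c not in schema]
        if missing or extra:
            raise InvalidArgumentError(
                f"schema mismatch: missing column(s) {missing}, unexpected {extra}")
        frame = frame[schema] if len(frame) else pd.DataFrame(columns=schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(
            {"config_digest": config.digest(), "seed": config.seed}, indent=0) + "\n")
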