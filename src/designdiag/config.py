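"""Run configuration: YAML/JSON parsing and validation for the CLI.

A run configuration names a catalogue design, its parameters, the
diagnosands to compute, and the simulation settings::

    design: table3_canonical
    params: {effect: 1.0}
    diagnosands: [bias, power, coverage]
    sims: 500
    bootstrap: 100
    seed: 42
    out: results.csv
    format: csv
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .core import ConfigurationError
from .diagnosands import get_diagnosand
from .library import CATALOGUE

__all__ = ["ConfigError", "RunConfig", "parse_config"]

_FORMATS = ("csv", "json")


class ConfigError(ValueError):
    """A malformed or invalid run configuration; names the field at fault."""


@dataclass
class RunConfig:
    design: str
    params: dict = field(default_factory=dict)
    diagnosands: list = field(default_factory=lambda: ["bias"])
    sims: int = 500
    bootstrap: int = 100
    seed: int = 0
    out: str | None = None
    format: str = "csv"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(cond: bool, path: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {message}")


def parse_config(source) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration.

    ``source`` may be a path, a document string, or a mapping.  Schema
    errors pinpoint the offending field; an unknown diagnosand name is
    reported with a closest-match suggestion.
    """
    if isinstance(source, dict):
        doc = dict(source)
    else:
        text = source
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"document: not valid YAML/JSON ({exc})")
    _require(isinstance(doc, dict), "document", "expected a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in doc:
        _require(key in known, key, f"unknown field; expected one of "
                 f"{sorted(known)}")
    _require("design" in doc, "design", "required field is missing")
    cfg = RunConfig(design=doc["design"],
                    params=doc.get("params") or {},
                    diagnosands=doc.get("diagnosands") or ["bias"],
                    sims=doc.get("sims", 500),
                    bootstrap=doc.get("bootstrap", 100),
                    seed=doc.get("seed", 0),
                    out=doc.get("out"),
                    format=doc.get("format", "csv"))
    _require(cfg.design in CATALOGUE, "design",
             f"unknown design {cfg.design!r}; available: "
             f"{sorted(CATALOGUE)}")
    _require(isinstance(cfg.params, dict), "params", "expected a mapping")
    _require(isinstance(cfg.sims, int) and cfg.sims >= 1, "sims",
             f"must be an integer >= 1, got {cfg.sims!r}")
    _require(isinstance(cfg.bootstrap, int) and cfg.bootstrap >= 0,
             "bootstrap", f"must be an integer >= 0, got {cfg.bootstrap!r}")
    _require(isinstance(cfg.seed, int), "seed",
             f"must be an integer, got {cfg.seed!r}")
    _require(cfg.format in _FORMATS, "format",
             f"must be one of {_FORMATS}, got {cfg.format!r}")
    _require(isinstance(cfg.diagnosands, list) and cfg.diagnosands,
             "diagnosands", "expected a non-empty list")
    for i, name in enumerate(cfg.diagnosands):
        if isinstance(name, dict):
            ((name, options),) = name.items()
        else:
            options = {}
        try:
            get_diagnosand(name, **options)
        except ConfigurationError as exc:
            raise ConfigError(f"diagnosands[{i}]: {exc}")
    return cfg
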