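"""Configuration loading: defaults < config file (YAML/JSON) < explicit overrides."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import yaml

from .cascade import FilterConfig
from .errors import FormatError, ValidationError

_FIELDS = {f.name for f in dataclasses.fields(FilterConfig)}


def load_filter_config(path=None, **overrides) -> FilterConfig:
    """Build a :class:`FilterConfig` from an optional file plus overrides.

    The file may be YAML or JSON; keys mirror the FilterConfig fields.
    ``accepted_assertions`` accepts a list of assertion tokens.  Unknown
    keys are rejected so typos cannot silently fall back to defaults.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FormatError(f"config file not found: {path}")
        text = path.read_text()
        try:
            data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        except Exception as exc:
            raise FormatError(f"cannot parse config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must be a mapping")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(values) - _FIELDS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "accepted_assertions" in values:
        values["accepted_assertions"] = frozenset(values["accepted_assertions"])
    return FilterConfig(**values)


def config_snapshot(config: FilterConfig) -> dict:
    d = dataclasses.asdict(config)
    d["accepted_assertions"] = sorted(config.accepted_assertions)
    return d
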