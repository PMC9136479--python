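"""Config loading and deterministic tabular output.

JSON in (schema-validated, defaults filled, unknown keys rejected),
RFC-4180 CSV out, plus a JSON metadata sidecar (seed, config hash,
package version) next to every table so any run can be reproduced
byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .params import RunConfig


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Omitted fields take the model defaults (an empty object yields the
    full default configuration); unknown keys and invariant violations
    raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON serialization of a config."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV deterministically (header row, UTF-8, LF line ends)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_sidecar(
    path: str | Path,
    *,
    command: str,
    seed: int,
    config: RunConfig,
    extra: dict | None = None,
) -> None:
    """Write the JSON provenance sidecar next to a run's CSV outputs."""
    from . import __version__

    meta = {
        "command": command,
        "seed": seed,
        "config_sha256": config_hash(config),
        "grcsim_version": __version__,
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
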