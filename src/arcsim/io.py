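"""Trace CSV readers/writers, config loading, and run manifests.

The trace schema is one header row of
``time_min,map_mmHg,cvp_mmHg,lactate_mmol_L,hct_frac,infusion_mL_min,fluid,bag_volume_mL``
(UTF-8, "." decimal separator), sampled uniformly; ``target_mmHg`` and
``phase`` columns are optional extensions written by the protocol runner.
Floats are written with 12 significant digits so a write-then-read
round-trip is an identity for practical purposes.

Configs are YAML with four optional sections (``subject``, ``arc``,
``autobleed``, ``protocol``) plus top-level ``seed`` and ``jitter``;
unknown keys are rejected with their key path and ranges are validated
before any simulation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .arc import ArcConfig
from .autobleed import AutoBleedConfig
from .protocol import ProtocolConfig
from .subject import SubjectParams

REQUIRED_TRACE_COLUMNS = (
    "time_min",
    "map_mmHg",
    "cvp_mmHg",
    "lactate_mmol_L",
    "hct_frac",
    "infusion_mL_min",
    "fluid",
    "bag_volume_mL",
)

_FLOAT_FORMAT = "%.12g"
_TIME_TOLERANCE = 1e-6  # min


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a trace CSV (header mandatory, 12-significant-digit floats)."""
    missing = [c for c in REQUIRED_TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing column(s): {', '.join(missing)}")
    trace.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trace(path) -> pd.DataFrame:
    """Read and validate a trace CSV.

    Rejects missing required columns (naming them) and non-uniform or
    non-monotone timesteps (naming the first offending row, 1-based data
    row numbers).
    """
    trace = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    t = trace["time_min"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-monotone time at data row {int(bad[0]) + 2}"
            )
        step = np.median(dt)
        off = np.nonzero(np.abs(dt - step) > _TIME_TOLERANCE)[0]
        if off.size:
            raise ValueError(
                f"{path}: non-uniform timestep at data row {int(off[0]) + 2}"
            )
    return trace


@dataclass
class RunConfig:
    """Validated bundle of all per-run settings."""

    subject: dict = field(default_factory=dict)   # SubjectParams overrides
    arc: ArcConfig = field(default_factory=ArcConfig)
    autobleed: AutoBleedConfig = field(default_factory=AutoBleedConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0
    jitter: float = 0.0


_SECTION_TYPES = {
    "arc": ArcConfig,
    "autobleed": AutoBleedConfig,
    "protocol": ProtocolConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown key(s) under '{name}': {', '.join(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value under '{name}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML run config; an empty file yields all defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")

    known_top = {"subject", "arc", "autobleed", "protocol", "seed", "jitter"}
    unknown = sorted(set(data) - known_top)
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(unknown)}")

    subject = data.get("subject") or {}
    if not isinstance(subject, dict):
        raise ValueError("'subject' must be a mapping of parameter overrides")
    known_subject = {f.name for f in dataclasses.fields(SubjectParams)}
    bad = sorted(set(subject) - known_subject)
    if bad:
        raise ValueError(f"unknown key(s) under 'subject': {', '.join(bad)}")
    # range-check the overrides by materialising a parameter set
    _build_section("subject", SubjectParams, subject)

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        raw = data.get(name) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"'{name}' must be a mapping")
        sections[name] = _build_section(name, cls, raw)

    seed = data.get("seed", 0)
    jitter = data.get("jitter", 0.0)
    if not isinstance(seed, int):
        raise ValueError("'seed' must be an integer")
    if not isinstance(jitter, (int, float)) or jitter < 0:
        raise ValueError("'jitter' must be a non-negative number")

    return RunConfig(
        subject=dict(subject),
        arc=sections["arc"],
        autobleed=sections["autobleed"],
        protocol=sections["protocol"],
        seed=int(seed),
        jitter=float(jitter),
    )


def config_hash(config: RunConfig) -> str:
    """Stable hash of the effective configuration."""
    payload = repr(
        (
            sorted(config.subject.items()),
            dataclasses.asdict(config.arc),
            dataclasses.asdict(config.autobleed),
            dataclasses.asdict(config.protocol),
            config.seed,
            config.jitter,
        )
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def write_manifest(path, config: RunConfig, extras: dict | None = None) -> None:
    """Plain-text key:value run manifest sufficient to re-run bit-identically."""
    import arcsim

    lines = {
        "arcsim_version": arcsim.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "jitter": config.jitter,
        "config_sha256": config_hash(config),
    }
    if extras:
        lines.update(extras)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in lines.items():
            fh.write(f"{key}: {value}\n")
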