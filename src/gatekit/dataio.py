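"""CSV readers/writers and run configuration.

Dialects (comma-separated, dot decimal, UTF-8, header row required,
floats written with 17 significant digits for bit-stable round trips):

``dose_response``
    conc_molar, response, voltage_mV, ca_molar
    (optional: replicate, sweep, is_reference)
``iv``
    voltage_mV, current, replicate, ca_molar
``trace``
    time_s, state_0 ... state_{n-1}, p_open

Human-facing columns and flags use mV and uM; the library speaks volts
and molar.  Conversion happens here and in the CLI only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError
from .fitting import CompositeDataset, DataBlock
from .mechanism import Conditions
from .permeation import IVDataset

__all__ = [
    "read_dataset",
    "write_block_dataset",
    "write_iv_dataset",
    "write_trace",
    "composite_from_frame",
    "RunConfig",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"

_REQUIRED = {
    "dose_response": ["conc_molar", "response", "voltage_mV", "ca_molar"],
    "iv": ["voltage_mV", "current", "replicate", "ca_molar"],
    "trace": ["time_s", "p_open"],
}


def read_dataset(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV dataset of the given kind.

    Missing columns raise :class:`SchemaError` naming the columns;
    non-numeric cells raise :class:`ParseError` carrying the file line
    numbers (header is line 1).
    """
    if kind not in _REQUIRED:
        raise SchemaError(f"unknown dataset kind {kind!r}")
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED[kind] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    numeric_cols = [
        c for c in frame.columns if c != "is_reference"
    ]
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ParseError(
                f"{path.name}: non-numeric value(s) in column {col!r} "
                f"at line(s) {lines}"
            )
        frame[col] = coerced
    if "is_reference" in frame.columns:
        frame["is_reference"] = frame["is_reference"].astype(bool)
    return frame


def write_block_dataset(data: CompositeDataset, path: str | Path) -> None:
    """Write a composite block/activation dataset as one long-format
    dose-response CSV plus a JSON provenance sidecar when available."""
    frames = []
    provenance = None
    for block in data.blocks:
        t = block.table.copy()
        t["voltage_mV"] = block.conditions.voltage * 1e3
        t["ca_molar"] = block.conditions.calcium
        frames.append(t)
        provenance = provenance or block.table.attrs.get("provenance")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if provenance is not None:
        Path(path).with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=1)
        )


def composite_from_frame(frame: pd.DataFrame, kind: str = "inhibition") -> CompositeDataset:
    """Group a long-format dose-response table into per-condition blocks."""
    blocks = []
    for (v_mv, ca), group in frame.groupby(["voltage_mV", "ca_molar"], sort=True):
        table = group.reset_index(drop=True)
        if "is_reference" in table.columns:
            table = table[~table["is_reference"]].reset_index(drop=True)
        cond = Conditions(voltage=float(v_mv) / 1e3, calcium=float(ca), blocker=0.0)
        blocks.append(DataBlock(kind=kind, conditions=cond, table=table))
    return CompositeDataset(blocks=blocks)


def write_iv_dataset(data: IVDataset, path: str | Path) -> None:
    t = data.table.copy()
    t["voltage_mV"] = t.pop("voltage_v") * 1e3
    cols = ["voltage_mV", "current", "replicate", "ca_molar"]
    t[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)
    provenance = data.table.attrs.get("provenance")
    if provenance is not None:
        Path(path).with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=1)
        )


def read_iv_dataset(path: str | Path) -> IVDataset:
    frame = read_dataset(path, "iv")
    frame = frame.copy()
    frame["voltage_v"] = frame.pop("voltage_mV") / 1e3
    frame = frame.sort_values(["replicate", "voltage_v"]).reset_index(drop=True)
    return IVDataset(table=frame)


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    trace.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class RunConfig:
    """JSON-backed run configuration; unknown keys are rejected.

    Human units at this boundary: mV, uM, kelvin.
    """

    mechanism: str = "open_block"
    parameter_file: str | None = None
    seed: int = 0
    temperature_K: float = 293.15
    sigma: float = 0.03
    n_replicates: int = 6
    rundown_rate: float = 0.0
    ca_uM: tuple[float, ...] = (0.4, 0.8, 2.0)
    voltage_mV: tuple[float, ...] = (-80.0, 80.0)
    blocker_uM: tuple[float, ...] | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed must be an integer")
        if self.temperature_K <= 0:
            raise ConfigurationError("temperature_K must be > 0")
        if self.parameter_file is not None and not Path(self.parameter_file).exists():
            raise ConfigurationError(
                f"parameter file not found: {self.parameter_file}"
            )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("ca_uM", "voltage_mV", "blocker_uM"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(float(x) for x in doc[key])
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
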