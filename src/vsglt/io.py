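"""Readers and writers for parameter tables, traces and result files.

All formats are plain text: TSV for the rate-constant/charge table (columns
``transition, k0, k0_units, eta, epsilon, note``, one row per directed
transition), CSV for traces and tidy result tables, JSON for truth sidecars
and summaries.  Result files start with a provenance comment block (package
version, seed, config hash) so any output can be regenerated from its
header; no timestamps, so identical runs produce byte-identical files.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .deer import DipolarTrace
from .gating_charge import ChargeSite
from .transport_cycle import (
    RATE_UNITS, TRANSITIONS, CycleChargeReport, TransportParameters,
    validate_cycle_charges,
)

__all__ = [
    "read_parameters",
    "write_parameters",
    "reference_parameters",
    "read_traces",
    "write_traces",
    "read_site_table",
    "write_results",
    "provenance",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits in all result files


def provenance(seed: int | None = None, config: Mapping[str, Any] | None = None) -> dict:
    """Provenance block identifying a run: version, seed and config hash."""
    block = {"package": "vsglt", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        payload = json.dumps(config, sort_keys=True, default=str).encode()
        block["config_sha256"] = hashlib.sha256(payload).hexdigest()
    return block


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def read_parameters(path: str | Path, validate: bool = True) -> tuple[TransportParameters, CycleChargeReport]:
    """Load a transport parameter TSV and attach its cycle-charge report.

    The table must contain exactly the ten directed transition labels with
    the correct unit string per row (1/(M*s) for 12 and 23, 1/(M^2*s) for
    54, 1/s otherwise).  Charge-sum violations are reported as warnings in
    the returned :class:`CycleChargeReport`, never silently fixed.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"transition": str})
    required = {"transition", "k0", "k0_units", "eta", "epsilon"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"parameter table is missing columns {sorted(missing_cols)}")
    labels = list(table["transition"])
    dupes = sorted({t for t in labels if labels.count(t) > 1})
    if dupes:
        raise ValueError(f"duplicate transition rows: {dupes}")
    missing = sorted(set(TRANSITIONS) - set(labels))
    if missing:
        raise ValueError(f"parameter table is missing transitions: {missing}")
    unknown = sorted(set(labels) - set(TRANSITIONS))
    if unknown:
        raise ValueError(f"unknown transition labels: {unknown}")
    units_ok = {}
    for _, row in table.iterrows():
        t = row["transition"]
        expected = RATE_UNITS[t]
        if str(row["k0_units"]).strip() != expected:
            raise ValueError(
                f"transition {t}: unit {row['k0_units']!r} does not match expected {expected!r}"
            )
        units_ok[t] = row
    meta = _read_meta(path)
    params = TransportParameters(
        base_rates={t: float(units_ok[t]["k0"]) for t in TRANSITIONS},
        eta={t: float(units_ok[t]["eta"]) for t in TRANSITIONS},
        epsilon={t: float(units_ok[t]["epsilon"]) for t in TRANSITIONS},
        q_gc_total=float(meta.get("q_gc_total", -0.7)),
        temperature_K=float(meta.get("temperature_K", 298.15)),
    )
    report = validate_cycle_charges(params)
    if validate and not report.ok:
        import warnings as _warnings
        for msg in report.warnings:
            _warnings.warn(msg, stacklevel=2)
    return params, report


def _read_meta(path: str | Path) -> dict[str, str]:
    """Key=value pairs from '# key = value' comment lines."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_parameters(params: TransportParameters, path: str | Path,
                     notes: Mapping[str, str] | None = None) -> None:
    """Write a parameter table in the canonical ten-row TSV layout."""
    notes = notes or {}
    lines = [
        f"# q_gc_total = {params.q_gc_total!r}",
        f"# temperature_K = {params.temperature_K!r}",
        "transition\tk0\tk0_units\teta\tepsilon\tnote",
    ]
    for t in TRANSITIONS:
        lines.append(
            "\t".join([
                t,
                _FLOAT_FMT % params.base_rates[t],
                RATE_UNITS[t],
                _FLOAT_FMT % (params.eta[t] if params.eta[t] != 0 else 0.0),
                _FLOAT_FMT % (params.epsilon[t] if params.epsilon[t] != 0 else 0.0),
                notes.get(t, ""),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def reference_parameters() -> tuple[TransportParameters, CycleChargeReport]:
    """The packaged reference parameter set (see data/reference_rates.tsv)."""
    with resources.as_file(resources.files("vsglt.data") / "reference_rates.tsv") as p:
        return read_parameters(p)


# ---------------------------------------------------------------------------
# traces and site tables
# ---------------------------------------------------------------------------

def write_traces(traces: list[DipolarTrace], directory: str | Path,
                 sidecar: Mapping[str, Any] | None = None) -> list[Path]:
    """Write each trace as a two-column CSV plus one JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trace in enumerate(traces):
        frame = pd.DataFrame({"time_us": trace.time_us, "signal": trace.signal})
        p = directory / f"trace_{i:02d}.csv"
        frame.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths.append(p)
    meta = {
        "conditions": [tr.condition_label for tr in traces],
        "files": [p.name for p in paths],
    }
    if sidecar:
        meta.update(sidecar)
    (directory / "traces.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths


def read_traces(directory: str | Path) -> list[DipolarTrace]:
    """Load a trace directory written by :func:`write_traces`."""
    directory = Path(directory)
    meta = json.loads((directory / "traces.json").read_text())
    traces = []
    for label, name in zip(meta["conditions"], meta["files"]):
        frame = pd.read_csv(directory / name)
        traces.append(DipolarTrace(time_us=frame["time_us"].to_numpy(),
                                   signal=frame["signal"].to_numpy(),
                                   condition_label=label))
    return traces


def read_site_table(path: str | Path) -> list[ChargeSite]:
    """Charge-site CSV: residue_id, charge_e, z_if, z_of."""
    frame = pd.read_csv(path, comment="#")
    required = {"residue_id", "charge_e", "z_if", "z_of"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"site table is missing columns {sorted(missing)}")
    return [
        ChargeSite(residue_id=str(r.residue_id), charge_e=float(r.charge_e),
                   z_if=float(r.z_if), z_of=float(r.z_of))
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(
    obj: pd.DataFrame | Mapping[str, Any],
    path: str | Path,
    fmt: str = "csv",
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write a tidy result table (CSV) or mapping (JSON) with a provenance header.

    Column order and float formatting (12 significant digits) are
    deterministic, so two identical runs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    block = provenance(seed=seed, config=config)
    if fmt == "csv":
        if not isinstance(obj, pd.DataFrame):
            raise TypeError("csv format requires a DataFrame")
        buf = _io.StringIO()
        for key, value in block.items():
            buf.write(f"# {key} = {value}\n")
        obj.to_csv(buf, index=False, float_format=_FLOAT_FMT)
        path.write_text(buf.getvalue())
    elif fmt == "json":
        if isinstance(obj, pd.DataFrame):
            payload: Any = obj.to_dict(orient="records")
        else:
            payload = dict(obj)
        document = {"provenance": block, "results": payload}
        path.write_text(json.dumps(document, indent=2, sort_keys=True, default=_json_default) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _json_default(value: Any) -> Any:
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"cannot serialize {type(value)!r}")
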