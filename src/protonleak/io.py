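"""Plain-text readers and writers for traces, dose series and FCS curves.

CSV files carry a small ``# key: value`` metadata header (membrane area,
temperature, buffer pH, curve label) above the column header; provenance
(true generating parameters, seed) goes to a JSON sidecar next to the data
file so synthetic and measured files share one format.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conductance import IVTrace
from .dose_response import DoseSeries
from .fcs import DEFAULT_OMEGA_UM, FcsCurve

__all__ = [
    "read_iv_csv", "write_iv_csv",
    "read_dose_csv", "write_dose_csv",
    "read_fcs_csv", "write_fcs_csv",
    "write_provenance", "read_provenance",
]


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            if value:
                meta[key.strip()] = value.strip()
    return meta


def _write_csv(path: Path, meta: dict, df: pd.DataFrame) -> None:
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_iv_csv(trace: IVTrace, path: str | Path) -> None:
    meta = {
        "area_cm2": repr(trace.area),
        "temperature_K": repr(trace.temperature),
        "side_cis": trace.side_labels[0],
        "side_trans": trace.side_labels[1],
    }
    df = pd.DataFrame({"voltage_mV": trace.voltage, "current_pA": trace.current})
    _write_csv(Path(path), meta, df)
    if trace.provenance:
        write_provenance(path, trace.provenance)


def read_iv_csv(path: str | Path) -> IVTrace:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    return IVTrace(
        voltage=df["voltage_mV"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        area=float(meta.get("area_cm2", 1.0)),
        side_labels=(meta.get("side_cis", "cis"), meta.get("side_trans", "trans")),
        temperature=float(meta.get("temperature_K", 306.0)),
        provenance=read_provenance(path) or {},
    )


def write_dose_csv(series: DoseSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "conc_uM": series.concentration,
        "rel_conductance": series.rel_conductance,
        "compound": series.compound,
        "replicate": series.replicate_id if series.replicate_id is not None else 0,
    })
    _write_csv(Path(path), {}, df)
    if series.provenance:
        write_provenance(path, series.provenance)


def read_dose_csv(path: str | Path) -> list[DoseSeries]:
    """One DoseSeries per compound found in the file."""
    df = pd.read_csv(path, comment="#")
    out = []
    for compound, grp in df.groupby("compound", sort=True):
        rep = grp["replicate"].to_numpy() if "replicate" in grp else None
        out.append(DoseSeries(
            concentration=grp["conc_uM"].to_numpy(),
            rel_conductance=grp["rel_conductance"].to_numpy(),
            compound=str(compound),
            replicate_id=rep,
            provenance=read_provenance(path) or {},
        ))
    return out


def write_fcs_csv(curve: FcsCurve, path: str | Path) -> None:
    meta = {"label": curve.label, "omega_um": repr(curve.omega_um)}
    df = pd.DataFrame({"lag_s": curve.lag, "G": curve.G})
    _write_csv(Path(path), meta, df)
    if curve.provenance:
        write_provenance(path, curve.provenance)


def read_fcs_csv(path: str | Path) -> FcsCurve:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    return FcsCurve(
        lag=df["lag_s"].to_numpy(),
        G=df["G"].to_numpy(),
        label=meta.get("label", ""),
        omega_um=float(meta.get("omega_um", DEFAULT_OMEGA_UM)),
        provenance=read_provenance(path) or {},
    )


def _sidecar(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".provenance.json")


def write_provenance(data_path: str | Path, provenance: dict) -> None:
    _sidecar(data_path).write_text(json.dumps(_jsonable(provenance), indent=1))


def read_provenance(data_path: str | Path) -> dict | None:
    side = _sidecar(data_path)
    if side.exists():
        return json.loads(side.read_text())
    return None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
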