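"""Delimited-text readers and writers for force curves and QCM-D exports.

Force curves are one-file-per-curve tab-separated tables with ``# key: value``
header lines carrying the calibration metadata (spring constant mandatory).
The dialect object names the columns and units, so vendor exports with
deflection in nm or spring constants in N/m normalize to the package units
(nm, pN, s) on read.

QCM-D traces are a single table with a ``time_s`` column and ``f<n>_Hz`` /
``d<n>`` columns per odd overtone; stage boundaries travel in the header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .qcmd import QcmTrace, StageBoundaries
from .smfs import ForceCurve

__all__ = [
    "CurveDialect",
    "read_force_curve",
    "read_force_curves",
    "write_force_curve",
    "read_qcm_trace",
    "write_qcm_trace",
]

_Z_UNIT = {"nm": 1.0, "um": 1e3, "m": 1e9}
_FORCE_UNIT = {"pN": 1.0, "nN": 1e3, "N": 1e12}
_TIME_UNIT = {"s": 1.0, "ms": 1e-3}
_SPRING_UNIT = {"pN/nm": 1.0, "N/m": 1e3, "mN/m": 1.0}
_SPEED_UNIT = {"nm/s": 1.0, "um/s": 1e3, "m/s": 1e9}


@dataclass
class CurveDialect:
    """Column names, units and header keys of a force-curve text format.

    If ``deflection_col`` is set it takes precedence over ``force_col``: the
    column is read as cantilever deflection in ``z_unit`` and multiplied by
    the spring constant to obtain force.
    """

    sep: str = "\t"
    time_col: str = "time_s"
    z_col: str = "piezo_nm"
    force_col: str = "force_pN"
    deflection_col: "str | None" = None
    time_unit: str = "s"
    z_unit: str = "nm"
    force_unit: str = "pN"
    spring_key: str = "spring_constant"
    speed_key: str = "retraction_speed"
    id_key: str = "curve_id"


DEFAULT_DIALECT = CurveDialect()


def _parse_quantity(text: str) -> tuple:
    """Parse '0.05 N/m' -> (0.05, 'N/m'); bare numbers get unit ''."""
    parts = str(text).strip().split(None, 1)
    value = float(parts[0])
    unit = parts[1].strip() if len(parts) > 1 else ""
    return value, unit


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_force_curve(path, dialect: CurveDialect = DEFAULT_DIALECT) -> ForceCurve:
    """Read one curve, normalizing to nm / pN / s."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty force-curve file")
    meta = _read_header(path)
    table = pd.read_csv(path, sep=dialect.sep, comment="#", float_precision="round_trip")
    if table.empty:
        raise ValueError(f"{path}: no data rows")

    if dialect.spring_key not in meta:
        raise ValueError(f"{path}: missing mandatory spring-constant header "
                         f"{dialect.spring_key!r}")
    k_value, k_unit = _parse_quantity(meta[dialect.spring_key])
    spring = k_value * _SPRING_UNIT.get(k_unit or "pN/nm", None) \
        if (k_unit or "pN/nm") in _SPRING_UNIT else None
    if spring is None:
        raise ValueError(f"{path}: unknown spring-constant unit {k_unit!r}")

    speed = 1.0
    if dialect.speed_key in meta:
        v_value, v_unit = _parse_quantity(meta[dialect.speed_key])
        speed = v_value * _SPEED_UNIT.get(v_unit or "nm/s", 1.0)

    time = table[dialect.time_col].to_numpy(float) * _TIME_UNIT[dialect.time_unit]
    z = table[dialect.z_col].to_numpy(float) * _Z_UNIT[dialect.z_unit]
    if dialect.deflection_col is not None:
        force = table[dialect.deflection_col].to_numpy(float) * _Z_UNIT[dialect.z_unit] * spring
    else:
        force = table[dialect.force_col].to_numpy(float) * _FORCE_UNIT[dialect.force_unit]

    curve_id = meta.get(dialect.id_key, path.stem)
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"curve {curve_id!r} ({path}): time not strictly increasing")
    return ForceCurve(
        time=time, piezo_position=z, force=force,
        spring_constant=spring, retraction_speed=speed, curve_id=curve_id,
    )


def read_force_curves(source, dialect: CurveDialect = DEFAULT_DIALECT,
                      pattern: str = "*.tsv") -> list:
    """Read a single file, or every ``pattern`` file in a directory (sorted)."""
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if source.is_dir():
        files = sorted(source.glob(pattern))
        if not files:
            raise ValueError(f"{source}: no {pattern} curve files found")
        return [read_force_curve(f, dialect) for f in files]
    return [read_force_curve(source, dialect)]


def write_force_curve(curve: ForceCurve, path,
                      dialect: CurveDialect = DEFAULT_DIALECT) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {dialect.id_key}: {curve.curve_id}\n")
        fh.write(f"# {dialect.spring_key}: {curve.spring_constant!r} pN/nm\n")
        fh.write(f"# {dialect.speed_key}: {curve.retraction_speed!r} nm/s\n")
        fh.write(dialect.sep.join([dialect.time_col, dialect.z_col, dialect.force_col]) + "\n")
        for t, z, f in zip(curve.time, curve.piezo_position, curve.force):
            fh.write(f"{float(t)!r}{dialect.sep}{float(z)!r}{dialect.sep}{float(f)!r}\n")


def write_qcm_trace(trace: QcmTrace, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    overtones = trace.overtones
    with open(path, "w") as fh:
        fh.write(f"# f0_Hz: {trace.f0!r}\n")
        fh.write(f"# stages_s: {trace.stages.baseline_end!r} "
                 f"{trace.stages.adsorption_end!r} {trace.stages.end!r}\n")
        cols = ["time_s"]
        for n in overtones:
            cols += [f"f{n}_Hz", f"d{n}"]
        fh.write("\t".join(cols) + "\n")
        for i, t in enumerate(trace.time):
            row = [repr(float(t))]
            for n in overtones:
                row.append(repr(float(trace.delta_f[n][i])))
                row.append(repr(float(trace.delta_d[n][i])) if n in trace.delta_d else "nan")
            fh.write("\t".join(row) + "\n")


def read_qcm_trace(path, stages: "StageBoundaries | None" = None) -> QcmTrace:
    """Read a QCM-D export; stage boundaries come from the header unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_header(path)
    table = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if table.empty:
        raise ValueError(f"{path}: no data rows")
    f0 = float(meta.get("f0_Hz", 5.0e6))
    if stages is None:
        if "stages_s" not in meta:
            raise ValueError(f"{path}: stage boundaries missing from header and argument")
        vals = [float(v) for v in meta["stages_s"].split()]
        stages = StageBoundaries(*vals)
    delta_f, delta_d = {}, {}
    for col in table.columns:
        if col.startswith("f") and col.endswith("_Hz"):
            n = int(col[1:-3])
            delta_f[n] = table[col].to_numpy(float)
        elif col.startswith("d") and col[1:].isdigit():
            n = int(col[1:])
            delta_d[n] = table[col].to_numpy(float)
    return QcmTrace(
        time=table["time_s"].to_numpy(float),
        delta_f=delta_f, delta_d=delta_d, stages=stages, f0=f0,
    )
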