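"""CSV/JSON formats and result writing.

TAC CSV dialect: long format with header ``time_min,series,value`` where
``series`` is a region name, ``CWB`` for whole-blood samples, or
``CPET:<region>`` for blood-volume-mixed traces.  Ground-truth/report JSON
mirrors the parameter-vector fields plus the measurement schedule.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    KineticParams,
    MeasurementSchedule,
    MeasurementSet,
    ParameterVector,
    PlasmaFractionParams,
    PolyexpCurve,
)

__all__ = [
    "SCHEMA_VERSION",
    "read_tac_csv",
    "write_tac_csv",
    "truth_to_dict",
    "truth_from_dict",
    "write_results",
]

SCHEMA_VERSION = "1"
logger = logging.getLogger("petkin")

_CSV_COLUMNS = ["time_min", "series", "value"]


def write_tac_csv(
    path,
    data: MeasurementSet,
    schedule: MeasurementSchedule,
    region_names,
    cpet: np.ndarray | None = None,
) -> None:
    """Write a MeasurementSet (and optionally C_PET traces) as a TAC CSV."""
    rows = []
    for i, name in enumerate(region_names):
        for t, v in zip(schedule.t, data.CT_matrix[i]):
            rows.append((t, name, v))
    for s, v in zip(schedule.s, data.CWB_samples):
        rows.append((s, "CWB", v))
    if cpet is not None:
        for i, name in enumerate(region_names):
            for t, v in zip(schedule.t, cpet[i]):
                rows.append((t, f"CPET:{name}", v))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_tac_csv(path, region_names=None, require_cwb: bool = True):
    """Parse a TAC CSV into (MeasurementSet, MeasurementSchedule, region_names).

    Times are sorted if needed (with a warning); duplicate (time, series)
    rows, missing series and non-numeric values raise a parse error naming
    the offending rows.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_CSV_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values at rows {list(bad.index)}")
    df["value"] = df["value"].astype(float)
    dup = df.duplicated(subset=["time_min", "series"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (time, series) rows at {list(df.index[dup])}"
        )
    series = df["series"].unique().tolist()
    regions = [s for s in series if s != "CWB" and not s.startswith("CPET:")]
    if region_names is not None:
        missing = [r for r in region_names if r not in regions]
        if missing:
            raise ValueError(f"{path}: missing region series {missing}")
        regions = list(region_names)
    if not regions:
        raise ValueError(f"{path}: no tissue series found")

    def pivot(name):
        sub = df[df["series"] == name].sort_values("time_min")
        if not sub["time_min"].is_monotonic_increasing or not np.array_equal(
            sub["time_min"].to_numpy(), df[df["series"] == name]["time_min"].to_numpy()
        ):
            warnings.warn(f"{path}: times for series {name!r} were unsorted; sorted")
        return sub["time_min"].to_numpy(), sub["value"].to_numpy()

    t = None
    CT = []
    for name in regions:
        ti, vi = pivot(name)
        if t is None:
            t = ti
        elif not np.allclose(t, ti):
            raise ValueError(f"{path}: region {name!r} uses a different time grid")
        CT.append(vi)
    if "CWB" in series:
        s, cwb = pivot("CWB")
    elif require_cwb:
        raise ValueError(f"{path}: CWB series required but absent")
    else:
        s, cwb = t, np.zeros_like(t)
    schedule = MeasurementSchedule(t=t, s=s)
    return MeasurementSet(np.array(CT), cwb), schedule, regions


# ---------------------------------------------------------------------------
# truth / report JSON
# ---------------------------------------------------------------------------

def truth_to_dict(x: ParameterVector, schedule: MeasurementSchedule | None = None,
                  region_names=None, VB: float | None = None) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "polyexp": {
            "lambdas": x.polyexp.lambdas.tolist(),
            "mus": x.polyexp.mus.tolist(),
        },
        "fraction": {
            "A": x.fraction.A, "xi1": x.fraction.xi1, "xi2": x.fraction.xi2
        },
        "regions": [
            {"K1": K.K1, "k2": K.k2, "k3": K.k3} for K in x.regions
        ],
    }
    if region_names is not None:
        d["region_names"] = list(region_names)
    if VB is not None:
        d["VB"] = VB
    if schedule is not None:
        d["schedule"] = {"t": schedule.t.tolist(), "s": schedule.s.tolist()}
    return d


def truth_from_dict(d: dict):
    x = ParameterVector(
        PolyexpCurve(np.array(d["polyexp"]["lambdas"]),
                     np.array(d["polyexp"]["mus"])),
        PlasmaFractionParams(**d["fraction"]),
        tuple(KineticParams(**r) for r in d["regions"]),
    )
    schedule = None
    if "schedule" in d:
        schedule = MeasurementSchedule(
            np.array(d["schedule"]["t"]), np.array(d["schedule"]["s"])
        )
    return x, schedule


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_results(result, out_dir, thin_iterates: int = 1) -> list:
    """Write a FitResult or ExperimentResult to ``out_dir``.

    FitResult -> fit_result.json (iterates optionally thinned).
    ExperimentResult -> experiment_result.json, a Table-style summary CSV
    (one row per region and parameter) and a divergence-count CSV.  Field
    ordering is deterministic so identical runs produce identical files.
    Returns the list of written paths.
    """
    from .experiments import ExperimentResult
    from .inversion import FitResult

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(result, FitResult):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "stopped_by": result.stopped_by,
            "stop_iteration": result.stop_iteration,
            "residual_norms": _jsonify(result.residual_norms),
            "final_x": _jsonify(result.final_packed),
            "iterates": _jsonify(result.iterates[::thin_iterates]),
        }
        path = out_dir / "fit_result.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)
    elif isinstance(result, ExperimentResult):
        summary = result.summary()
        payload = {
            "schema_version": SCHEMA_VERSION,
            "setup": result.setup,
            "count_setting": result.setting.name,
            "delta_y": result.setting.delta_y,
            "delta_x": result.delta_x,
            "n_divergent": result.n_divergent,
            "median_representative": result.median_representative(),
            "rho_opt": [r.rho_opt for r in result.replicates],
            "rho_d": [r.rho_d for r in result.replicates],
            "summary_available": summary is not None,
        }
        path = out_dir / "experiment_result.json"
        path.write_text(json.dumps(_jsonify(payload), indent=1, sort_keys=True))
        written.append(path)
        if summary is not None:
            rows = []
            for i, name in enumerate(result.region_names):
                for j, par in enumerate(("K1", "k2", "k3")):
                    rows.append(
                        (name, par, summary["mean"][i, j], summary["std"][i, j])
                    )
            spath = out_dir / "summary.csv"
            pd.DataFrame(
                rows, columns=["region", "parameter", "mean", "std"]
            ).to_csv(spath, index=False, float_format="%.6f")
            written.append(spath)
        dpath = out_dir / "divergence.csv"
        pd.DataFrame(
            [(result.setup, result.setting.name, result.delta_x,
              result.n_divergent, len(result.replicates))],
            columns=["setup", "count", "delta_x", "n_divergent", "n_total"],
        ).to_csv(dpath, index=False)
        written.append(dpath)
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")
    return written
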