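"""Plain-text table and configuration I/O shared by all stages.

CSV dialects (header row required, units embedded in the column names):

* exposure:  ``time_d, conc_nmol_per_mL`` — one row per segment start plus a
  final row carrying the end time with an empty concentration;
* survival:  ``treatment, time_d, survivors, n_initial`` (long format,
  one row per treatment x observation time);
* TK:        ``time_d, cint_nmol_per_g`` — the exposure profile travels in
  its own file.

Every writer's output is accepted by the matching reader (round-trip
identity).  Configurations and fit reports are structured text (YAML in,
JSON out).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError
from .exposure import ExposureProfile
from .calibration import SurvivalDataset
from .tk import TKObservations

__all__ = [
    "read_exposure_csv",
    "write_exposure_csv",
    "read_survival_csv",
    "write_survival_csv",
    "read_tk_csv",
    "write_tk_csv",
    "read_config",
    "write_report",
]


def write_exposure_csv(profile: ExposureProfile, path: str | Path) -> None:
    rows = [
        {"time_d": t, "conc_nmol_per_mL": c}
        for t, c in zip(profile.start_times, profile.concentrations)
    ]
    rows.append({"time_d": profile.end_time, "conc_nmol_per_mL": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_exposure_csv(path: str | Path) -> ExposureProfile:
    df = pd.read_csv(path)
    if not {"time_d", "conc_nmol_per_mL"}.issubset(df.columns):
        raise DataError("exposure CSV needs columns time_d, conc_nmol_per_mL")
    df = df.sort_values("time_d")
    conc = df["conc_nmol_per_mL"].to_numpy()
    times = df["time_d"].to_numpy(dtype=float)
    # last row marks the end time; its concentration (if any) is ignored
    end, times, conc = times[-1], times[:-1], conc[:-1]
    return ExposureProfile(tuple(times), tuple(float(c) for c in conc), float(end))


def write_survival_csv(datasets: Sequence[SurvivalDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for t, y in zip(ds.observation_times, ds.survivor_counts):
            rows.append(
                {
                    "treatment": ds.treatment_id,
                    "time_d": t,
                    "survivors": y,
                    "n_initial": ds.n_initial,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_csv(
    path: str | Path, exposures: Mapping[str, ExposureProfile]
) -> list[SurvivalDataset]:
    """Read survivor counts; ``exposures`` maps treatment id -> profile."""
    df = pd.read_csv(path)
    need = {"treatment", "time_d", "survivors", "n_initial"}
    if not need.issubset(df.columns):
        raise DataError(f"survival CSV needs columns {sorted(need)}")
    out = []
    for tid, g in df.groupby("treatment", sort=False):
        if str(tid) not in exposures:
            raise DataError(f"no exposure profile supplied for treatment '{tid}'")
        g = g.sort_values("time_d")
        out.append(
            SurvivalDataset(
                str(tid),
                exposures[str(tid)],
                tuple(g["time_d"].astype(float)),
                tuple(g["survivors"].astype(int)),
            )
        )
    return out


def write_tk_csv(obs: TKObservations, path: str | Path) -> None:
    pd.DataFrame(
        {"time_d": obs.times, "cint_nmol_per_g": obs.internal_concentrations}
    ).to_csv(path, index=False)


def read_tk_csv(path: str | Path, exposure: ExposureProfile) -> TKObservations:
    df = pd.read_csv(path)
    if not {"time_d", "cint_nmol_per_g"}.issubset(df.columns):
        raise DataError("TK CSV needs columns time_d, cint_nmol_per_g")
    df = df.sort_values("time_d")
    return TKObservations(
        tuple(df["time_d"].astype(float)),
        tuple(df["cint_nmol_per_g"].astype(float)),
        exposure,
    )


def read_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON — a YAML subset) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError("configuration must be a mapping")
    return cfg


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Serialise a pipeline report as JSON (NaN/inf mapped to null)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(dict(report)), fh, indent=2, sort_keys=True)
        fh.write("\n")
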