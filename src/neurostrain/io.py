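"""Tabular, array and configuration I/O for the injury pipeline.

Column conventions: lengths in µm (``*_um``), times in hours (``*_hr``),
strains dimensionless.  Cohort CSVs leave ``death_time_hr`` empty for
surviving cells.  Displacement/strain fields travel as compressed NumPy
archives with named arrays (``u`` or ``E``, ``spacing``, ``origin``);
per-axis multi-page TIFF stacks can be imported when tifffile is present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .injury import BlebStrainSample, InjuryRecord
from .permeability import IntensityTrace, PermeabilityResult
from .strain import CellStrainSummary, DisplacementField, StrainField

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_bleb_csv",
    "write_bleb_csv",
    "read_traces_csv",
    "write_traces_csv",
    "write_strain_summaries_csv",
    "write_permeability_csv",
    "save_field",
    "load_field",
    "displacement_from_tiff",
    "write_fit_report",
    "read_fit_report",
    "load_config",
]

COHORT_COLUMNS = [
    "cell_id", "rate_group", "mean_Ec", "mean_Es",
    "death_time_hr", "bleb_formed", "n_blebs",
]


def write_cohort_csv(records: list[InjuryRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "rate_group": r.rate_group,
                "mean_Ec": r.mean_Ec,
                "mean_Es": r.mean_Es,
                "death_time_hr": r.death_time_hr,
                "bleb_formed": int(r.bleb_formed),
                "n_blebs": len(r.bleb_positions),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[InjuryRecord]:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        td = row["death_time_hr"]
        records.append(
            InjuryRecord(
                cell_id=str(row["cell_id"]),
                rate_group=str(row["rate_group"]),
                mean_Ec=float(row["mean_Ec"]),
                mean_Es=float(row["mean_Es"]),
                death_time_hr=None if pd.isna(td) else float(td),
                bleb_formed=bool(row["bleb_formed"]),
            )
        )
    return records


def write_bleb_csv(samples: list[BlebStrainSample], path: str | Path,
                   positions_um: list[float] | None = None) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in samples],
            "s_um": positions_um if positions_um is not None else np.nan,
            "Ec_max": [s.Ec_max for s in samples],
            "Es_max": [s.Es_max for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_bleb_csv(path: str | Path) -> list[BlebStrainSample]:
    df = pd.read_csv(path)
    return [
        BlebStrainSample(
            cell_id=str(r.cell_id), Ec_max=float(r.Ec_max), Es_max=float(r.Es_max)
        )
        for r in df.itertuples()
    ]


def write_traces_csv(traces: list[IntensityTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "channel": t.channel,
                "time_hr": t.times_hr,
                "intensity": t.values,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    traces = []
    for (cell_id, channel), sub in df.groupby(["cell_id", "channel"], sort=False):
        sub = sub.sort_values("time_hr")
        traces.append(
            IntensityTrace(
                times_hr=sub["time_hr"].to_numpy(),
                values=sub["intensity"].to_numpy(),
                channel=str(channel),
                cell_id=str(cell_id),
            )
        )
    return traces


def write_strain_summaries_csv(
    summaries: list[CellStrainSummary], path: str | Path,
    rate_groups: dict[str, str] | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "rate_group": [
                (rate_groups or {}).get(s.cell_id, "") for s in summaries
            ],
            "mean_Ec": [s.mean_Ec for s in summaries],
            "mean_Es": [s.mean_Es for s in summaries],
            "length_um": [s.length_um for s in summaries],
        }
    )
    df.to_csv(path, index=False)


def write_permeability_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def save_field(field: DisplacementField | StrainField, path: str | Path) -> None:
    """Save a gridded field as a compressed named-array archive (.npz)."""
    arrays = {
        "spacing": np.asarray(field.spacing),
        "origin": np.asarray(field.origin),
    }
    if isinstance(field, DisplacementField):
        arrays["u"] = field.u
    else:
        arrays["E"] = field.E
    np.savez_compressed(path, **arrays)


def load_field(path: str | Path) -> DisplacementField | StrainField:
    with np.load(path) as data:
        spacing = tuple(data["spacing"])
        origin = tuple(data["origin"]) if "origin" in data else (0.0, 0.0, 0.0)
        if "u" in data:
            return DisplacementField(u=data["u"], spacing=spacing, origin=origin)
        if "E" in data:
            return StrainField(E=data["E"], spacing=spacing, origin=origin)
    raise ValueError(f"{path}: expected a 'u' or 'E' array")


def displacement_from_tiff(
    paths: tuple[str | Path, str | Path, str | Path],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DisplacementField:
    """Import per-axis displacement component stacks from multi-page TIFFs."""
    import tifffile

    comps = [np.asarray(tifffile.imread(str(p)), dtype=float) for p in paths]
    if not all(c.shape == comps[0].shape for c in comps):
        raise ValueError("component stacks must share a shape")
    return DisplacementField(
        u=np.stack(comps, axis=-1), spacing=spacing, origin=origin
    )


def write_fit_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
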