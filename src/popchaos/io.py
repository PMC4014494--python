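"""Reading and writing abundance series and ensemble directory layouts.

On disk a run is ``conc_<value>/run_<i>.csv`` with the header
``day,neonates,juveniles,adults,total`` plus a JSON sidecar
``run_<i>.json`` holding ``{concentration, run, seed}``. External data in
the same schema can be analysed in place of simulator output.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .population import AbundanceSeries

CSV_COLUMNS = ("day", "neonates", "juveniles", "adults", "total")


def _conc_tag(c: float) -> str:
    return f"conc_{c:g}"


def write_series(series: AbundanceSeries, directory, run: int | None = None) -> Path:
    """Write one run (CSV + JSON sidecar) into an ensemble directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    i = series.run if run is None else run
    csv_path = directory / f"run_{i}.csv"
    series.to_frame().to_csv(csv_path, index=False)
    sidecar = {"concentration": series.concentration, "run": int(i),
               "seed": int(series.seed)}
    (directory / f"run_{i}.json").write_text(json.dumps(sidecar))
    return csv_path


def write_ensemble(ensemble: list[AbundanceSeries], out_dir) -> Path:
    """Write ``out_dir/conc_<c>/run_<i>.csv`` for a single-treatment ensemble."""
    out_dir = Path(out_dir)
    if not ensemble:
        raise ValueError("empty ensemble")
    conc_dir = out_dir / _conc_tag(ensemble[0].concentration)
    for s in ensemble:
        write_series(s, conc_dir)
    return conc_dir


def validate_frame(df: pd.DataFrame, path: str = "<memory>") -> None:
    """Schema checks for an abundance CSV; raises with the offending detail."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    day = df["day"].to_numpy()
    expected = np.arange(day.size)
    if not np.array_equal(day, expected):
        gap = int(expected[np.argmax(day != expected)])
        raise ValueError(f"{path}: day column must be 0..N without gaps "
                         f"(first problem at day {gap})")
    counts = df[["neonates", "juveniles", "adults", "total"]].to_numpy()
    if (counts < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    bad = np.flatnonzero(df["neonates"] + df["juveniles"] + df["adults"]
                         != df["total"])
    if bad.size:
        raise ValueError(f"{path}: class counts do not sum to total at day "
                         f"{int(bad[0])}")


def read_series(csv_path) -> AbundanceSeries:
    """Read one abundance CSV (sidecar metadata picked up when present)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    validate_frame(df, str(csv_path))
    meta = {"concentration": 0.0, "run": 0, "seed": 0}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    else:
        m = re.match(r"run_(\d+)$", csv_path.stem)
        if m:
            meta["run"] = int(m.group(1))
        m = re.match(r"conc_([\d.]+)$", csv_path.parent.name)
        if m:
            meta["concentration"] = float(m.group(1))
    return AbundanceSeries(
        day=df["day"].to_numpy(),
        neonates=df["neonates"].to_numpy(),
        juveniles=df["juveniles"].to_numpy(),
        adults=df["adults"].to_numpy(),
        concentration=float(meta["concentration"]),
        run=int(meta["run"]),
        seed=int(meta["seed"]),
    )


def read_ensemble_tree(root) -> dict[float, list[AbundanceSeries]]:
    """Read a ``conc_*/run_*.csv`` tree into {concentration: [series...]}."""
    root = Path(root)
    out: dict[float, list[AbundanceSeries]] = {}
    conc_dirs = sorted(root.glob("conc_*"))
    if not conc_dirs:
        raise ValueError(f"{root}: no conc_<value> subdirectories found")
    for cd in conc_dirs:
        runs = sorted(cd.glob("run_*.csv"),
                      key=lambda p: int(re.findall(r"\d+", p.stem)[0]))
        if not runs:
            raise ValueError(f"{cd}: no run_<i>.csv files")
        series = [read_series(p) for p in runs]
        out[series[0].concentration] = series
    return out
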