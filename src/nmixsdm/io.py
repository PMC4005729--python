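"""CSV/JSON readers and writers for count data, occurrences and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import OccurrenceSet
from .nmixture import CountData


def write_count_data(data: CountData, directory: str | Path) -> dict[str, Path]:
    """Write counts, site covariates and observation covariates as CSVs.

    counts.csv: site_id, survey_1..survey_J (empty cell = missing).
    site_covariates.csv: site_id + one column per covariate.
    obs_covariates.csv: long table keyed by (site_id, survey).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    R, J = data.counts.shape
    site_id = np.arange(1, R + 1)

    counts = pd.DataFrame(data.counts, columns=[f"survey_{j + 1}" for j in range(J)])
    counts.insert(0, "site_id", site_id)
    counts_path = directory / "counts.csv"
    counts.to_csv(counts_path, index=False)

    site = data.site_covariates.copy()
    site.insert(0, "site_id", site_id)
    site_path = directory / "site_covariates.csv"
    site.to_csv(site_path, index=False)

    obs_path = directory / "obs_covariates.csv"
    long = pd.DataFrame({
        "site_id": np.repeat(site_id, J),
        "survey": np.tile(np.arange(1, J + 1), R),
    })
    for name, arr in data.obs_covariates.items():
        long[name] = np.asarray(arr).ravel()
    long.to_csv(obs_path, index=False)
    return {"counts": counts_path, "site_covariates": site_path, "obs_covariates": obs_path}


def read_count_data(counts_csv: str | Path, site_csv: str | Path,
                    obs_csv: str | Path | None = None) -> CountData:
    for p in (counts_csv, site_csv) + ((obs_csv,) if obs_csv else ()):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    counts = pd.read_csv(counts_csv).sort_values("site_id")
    site = pd.read_csv(site_csv).sort_values("site_id").drop(columns=["site_id"])
    survey_cols = [c for c in counts.columns if c.startswith("survey_")]
    y = counts[survey_cols].to_numpy(dtype=float)
    obs = {}
    if obs_csv is not None:
        long = pd.read_csv(obs_csv).sort_values(["site_id", "survey"])
        R, J = y.shape
        for name in long.columns:
            if name in ("site_id", "survey"):
                continue
            obs[name] = long[name].to_numpy(dtype=float).reshape(R, J)
    return CountData(counts=y, site_covariates=site.reset_index(drop=True),
                     obs_covariates=obs)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    pd.DataFrame({
        "species": occ.species, "x": occ.points[:, 0], "y": occ.points[:, 1],
    }).to_csv(path, index=False)


def read_occurrences(path: str | Path, species: str | None = None) -> OccurrenceSet:
    df = pd.read_csv(path)
    if species is not None:
        df = df[df["species"] == species]
        if df.empty:
            raise ValueError(f"no occurrences for species {species!r} in {path}")
    name = species if species is not None else str(df["species"].iloc[0])
    return OccurrenceSet(species=name, points=df[["x", "y"]].to_numpy(dtype=float))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
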