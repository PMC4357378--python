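"""File formats: pool frequency tables, difference matrices, scenario configs.

All formats are plain text.  Frequency tables and difference matrices are
TSV; scenario and grid configurations are YAML key-value files.  Pool sets
are 1-based in files (j = 1..J); markers are ordered candidate-first.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ScenarioConfig
from .stats import DifferenceMatrix, PoolDataError, PoolFrequencyTable

__all__ = [
    "read_pool_table",
    "write_pool_table",
    "read_dmatrix",
    "write_dmatrix",
    "load_scenario_config",
    "dump_scenario_config",
    "load_grid",
]

POOL_TABLE_COLUMNS = ("marker_id", "pool_set", "p1", "p0")
CANDIDATE_ID = "candidate"


def read_pool_table(path: str | Path, candidate: str | None = None) -> PoolFrequencyTable:
    """Read a long-format TSV of pool allele frequencies.

    Columns: marker_id, pool_set (1-based), p1, p0; every (marker,
    pool_set) pair exactly once over a full grid.  The candidate marker is
    the one named ``candidate`` (or the id passed via ``candidate=``); it
    becomes row 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str}, float_precision="round_trip")
    missing = [c for c in POOL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PoolDataError(f"{path}: missing required column(s) {missing}")
    if df[["p1", "p0"]].isna().any().any():
        raise PoolDataError(f"{path}: missing p1/p0 cell")

    dup = df.duplicated(subset=["marker_id", "pool_set"])
    if dup.any():
        row = df[dup].iloc[0]
        raise PoolDataError(
            f"{path}: duplicate entry for marker {row.marker_id!r}, pool set {row.pool_set}"
        )

    cand = candidate if candidate is not None else CANDIDATE_ID
    markers = list(dict.fromkeys(df["marker_id"]))
    if cand not in markers:
        raise PoolDataError(f"{path}: candidate marker {cand!r} not found")
    markers = [cand] + [m for m in markers if m != cand]

    sets = np.sort(df["pool_set"].unique())
    J = len(sets)
    if not np.array_equal(sets, np.arange(1, J + 1)):
        raise PoolDataError(f"{path}: pool_set values must be exactly 1..J, got {sets.tolist()}")
    if len(df) != len(markers) * J:
        raise PoolDataError(
            f"{path}: ragged data — expected the full {len(markers)} x {J} grid "
            f"({len(markers) * J} rows), found {len(df)} rows"
        )

    for col in ("p1", "p0"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            row = bad.iloc[0]
            raise PoolDataError(
                f"{path}: {col} = {row[col]!r} outside [0, 1] at marker "
                f"{row.marker_id!r}, pool set {row.pool_set}"
            )

    wide1 = df.pivot(index="marker_id", columns="pool_set", values="p1")
    wide0 = df.pivot(index="marker_id", columns="pool_set", values="p0")
    return PoolFrequencyTable(
        markers=tuple(markers),
        p1=wide1.loc[markers, sets].to_numpy(),
        p0=wide0.loc[markers, sets].to_numpy(),
    )


def write_pool_table(table: PoolFrequencyTable, path: str | Path) -> None:
    """Write the long-format TSV (full precision), candidate rows first."""
    records = [
        (table.markers[i], j + 1, table.p1[i, j], table.p0[i, j])
        for i in range(table.n_markers)
        for j in range(table.n_sets)
    ]
    pd.DataFrame.from_records(records, columns=POOL_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_dmatrix(path: str | Path) -> DifferenceMatrix:
    """Read a wide TSV difference matrix (first data row = candidate)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str}, float_precision="round_trip")
    if "marker_id" not in df.columns or df.shape[1] < 3:
        raise PoolDataError(
            f"{path}: expected columns marker_id, set_1..set_J (J >= 2)"
        )
    vals = df.drop(columns="marker_id").to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise PoolDataError(f"{path}: non-finite or unparseable numeric cell")
    return DifferenceMatrix(D=vals, markers=tuple(df["marker_id"]))


def write_dmatrix(D: DifferenceMatrix, path: str | Path) -> None:
    markers = D.markers or tuple(
        [CANDIDATE_ID] + [f"null_{i}" for i in range(1, D.D.shape[0])]
    )
    df = pd.DataFrame(D.D, columns=[f"set_{j + 1}" for j in range(D.n_sets)])
    df.insert(0, "marker_id", markers)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _scenario_from_mapping(data: dict, where: str) -> ScenarioConfig:
    known = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise PoolDataError(f"{where}: unknown scenario field(s) {sorted(unknown)}")
    if "kappa_range" in data:
        kr = data["kappa_range"]
        if not (isinstance(kr, (list, tuple)) and len(kr) == 2):
            raise PoolDataError(f"{where}: kappa_range must be a [lo, hi] pair")
        data = {**data, "kappa_range": (float(kr[0]), float(kr[1]))}
    return ScenarioConfig(**data)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario YAML (any subset of ScenarioConfig fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PoolDataError(f"{path}: scenario config must be a key-value mapping")
    return _scenario_from_mapping(data, str(path))


def dump_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write the fully-resolved scenario (all defaults materialized)."""
    data = asdict(config)
    data["kappa_range"] = list(config.kappa_range)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_grid(path: str | Path) -> tuple[str, list[ScenarioConfig], list[float]]:
    """Load an experiment grid YAML.

    Schema: ``mode`` ("type1" or "power"), optional ``alphas`` (default
    [0.05, 0.005]), ``base`` (scenario fields), ``vary`` (mapping of
    scenario field -> list of values, expanded as a full factorial
    product).  Returns (mode, scenarios, alphas).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not data:
        raise PoolDataError(f"{path}: no scenarios (empty grid file)")
    if not isinstance(data, dict):
        raise PoolDataError(f"{path}: grid file must be a key-value mapping")
    mode = data.get("mode", "type1")
    if mode not in ("type1", "power"):
        raise PoolDataError(f"{path}: mode must be 'type1' or 'power', got {mode!r}")
    alphas = [float(a) for a in data.get("alphas", [0.05, 0.005])]
    base = data.get("base", {}) or {}
    vary = data.get("vary", {}) or {}
    keys = list(vary)
    combos = list(itertools.product(*(vary[k] for k in keys))) if keys else [()]
    scenarios = [
        _scenario_from_mapping({**base, **dict(zip(keys, combo))}, str(path))
        for combo in combos
    ]
    if not scenarios:
        raise PoolDataError(f"{path}: no scenarios (empty grid)")
    return mode, scenarios, alphas
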