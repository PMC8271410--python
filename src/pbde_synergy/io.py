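"""Readers and writers for the pipeline's CSV dialects, plus packaged fixtures.

All readers normalize typographic minus/dash characters (U+2212, U+2013) to
ASCII before parsing, since the source tables use them.
"""
from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .queuing import ScoreTable

__all__ = [
    "fixture_path",
    "read_score_table",
    "read_predictions",
    "read_env_profiles",
    "read_responses",
    "read_interactions",
    "read_snr_ledger",
]

FIXTURES = (
    "table1_scores.csv",
    "table3_predictions.csv",
    "table4_env.csv",
    "table5_snr.csv",
    "table6_responses.csv",
    "table7_interactions.csv",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return Path(resources.files("pbde_synergy.data") / name)


def _read_csv(path, **kwargs) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    text = text.replace("−", "-").replace("–", "-")
    return pd.read_csv(_io.StringIO(text), **kwargs)


def _require_numeric(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = bad[0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row}, column {col!r}"
            )
        df[col] = coerced


def read_score_table(path, endpoints: tuple[str, ...] = ("PS", "MS")) -> ScoreTable:
    """Read a molecule_id,PS,MS,... CSV into a validated ScoreTable."""
    df = _read_csv(path)
    if "molecule_id" not in df.columns:
        raise ValueError(f"{path}: missing molecule_id header")
    missing = [e for e in endpoints if e not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing endpoint column(s) {missing}")
    dupes = df["molecule_id"][df["molecule_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate molecule_ids: {dupes}")
    _require_numeric(df, list(endpoints), path)
    return ScoreTable(df.set_index("molecule_id")[list(endpoints)])


def read_predictions(path) -> pd.DataFrame:
    """Model predictions per derivative, indexed by molecule id."""
    df = _read_csv(path)
    cols = [c for c in df.columns if c != "molecule_id"]
    _require_numeric(df, cols, path)
    return df.set_index("molecule_id")


def read_env_profiles(path) -> pd.DataFrame:
    """Environmental/flame-retardancy property profiles."""
    df = _read_csv(path)
    num = ["cbr_bde_kcal_mol", "ec50_mg_l", "log_bcf", "vp_pa"]
    _require_numeric(df, num, path)
    df["insoluble"] = df["insoluble"].astype(bool)
    return df.set_index("molecule_id")


def read_responses(path) -> pd.DataFrame:
    """Long-format DOE responses: run, system, binding_energy_kj_mol.

    Empty energy cells are kept as NaN (failed simulations, not zeros).
    Extra columns (factor levels) pass through untouched.
    """
    df = _read_csv(path)
    req = {"run", "system", "binding_energy_kj_mol"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: responses need columns {sorted(req)}")
    _require_numeric(df, ["binding_energy_kj_mol"], path)
    df["run"] = df["run"].astype(int)
    return df


def read_interactions(path) -> pd.DataFrame:
    """Contact records: ligand, receptor, residue, distance_A, bond_type."""
    df = _read_csv(path)
    req = {"ligand", "receptor", "residue", "distance_A", "bond_type"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: interactions need columns {sorted(req)}")
    _require_numeric(df, ["distance_A"], path)
    return df


def read_snr_ledger(path, group: str) -> pd.DataFrame:
    """A printed SNR ledger (factor, level means, delta, rank) for one group."""
    df = _read_csv(path)
    df = df[df["group"] == group].drop(columns="group")
    if df.empty:
        raise ValueError(f"{path}: no rows for group {group!r}")
    _require_numeric(df, ["level1_mean", "level2_mean", "delta", "rank"], path)
    df["rank"] = df["rank"].astype(int)
    return df.set_index("factor")


def write_csv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label=index_label, float_format="%.6g")
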