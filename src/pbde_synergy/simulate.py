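"""Seeded synthetic-data generators for every pipeline stage.

Each generator takes an explicit seed, uses one local random source and is
bit-reproducible; no global random state is touched.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qsar.pls import QsarDataset

__all__ = [
    "ScoreTableSpec",
    "FieldDatasetSpec",
    "DoeResponseSpec",
    "gen_score_table",
    "gen_field_dataset",
    "gen_doe_responses",
]

# sample moments of the packaged docking-score fixture (PS, MS)
TABLE1_MOMENTS = {
    "mean_ps": 47.73,
    "mean_ms": 52.13,
    "std_ps": 8.51,
    "std_ms": 6.88,
    "rho": 0.31,
}


@dataclass(frozen=True)
class ScoreTableSpec:
    n_molecules: int = 177
    mean_ps: float = TABLE1_MOMENTS["mean_ps"]
    mean_ms: float = TABLE1_MOMENTS["mean_ms"]
    std_ps: float = TABLE1_MOMENTS["std_ps"]
    std_ms: float = TABLE1_MOMENTS["std_ms"]
    rho: float = TABLE1_MOMENTS["rho"]

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if self.std_ps <= 0 or self.std_ms <= 0:
            raise ValueError("stdevs must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")


def gen_score_table(spec: ScoreTableSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Bivariate-normal (PS, MS) docking scores, clipped to stay positive."""
    if spec is None:
        spec = ScoreTableSpec()
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [spec.std_ps**2, spec.rho * spec.std_ps * spec.std_ms],
            [spec.rho * spec.std_ps * spec.std_ms, spec.std_ms**2],
        ]
    )
    draws = rng.multivariate_normal([spec.mean_ps, spec.mean_ms], cov, size=spec.n_molecules)
    draws = np.clip(draws, 1e-3, None)
    return pd.DataFrame(
        draws,
        columns=["PS", "MS"],
        index=pd.Index([f"M{i+1}" for i in range(spec.n_molecules)], name="molecule_id"),
    )


@dataclass(frozen=True)
class FieldDatasetSpec:
    """Planted-structure field/activity dataset for PLS recovery tests."""

    n_molecules: int = 40
    n_steric: int = 60
    n_electro: int = 60
    n_components: int = 3
    mass_split: tuple[float, float] = (1.0, 1.0)  # steric : electrostatic
    noise_scale: float = 0.1  # y-noise stdev as fraction of signal stdev
    x_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.n_components > self.n_molecules - 2:
            raise ValueError("latent components must be <= molecules - 2")
        if self.noise_scale < 0 or self.x_noise < 0:
            raise ValueError("noise must be >= 0")


def gen_field_dataset(
    spec: FieldDatasetSpec | None = None, seed: int = 0
) -> tuple[QsarDataset, dict]:
    """X = latent scores x loadings + noise; y linear in the latent scores.

    Components are assigned alternately to the steric and electrostatic
    column blocks and their activity weights are scaled so total coefficient
    mass splits between the blocks as ``mass_split``. Returns the dataset
    plus a ground-truth dict for recovery assertions.
    """
    if spec is None:
        spec = FieldDatasetSpec()
    rng = np.random.default_rng(seed)
    n, a = spec.n_molecules, spec.n_components
    p_s, p_e = spec.n_steric, spec.n_electro

    T = rng.standard_normal((n, a))
    fields_of_comp = ["steric" if j % 2 == 0 else "electrostatic" for j in range(a)]
    if a == 1:
        fields_of_comp = ["steric"]
    P = np.zeros((a, p_s + p_e))
    for j, f in enumerate(fields_of_comp):
        block = slice(0, p_s) if f == "steric" else slice(p_s, p_s + p_e)
        load = rng.standard_normal(block.stop - block.start)
        P[j, block] = load / np.linalg.norm(load)

    w = rng.uniform(0.5, 1.5, size=a)
    ms, me = spec.mass_split
    n_s = max(sum(f == "steric" for f in fields_of_comp), 1)
    n_e = max(sum(f == "electrostatic" for f in fields_of_comp), 1)
    for j, f in enumerate(fields_of_comp):
        w[j] *= (ms / n_s) if f == "steric" else (me / n_e)

    X = T @ P + spec.x_noise * rng.standard_normal((n, p_s + p_e))
    signal = T @ w
    y = signal + spec.noise_scale * signal.std() * rng.standard_normal(n)

    ids = pd.Index([f"M{i+1}" for i in range(n)], name="molecule_id")
    columns = pd.DataFrame({"field": ["steric"] * p_s + ["electrostatic"] * p_e})
    dataset = QsarDataset(
        X=pd.DataFrame(X, index=ids),
        y=pd.Series(y, index=ids, name="CS"),
        columns=columns,
    )
    truth = {
        "n_components": a,
        "weights": w,
        "component_fields": fields_of_comp,
        "mass_split": spec.mass_split,
        "signal": signal,
    }
    return dataset, truth


@dataclass(frozen=True)
class DoeResponseSpec:
    """Main-effect model for binding-energy responses (kJ/mol, <= 0)."""

    control_energy: float = -40.0
    effects: tuple[float, ...] = ()  # per-factor shift when the factor is at level 1
    noise: float = 1.0

    def __post_init__(self) -> None:
        if self.control_energy > 0:
            raise ValueError("control binding energy must be <= 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def gen_doe_responses(
    design: pd.DataFrame, spec: DoeResponseSpec, seed: int = 0
) -> pd.Series:
    """Binding energy per run: control + sum(effect * level) + noise, <= 0."""
    effects = np.asarray(spec.effects, dtype=float)
    if effects.size != design.shape[1]:
        raise ValueError("one effect per design factor required")
    rng = np.random.default_rng(seed)
    levels = design.to_numpy(float)
    energy = spec.control_energy + levels @ effects
    energy = energy + spec.noise * rng.standard_normal(len(design))
    if (energy > 0).any():
        warnings.warn("effects pushed binding energy positive; clipping to 0", stacklevel=2)
        energy = np.minimum(energy, 0.0)
    return pd.Series(energy, index=design.index, name="binding_energy_kj_mol")
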