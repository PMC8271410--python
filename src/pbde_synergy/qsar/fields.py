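"""Steric and electrostatic probe fields on a regular lattice.

Aligned conformers are sampled by an sp3-carbon, +1 charge probe on a grid
covering their union bounding box. Steric energies are Lennard-Jones 6-12
sums truncated at a cutoff; electrostatic energies are Coulomb sums with a
distance-dependent dielectric eps(r) = r.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Conformer",
    "ConformerSet",
    "GridSpec",
    "FieldGrid",
    "probe_energies",
    "compute_fields",
    "read_atom_table",
]

COULOMB_K = 332.0  # kcal*A/(mol*e^2)

# van der Waals radius (A), well depth (kcal/mol) — Tripos-style parameters
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}
PROBE_RADIUS, PROBE_EPS = VDW_PARAMS["C"]  # sp3 carbon probe


@dataclass(frozen=True)
class Conformer:
    """One molecule: element symbols, coordinates (A) and partial charges (e)."""

    molecule_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3)
    charges: np.ndarray  # (n_atoms,)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        charges = np.asarray(self.charges, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"{self.molecule_id}: coords must be (n_atoms, 3), n>=1")
        if charges.shape != (coords.shape[0],):
            raise ValueError(f"{self.molecule_id}: one charge per atom required")
        if not (np.isfinite(coords).all() and np.isfinite(charges).all()):
            raise ValueError(f"{self.molecule_id}: non-finite coordinates/charges")
        unknown = sorted(set(self.elements) - set(VDW_PARAMS))
        if unknown:
            raise ValueError(f"{self.molecule_id}: no vdW parameters for {unknown}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)


@dataclass(frozen=True)
class ConformerSet:
    conformers: tuple[Conformer, ...]
    aligned: bool = True

    def __post_init__(self) -> None:
        ids = [c.molecule_id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in conformer set")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class GridSpec:
    """Lattice parameters; defaults follow common CoMFA practice."""

    spacing: float = 2.0
    margin: float = 4.0
    steric_cutoff: float = 30.0
    probe_charge: float = 1.0
    min_sigma: float = 2.0  # drop columns with stdev below this (kcal/mol)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.margin < 0 or self.steric_cutoff <= 0:
            raise ValueError("margin must be >= 0 and cutoff > 0")


@dataclass(frozen=True)
class FieldGrid:
    """Probe energies of one molecule on a shared lattice."""

    molecule_id: str
    origin: np.ndarray  # (3,)
    spacing: float
    shape: tuple[int, int, int]
    steric: np.ndarray  # (n_points,) kcal/mol, truncated
    electrostatic: np.ndarray  # (n_points,) kcal/mol
    steric_clipped: np.ndarray = field(repr=False, default=None)  # bool mask


def lattice_points(origin: np.ndarray, spacing: float, shape: tuple[int, int, int]) -> np.ndarray:
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_lattice(conformers: ConformerSet, spec: GridSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Origin and shape of a lattice enclosing every conformer plus margin."""
    all_xyz = np.vstack([c.coords for c in conformers.conformers])
    lo = all_xyz.min(axis=0) - spec.margin
    hi = all_xyz.max(axis=0) + spec.margin
    shape = tuple(int(np.floor((hi[d] - lo[d]) / spec.spacing)) + 1 for d in range(3))
    return lo, shape


def probe_energies(
    conformer: Conformer,
    points: np.ndarray,
    spec: GridSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steric and electrostatic probe energy at each lattice point.

    Returns (steric, electrostatic, clipped_mask). Steric is clipped to
    +/- cutoff; the mask marks points at the positive cutoff (sterically
    excluded volume).
    """
    diff = points[:, None, :] - conformer.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    r = np.maximum(r, 1e-6)

    radii = np.array([VDW_PARAMS[e][0] for e in conformer.elements])
    eps = np.array([VDW_PARAMS[e][1] for e in conformer.elements])
    r_min = radii + PROBE_RADIUS  # pair minimum-energy distance
    eps_ij = np.sqrt(eps * PROBE_EPS)
    ratio6 = (r_min[None, :] / r) ** 6
    lj = eps_ij[None, :] * (ratio6**2 - 2.0 * ratio6)
    steric = np.clip(lj.sum(axis=1), -spec.steric_cutoff, spec.steric_cutoff)
    clipped = steric >= spec.steric_cutoff

    # eps(r) = r distance-dependent dielectric -> k*q*q/r^2
    elec = (COULOMB_K * spec.probe_charge * conformer.charges[None, :] / r**2).sum(axis=1)
    return steric, elec, clipped


def compute_fields(
    conformers: ConformerSet,
    spec: GridSpec | None = None,
) -> tuple[list[FieldGrid], pd.DataFrame, pd.DataFrame]:
    """Field grids per molecule plus the assembled descriptor matrix.

    Returns (grids, X, column metadata). X rows are molecules; columns are
    the lattice steric block followed by the lattice electrostatic block,
    after two fixups: electrostatic values at sterically excluded points are
    replaced by their column mean over the non-excluded molecules, and
    columns with standard deviation below ``min_sigma`` are dropped.
    """
    if spec is None:
        spec = GridSpec()
    if not conformers.aligned:
        raise ValueError("conformers must share one aligned frame of reference")
    if all(np.allclose(c.charges, 0.0) for c in conformers.conformers):
        import warnings

        warnings.warn("all partial charges are zero; electrostatic block is zero", stacklevel=2)

    origin, shape = build_lattice(conformers, spec)
    points = lattice_points(origin, spec.spacing, shape)
    grids: list[FieldGrid] = []
    ster_rows, elec_rows, clip_rows = [], [], []
    for conf in conformers.conformers:
        steric, elec, clipped = probe_energies(conf, points, spec)
        grids.append(
            FieldGrid(conf.molecule_id, origin, spec.spacing, shape, steric, elec, clipped)
        )
        ster_rows.append(steric)
        elec_rows.append(elec)
        clip_rows.append(clipped)

    S = np.vstack(ster_rows)
    E = np.vstack(elec_rows)
    C = np.vstack(clip_rows)
    # excluded-volume electrostatics -> column mean of the remaining molecules
    with np.errstate(invalid="ignore"):
        import warnings as _warnings

        masked = np.where(C, np.nan, E)
        with _warnings.catch_warnings():
            # columns excluded for every molecule fall back to 0
            _warnings.filterwarnings("ignore", message="Mean of empty slice")
            col_mean = np.nanmean(masked, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    E = np.where(C, col_mean[None, :], E)

    n_pts = S.shape[1]
    ids = [c.molecule_id for c in conformers.conformers]
    X = np.hstack([S, E])
    meta = pd.DataFrame(
        {
            "field": ["steric"] * n_pts + ["electrostatic"] * n_pts,
            "point": list(range(n_pts)) * 2,
        }
    )
    keep = X.std(axis=0) >= spec.min_sigma
    X = pd.DataFrame(X[:, keep], index=ids, columns=np.flatnonzero(keep))
    meta = meta.loc[keep.nonzero()[0]].reset_index(names="raw_column")
    return grids, X, meta


def read_atom_table(path, molecule_id: str | None = None) -> Conformer:
    """Read a plain per-atom CSV (element,x,y,z,charge) as a Conformer."""
    df = pd.read_csv(path)
    req = {"element", "x", "y", "z", "charge"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: atom table needs columns {sorted(req)}")
    if molecule_id is None:
        from pathlib import Path

        molecule_id = Path(path).stem
    return Conformer(
        molecule_id=molecule_id,
        elements=tuple(df["element"].astype(str)),
        coords=df[["x", "y", "z"]].to_numpy(float),
        charges=df["charge"].to_numpy(float),
    )
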