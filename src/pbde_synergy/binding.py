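"""Protein-ligand contact statistics and end-state binding-energy ledgers."""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HYDROPHOBIC",
    "AMINO_ACIDS",
    "BondStats",
    "EnergyDecomposition",
    "bond_stats",
    "length_change",
    "mmpbsa_ledger",
    "term_change_rates",
]

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
DEFAULT_HYDROPHOBIC = frozenset("ALA VAL LEU ILE PRO PHE MET TRP".split())

_RESIDUE_RE = re.compile(r"^[A-Z]{3}\d+$")
HALOGEN_BOND_TYPE = "Br"


@dataclass(frozen=True)
class BondStats:
    """Summary of one ligand/receptor contact table."""

    contact_count: int
    mean_distance: float
    halogen_bond_count: int
    hydrophobic_fraction: float
    residue_count: int  # distinct amino-acid residues, cofactors excluded


def bond_stats(
    table: pd.DataFrame,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> BondStats:
    """Contact statistics for one ligand-receptor interaction table.

    Every listed distance counts once in the mean (a residue with two
    contacts contributes twice). Halogen bonds are records typed 'Br'.
    Cofactors (residue code not a standard amino acid) contribute distances
    but are excluded from residue counts and the hydrophobic fraction.
    """
    if len(table) == 0:
        raise ValueError("empty interaction table")
    res = table["residue"].astype(str)
    bad = res[~res.str.match(_RESIDUE_RE)].tolist()
    if bad:
        raise ValueError(f"malformed residue labels: {bad}")
    d = table["distance_A"].astype(float)
    if (d <= 0).any():
        raise ValueError("contact distances must be positive")

    codes = res.str[:3]
    is_aa = codes.isin(AMINO_ACIDS)
    residues = res[is_aa].unique()
    hydro = [r for r in residues if r[:3] in hydrophobic_set]
    frac = len(hydro) / len(residues) if len(residues) else 0.0
    return BondStats(
        contact_count=len(table),
        mean_distance=float(d.mean()),
        halogen_bond_count=int((table["bond_type"] == HALOGEN_BOND_TYPE).sum()),
        hydrophobic_fraction=frac,
        residue_count=len(residues),
    )


def length_change(before: BondStats, after: BondStats) -> float:
    """Percent decrease in mean contact distance, on unrounded means."""
    if before.mean_distance <= 0:
        raise ValueError("reference mean distance must be positive")
    return (before.mean_distance - after.mean_distance) / before.mean_distance * 100.0


@dataclass(frozen=True)
class EnergyDecomposition:
    """End-state binding free-energy ledger (one unit system, kJ/mol).

    ``g_bind`` is always G_complex - G_protein - G_ligand. When the
    gas/solvation split is supplied, G = E_gas - T*S_gas + G_solvation and
    G_solvation = G_polar + G_nonpolar must hold. An optional per-term
    ledger (van der Waals, electrostatic, polar solvation, SASA, SAV, WCA)
    must sum to ``total`` within tolerance.
    """

    g_complex: float
    g_free_protein: float
    g_free_ligand: float
    g_bind: float
    e_gas: float | None = None
    ts_gas: float | None = None
    g_solvation: float | None = None
    g_polar: float | None = None
    g_nonpolar: float | None = None
    terms: dict[str, float] = field(default_factory=dict)
    total: float | None = None


_LEDGER_TOL = 0.01  # kJ/mol


def mmpbsa_ledger(
    g_complex: float,
    g_free_protein: float,
    g_free_ligand: float,
    e_gas: float | None = None,
    ts_gas: float | None = None,
    g_polar: float | None = None,
    g_nonpolar: float | None = None,
    terms: dict[str, float] | None = None,
    total: float | None = None,
) -> EnergyDecomposition:
    """Assemble and validate an MM/PBSA-style energy decomposition.

    Fills G_bind from the three state energies; when polar/nonpolar parts
    are given, fills G_solvation (and G from the gas-phase split when that
    is also supplied). A supplied per-term ledger must sum to ``total``
    within 0.01 kJ/mol, otherwise the residual is reported in the error.
    """
    g_bind = g_complex - g_free_protein - g_free_ligand
    g_solvation = None
    if g_polar is not None and g_nonpolar is not None:
        g_solvation = g_polar + g_nonpolar
    terms = dict(terms or {})
    if terms:
        ledger_sum = sum(terms.values())
        if total is None:
            total = ledger_sum
        elif abs(ledger_sum - total) > _LEDGER_TOL:
            raise ValueError(
                f"term ledger sums to {ledger_sum:.4f}, expected {total:.4f} "
                f"(residual {ledger_sum - total:+.4f} kJ/mol)"
            )
    return EnergyDecomposition(
        g_complex=g_complex,
        g_free_protein=g_free_protein,
        g_free_ligand=g_free_ligand,
        g_bind=g_bind,
        e_gas=e_gas,
        ts_gas=ts_gas,
        g_solvation=g_solvation,
        g_polar=g_polar,
        g_nonpolar=g_nonpolar,
        terms=terms,
        total=total,
    )


def solution_free_energy(decomp: EnergyDecomposition) -> float:
    """G = E_gas - T*S_gas + G_solvation; needs the gas/solvation split."""
    if decomp.e_gas is None or decomp.ts_gas is None or decomp.g_solvation is None:
        raise ValueError("gas/solvation split not supplied")
    return decomp.e_gas - decomp.ts_gas + decomp.g_solvation


def term_change_rates(
    before: EnergyDecomposition,
    after: EnergyDecomposition,
) -> tuple[dict[str, float | None], str | None]:
    """Per-term percent change (after - before)/|before| * 100.

    Terms at zero before and after report 0; a zero-before/nonzero-after
    term is flagged undefined (None) and skipped when picking the largest
    magnitude rate. Strengthening (more negative) terms give negative rates.
    """
    if set(before.terms) != set(after.terms):
        raise ValueError("term ledgers do not match")
    rates: dict[str, float | None] = {}
    for name, b in before.terms.items():
        a = after.terms[name]
        if b == 0:
            rates[name] = 0.0 if a == 0 else None
        else:
            rates[name] = (a - b) / abs(b) * 100.0
    defined = {k: v for k, v in rates.items() if v is not None}
    largest = max(defined, key=lambda k: abs(defined[k]), default=None)
    return rates, largest
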