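"""Relative-change arithmetic and rule-based derivative selection.

Covers the degradability screen over model predictions, the environmental /
flame-retardancy screen over property profiles, and homolysis-enthalpy
bookkeeping for the C-Br bond.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnthalpyComponents",
    "relative_change",
    "functional_screen",
    "environmental_screen",
    "standard_enthalpy",
    "bond_dissociation_enthalpy",
]

MODEL_LABELS = ("CM", "PM", "MM")

# kcal/mol per unit of each tag
_UNIT_TO_KCAL = {"kcal/mol": 1.0, "kJ/mol": 1.0 / 4.184, "hartree": 627.5094740631}


def relative_change(value: float, reference: float, ndigits: int | None = None) -> float:
    """Percent change of ``value`` relative to ``reference``.

    (value - reference) / reference * 100; optionally rounded to ``ndigits``.
    """
    if reference == 0:
        raise ZeroDivisionError("relative_change undefined for reference == 0")
    pct = (value - reference) / reference * 100.0
    return round(pct, ndigits) if ndigits is not None else pct


def functional_screen(
    predictions: pd.DataFrame,
    template: str = "BDEs-3",
    models: tuple[str, ...] = MODEL_LABELS,
) -> list[str]:
    """Select derivatives whose predictions beat the template on every model.

    ``predictions`` is indexed by molecule id with one column per model
    label; selection requires a strictly greater prediction in all columns.
    """
    missing = [m for m in models if m not in predictions.columns]
    if missing:
        raise KeyError(f"missing model column(s): {missing}")
    if template not in predictions.index:
        raise KeyError(f"template {template!r} not in predictions")
    ref = predictions.loc[template, list(models)]
    others = predictions.drop(index=template)
    mask = (others[list(models)] > ref).all(axis=1)
    return others.index[mask].tolist()


def environmental_screen(
    profiles: pd.DataFrame,
    template: str = "BDEs-3",
) -> tuple[list[str], pd.DataFrame, dict[str, int]]:
    """Screen derivative property profiles against the template molecule.

    ``profiles`` is indexed by molecule id with columns ``cbr_bde_kcal_mol``
    (C-Br bond-dissociation enthalpy), ``ec50_mg_l``, ``log_bcf``, ``vp_pa``
    and a boolean ``insoluble`` flag. A derivative passes when, versus the
    template: the C-Br enthalpy is >= (flame retardancy maintained), and
    EC50, logBCF and vapor pressure are all strictly lower. Insoluble-flagged
    rows are excluded from screening but kept in the ledger with a reason.

    Returns (selected ids, per-derivative ledger, per-criterion pass counts).
    """
    if template not in profiles.index:
        raise KeyError(f"template {template!r} not in profiles")
    tpl = profiles.loc[template]
    derivs = profiles.drop(index=template)

    measurable = derivs[~derivs["insoluble"].astype(bool)]
    for col in ("ec50_mg_l", "vp_pa"):
        bad = measurable.index[measurable[col] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive {col} for: {bad}")

    ledger = pd.DataFrame(index=derivs.index)
    ledger["excluded_insoluble"] = derivs["insoluble"].astype(bool)
    ledger["flame_retardancy_ok"] = derivs["cbr_bde_kcal_mol"] >= tpl["cbr_bde_kcal_mol"]
    ledger["toxicity_lower"] = derivs["ec50_mg_l"] < tpl["ec50_mg_l"]
    ledger["bcf_lower"] = derivs["log_bcf"] < tpl["log_bcf"]
    ledger["vp_lower"] = derivs["vp_pa"] < tpl["vp_pa"]
    crit_cols = ["flame_retardancy_ok", "toxicity_lower", "bcf_lower", "vp_lower"]
    # insoluble rows do not count toward any criterion
    ledger.loc[ledger["excluded_insoluble"], crit_cols] = False
    ledger["selected"] = ledger[crit_cols].all(axis=1) & ~ledger["excluded_insoluble"]

    counts = {c: int(ledger[c].sum()) for c in crit_cols}
    selected = ledger.index[ledger["selected"]].tolist()
    return selected, ledger, counts


@dataclass(frozen=True)
class EnthalpyComponents:
    """Components of a species' standard enthalpy at a given temperature.

    All energy terms share one declared unit tag ('kcal/mol', 'kJ/mol' or
    'hartree'); ``rt`` is the gas-constant * temperature term in that unit.
    """

    electronic_energy: float
    zpe: float
    h_trans: float
    h_rot: float
    h_vib: float
    rt: float
    temperature_k: float = 298.15
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_TO_KCAL:
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")

    def total(self) -> float:
        return (
            self.electronic_energy
            + self.zpe
            + self.h_trans
            + self.h_rot
            + self.h_vib
            + self.rt
        )

    def to_kcal_mol(self) -> float:
        return self.total() * _UNIT_TO_KCAL[self.unit]


def standard_enthalpy(parts: EnthalpyComponents) -> float:
    """H(species) = E + ZPE + H_trans + H_rot + H_vib + RT, in its own unit."""
    return parts.total()


def bond_dissociation_enthalpy(
    radical: EnthalpyComponents,
    bromine: EnthalpyComponents,
    parent: EnthalpyComponents,
) -> float:
    """Homolysis enthalpy H(R) + H(Br) - H(RBr) in kcal/mol.

    All three component sets must carry the same unit tag; the result is
    converted to kcal/mol.
    """
    units = {radical.unit, bromine.unit, parent.unit}
    if len(units) != 1:
        raise ValueError(f"mixed unit tags: {sorted(units)}")
    scale = _UNIT_TO_KCAL[radical.unit]
    return (radical.total() + bromine.total() - parent.total()) * scale


def screen_report(
    predictions: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    template: str = "BDEs-3",
) -> pd.DataFrame:
    """One-row-per-derivative ledger combining both screens.

    Adds per-model relative changes (2 dp) and the functional pass flag;
    when ``profiles`` is given, merges the environmental ledger and a final
    ``recommended`` flag (passes both screens).
    """
    models = [m for m in MODEL_LABELS if m in predictions.columns]
    ref = predictions.loc[template]
    out = predictions.drop(index=template).copy()
    for m in models:
        out[f"{m}_rel_change_pct"] = [
            relative_change(v, ref[m], ndigits=2) for v in out[m]
        ]
    selected = set(functional_screen(predictions, template, tuple(models)))
    out["functional_pass"] = [i in selected for i in out.index]
    if profiles is not None:
        _, ledger, _ = environmental_screen(profiles, template)
        out = out.join(ledger, how="left")
        env_ok = out["selected"].eq(True)
        out["recommended"] = out["functional_pass"] & env_ok
        out = out.drop(columns=["selected"])
    return out
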