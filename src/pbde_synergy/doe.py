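"""Design-of-experiments screening: Taguchi L12 / full factorial designs,
signal-to-noise factor effects, and binding-energy scheme evaluation."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_LABELS",
    "taguchi_L12",
    "full_factorial",
    "snr_larger_is_better",
    "factor_effects",
    "common_divergence_factors",
    "scheme_improvements",
    "SchemeEvaluation",
]

# A=carbon dioxide, B=glucose, C=ammonia-nitrogen, D=urea, E=oxygen,
# F=phosphorus pentoxide, G=phosphate ester, H=magnesium ion, I=calcium ion,
# J=hydrogen peroxide, K=hydrogen sulfide
FACTOR_LABELS = tuple("ABCDEFGHIJK")

# Plackett-Burman 12-run generator row; cyclic shifts + all-low row.
_PB12_GENERATOR = (1, 1, 0, 1, 1, 1, 0, 0, 0, 1, 0)


def taguchi_L12(n_factors: int = 11) -> pd.DataFrame:
    """12-run two-level orthogonal array for up to 11 factors (levels 0/1).

    Every column is balanced 6/6 and every column pair sees each of the four
    level combinations exactly three times.
    """
    if not 1 <= n_factors <= 11:
        raise ValueError(f"n_factors={n_factors} must be in 1..11")
    rows = [list(np.roll(_PB12_GENERATOR, i)) for i in range(11)]
    rows.append([0] * 11)
    design = pd.DataFrame(rows, columns=list(FACTOR_LABELS), dtype=int)
    design = design[list(FACTOR_LABELS[:n_factors])]
    design.index.name = "run"
    return design


def full_factorial(k: int = 4, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """All 2**k two-level combinations in lexicographic order.

    Run 0 (the all-zero row) is the natural blank control.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if labels is None:
        labels = FACTOR_LABELS[:k]
    if len(labels) != k:
        raise ValueError("labels length must equal k")
    grid = np.indices((2,) * k).reshape(k, -1).T
    design = pd.DataFrame(grid, columns=list(labels), dtype=int)
    design.index.name = "run"
    return design


def snr_larger_is_better(responses) -> float:
    """Taguchi larger-the-better SNR in dB: -10*log10(mean(1/y^2))."""
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise ValueError("empty response vector")
    if (y <= 0).any():
        raise ValueError("larger-is-better SNR needs strictly positive responses")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def factor_effects(design: pd.DataFrame, snr) -> pd.DataFrame:
    """Per-factor SNR level means, delta and rank (1 = largest delta).

    ``snr`` gives one SNR value per design run; every run must be present.
    Ties in delta keep the factors' input order.
    """
    snr = np.asarray(snr, dtype=float)
    if len(snr) != len(design):
        raise ValueError(
            f"need one SNR per run: got {len(snr)} for {len(design)} runs"
        )
    if not np.isfinite(snr).all():
        raise ValueError("missing/non-finite SNR values; all runs are required")
    records = []
    for factor in design.columns:
        lv = design[factor].to_numpy()
        m0 = snr[lv == 0].mean()
        m1 = snr[lv == 1].mean()
        records.append((factor, m0, m1, abs(m1 - m0)))
    ledger = pd.DataFrame(
        records, columns=["factor", "level1_mean", "level2_mean", "delta"]
    ).set_index("factor")
    order = np.argsort(-ledger["delta"].to_numpy(), kind="stable")
    ranks = np.empty(len(ledger), dtype=int)
    ranks[order] = np.arange(1, len(ledger) + 1)
    ledger["rank"] = ranks
    return ledger


def common_divergence_factors(
    ledger_a: pd.DataFrame,
    ledger_b: pd.DataFrame,
    top_k: int = 6,
) -> dict[str, tuple[int, int]]:
    """Factors in the top-``top_k`` of both SNR ledgers, with both ranks."""
    if set(ledger_a.index) != set(ledger_b.index):
        raise ValueError("ledgers must cover the same factor universe")
    top_a = set(ledger_a.index[ledger_a["rank"] <= top_k])
    top_b = set(ledger_b.index[ledger_b["rank"] <= top_k])
    common = sorted(top_a & top_b)
    return {
        f: (int(ledger_a.loc[f, "rank"]), int(ledger_b.loc[f, "rank"]))
        for f in common
    }


@dataclass(frozen=True)
class SchemeEvaluation:
    """Per-run relative improvements, synergy flags/averages, best scheme."""

    frame: pd.DataFrame
    control_run: int
    best_scheme: int | None

    @property
    def synergy_runs(self) -> list[int]:
        return self.frame.index[self.frame["synergy"]].tolist()


def scheme_improvements(
    responses: pd.DataFrame,
    control_run: int = 0,
    systems: tuple[str, str] = ("plant", "microbe"),
) -> SchemeEvaluation:
    """Evaluate factorial regulatory schemes by binding-energy improvement.

    ``responses`` has columns ``run``, ``system``, ``binding_energy_kj_mol``
    (NaN = failed simulation). Improvement per system is computed on energy
    magnitudes, (|E_run| - |E_control|)/|E_control| * 100, so positive means
    stronger binding. A run is synergy-flagged when both systems are present
    and both improvements are positive; its synergy average is the mean of
    the two improvements and the best scheme maximizes that average.
    """
    req = {"run", "system", "binding_energy_kj_mol"}
    if not req.issubset(responses.columns):
        raise KeyError(f"responses needs columns {sorted(req)}")
    wide = responses.pivot(index="run", columns="system", values="binding_energy_kj_mol")
    for sys_name in systems:
        if sys_name not in wide.columns:
            raise KeyError(f"system {sys_name!r} absent from responses")
    if control_run not in wide.index:
        raise ValueError(f"control run {control_run} missing")
    present = wide.to_numpy()
    if (present[np.isfinite(present)] > 0).any():
        raise ValueError("binding energies of bound complexes must be <= 0")

    out = pd.DataFrame(index=wide.index.drop(control_run))
    for sys_name in systems:
        e_ctrl = wide.loc[control_run, sys_name]
        if pd.isna(e_ctrl) or e_ctrl == 0:
            raise ValueError(f"control response missing/zero for {sys_name!r}")
        e_run = wide.loc[out.index, sys_name]
        out[f"improvement_{sys_name}_pct"] = (e_run.abs() - abs(e_ctrl)) / abs(e_ctrl) * 100.0

    imp = out[[f"improvement_{s}_pct" for s in systems]]
    out["incomplete"] = imp.isna().any(axis=1)
    out["synergy"] = (~out["incomplete"]) & (imp > 0).all(axis=1)
    out["synergy_avg_pct"] = np.where(out["synergy"], imp.mean(axis=1), np.nan)
    best = None
    if out["synergy"].any():
        best = int(out["synergy_avg_pct"].idxmax())
    return SchemeEvaluation(frame=out, control_run=control_run, best_scheme=best)
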