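"""Umbrella pipeline: run the requested stages and write a report bundle."""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import binding, doe, io, screening
from .config import PipelineConfig
from .queuing import composite_scores

log = logging.getLogger("synergy")

__all__ = ["run_pipeline"]


def _stage_score(cfg: PipelineConfig, out: Path, summary: list[str]) -> None:
    path = cfg.scores_path or io.fixture_path("table1_scores.csv")
    table = io.read_score_table(path)
    result = composite_scores(table, weight_mode=cfg.weight_mode, tie_policy=cfg.tie_policy)
    io.write_csv(result.frame, out / "composite_scores.csv", index_label="molecule_id")
    top = result.cs.idxmax()
    summary.append(
        f"score: {len(result.frame)} molecules scored; top CS = "
        f"{result.cs.max():.3f} (molecule {top})"
    )


def _stage_screen(cfg: PipelineConfig, out: Path, summary: list[str]) -> None:
    preds = io.read_predictions(cfg.predictions_path or io.fixture_path("table3_predictions.csv"))
    profiles = io.read_env_profiles(cfg.env_path or io.fixture_path("table4_env.csv"))
    ledger = screening.screen_report(preds, profiles, template=cfg.template)
    io.write_csv(ledger, out / "screen_ledger.csv", index_label="molecule_id")
    n_fun = int(ledger["functional_pass"].sum())
    rec = ledger.index[ledger["recommended"].eq(True)].tolist()
    summary.append(
        f"screen: {n_fun} derivatives pass the functional screen; "
        f"recommended: {', '.join(rec) if rec else 'none'}"
    )


def _stage_doe(cfg: PipelineConfig, out: Path, summary: list[str]) -> None:
    responses = io.read_responses(cfg.responses_path or io.fixture_path("table6_responses.csv"))
    evaluation = doe.scheme_improvements(responses)
    io.write_csv(evaluation.frame, out / "scheme_evaluation.csv", index_label="run")
    summary.append(
        f"doe: synergy runs {evaluation.synergy_runs}; "
        f"best scheme = {evaluation.best_scheme}"
    )


def _stage_bonds(cfg: PipelineConfig, out: Path, summary: list[str]) -> None:
    table = io.read_interactions(
        cfg.interactions_path or io.fixture_path("table7_interactions.csv")
    )
    hydro = frozenset(cfg.hydrophobic_set)
    rows = []
    for (ligand, receptor), sub in table.groupby(["ligand", "receptor"]):
        st = binding.bond_stats(sub, hydro)
        rows.append(
            {
                "ligand": ligand,
                "receptor": receptor,
                "contacts": st.contact_count,
                "mean_distance_A": st.mean_distance,
                "halogen_bonds": st.halogen_bond_count,
                "hydrophobic_fraction": st.hydrophobic_fraction,
                "residues": st.residue_count,
            }
        )
    stats = pd.DataFrame(rows).set_index(["ligand", "receptor"])
    io.write_csv(stats, out / "bond_stats.csv")
    summary.append(f"bonds: {len(stats)} ligand/receptor tables summarized")


_STAGE_FNS = {
    "score": _stage_score,
    "screen": _stage_screen,
    "doe": _stage_doe,
    "bonds": _stage_bonds,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; write reports + summary.

    Returns {'out_dir': ..., 'summary': [...]}. A stage failure aborts with
    the stage name attached to the exception.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: list[str] = []
    for stage in cfg.stages:
        fn = _STAGE_FNS.get(stage)
        if fn is None:
            raise ValueError(f"stage {stage!r} has no batch runner (use the CLI subcommand)")
        log.info("[%s] running", stage)
        try:
            fn(cfg, out, summary)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    cfg.to_yaml(out / "config.resolved.yaml")
    return {"out_dir": str(out), "summary": summary}
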