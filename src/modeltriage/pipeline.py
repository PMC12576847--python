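"""End-to-end triage: cluster -> shortlist -> picker -> head-to-head selection.

The refinement step itself (a web service in the original workflow) is
replaced by a file-based contract: the pipeline consumes a per-candidate
metrics table produced by any refinement engine, joins it to the cluster
representatives by model id, and applies the picker and selection rules.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path

from .cluster import adaptive_cluster, load_ensemble
from .errors import NoAcceptableModelError, TriageError, InputError
from .triage import (
    RefinementMetrics,
    SelectionDecision,
    pick_winner,
    read_metrics_table,
    select_input_model,
)

__all__ = ["PipelineConfig", "run_reconstruction_triage", "report_to_json"]


@dataclass
class PipelineConfig:
    """All tunable knobs of the triage pipeline, with study defaults.

    Clustering aims for more than ``target_clusters`` clusters starting at a
    1 Angstrom CA-RMSD threshold; the best ``top_n_by_score`` cluster
    representatives are refined externally; the picker inspects the
    ``top_n_by_rfree`` lowest-Rfree refined candidates; the head-to-head
    rule needs a ``bayes_threshold`` free log-likelihood margin (6.7 =
    decisive Bayes factor) plus one sigma(Rfree).
    """

    target_clusters: int = 100
    start_threshold: float = 1.0
    shrink_factor: float = 0.8
    floor: float = 0.05
    top_n_by_score: int = 100
    top_n_by_rfree: int = 10
    max_rmsz: float = 1.0
    overfit_ratio_ceiling: float = 1.30
    overfit_gap_ceiling: float = 0.06
    bayes_threshold: float = 6.7
    rmsd_mode: str = "fixed_frame"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_clusters",
            "start_threshold",
            "shrink_factor",
            "floor",
            "top_n_by_score",
            "top_n_by_rfree",
            "max_rmsz",
            "overfit_ratio_ceiling",
            "overfit_gap_ceiling",
            "bayes_threshold",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"config {name} must be positive")


@contextmanager
def _stage(name: str):
    try:
        yield
    except TriageError as exc:
        exc.args = (f"[stage: {name}] {exc}",)
        raise


def run_reconstruction_triage(
    ensemble_dir: str | Path,
    scores: str | Path,
    metrics: str | Path,
    original_metrics: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[SelectionDecision, dict]:
    """Run the full triage and return (final decision, run report).

    Stages: adaptive leader clustering of the scored ensemble; shortlist of
    the top-scoring representatives; join with the refined-candidate metrics
    table; picker (geometry/overfitting filters + lowest Rfree); head-to-head
    selection against the original deposited model. If the picker rejects
    every candidate the decision falls back to the original model.

    The run report is a plain dict with per-stage counts; serialized with
    sorted keys it is byte-identical across repeated runs on the same inputs.
    """
    cfg = config or PipelineConfig()
    report: dict = {"config": asdict(cfg), "stages": {}}

    with _stage("load_ensemble"):
        solutions = load_ensemble(ensemble_dir, scores)
    report["stages"]["load_ensemble"] = {"n_solutions": len(solutions)}

    with _stage("cluster"):
        clusters = adaptive_cluster(
            solutions,
            target_clusters=cfg.target_clusters,
            start_threshold=cfg.start_threshold,
            shrink_factor=cfg.shrink_factor,
            floor=cfg.floor,
            mode=cfg.rmsd_mode,
        )
    report["stages"]["cluster"] = {
        "n_clusters": clusters.n_clusters,
        "threshold_used": clusters.threshold_used,
        "degenerate": clusters.degenerate,
        "n_members_assigned": clusters.n_solutions - clusters.n_clusters,
    }

    shortlist = clusters.representatives[: cfg.top_n_by_score]
    report["stages"]["shortlist"] = {"n_representatives_considered": len(shortlist)}

    with _stage("join_metrics"):
        table = read_metrics_table(metrics)
        by_id = {m.model_id: m for m in table}
        candidates: list[RefinementMetrics] = []
        missing: list[str] = []
        for rep in shortlist:
            m = by_id.get(rep.solution_id)
            if m is None:
                missing.append(rep.solution_id)
            else:
                candidates.append(m)
    report["stages"]["join_metrics"] = {
        "n_with_metrics": len(candidates),
        "n_missing_metrics": len(missing),
        "missing_metrics": sorted(missing),
    }

    with _stage("read_original_metrics"):
        original_table = read_metrics_table(original_metrics)
        original = original_table[0]

    fallback = False
    with _stage("picker"):
        if not candidates:
            fallback = True
            picker_decision = None
        else:
            try:
                picker_decision = pick_winner(
                    candidates,
                    top_n_by_rfree=cfg.top_n_by_rfree,
                    max_rmsz=cfg.max_rmsz,
                    overfit_ratio_ceiling=cfg.overfit_ratio_ceiling,
                    overfit_gap_ceiling=cfg.overfit_gap_ceiling,
                )
            except NoAcceptableModelError:
                fallback = True
                picker_decision = None
    report["stages"]["picker"] = (
        picker_decision.to_dict()
        if picker_decision is not None
        else {"fallback": "no_acceptable_candidate"}
    )

    if fallback:
        decision = SelectionDecision(
            chosen=original.model_id,
            reasons=[{"rule": "fallback_no_acceptable_candidate"}],
            rejected=[(rep.solution_id, "picker") for rep in shortlist],
        )
        report["decision"] = decision.to_dict()
        return decision, report

    with _stage("select_input_model"):
        winner = by_id[picker_decision.chosen]
        decision = select_input_model(original, winner, bayes_threshold=cfg.bayes_threshold)
    report["stages"]["selection"] = decision.to_dict()
    report["decision"] = decision.to_dict()
    return decision, report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON form of a run report."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
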