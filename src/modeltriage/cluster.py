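"""Greedy, score-ordered leader clustering with an adaptive CA-RMSD threshold.

A reconstruction puzzle can attract on the order of 150 000 player
solutions. To reduce such an ensemble to roughly one hundred
representatives, solutions are scanned in descending score order; a
solution founds a new cluster iff it lies at least a threshold CA-RMSD
away from every existing representative, otherwise it joins its nearest
representative. Starting at 1 Angstrom, the threshold is shrunk
geometrically until more than the target number of clusters emerge (or a
floor is hit, which flags the result as degenerate).

Distances are evaluated against representatives only — O(n*k), never the
full n^2 matrix — so large ensembles remain feasible.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, PairingError
from .structio import CATrace, read_model, extract_ca_trace
from .superpose import kabsch_superpose

__all__ = [
    "SolutionRecord",
    "ClusterResult",
    "greedy_leader_cluster",
    "adaptive_cluster",
    "load_ensemble",
    "write_cluster_output",
]


@dataclass
class SolutionRecord:
    """One scored candidate model. Higher score is better."""

    solution_id: str
    score: float
    trace: CATrace
    path: str = ""


@dataclass
class ClusterResult:
    representatives: list[SolutionRecord]  # descending score
    assignment: dict[str, str]  # solution_id -> representative_id
    threshold_used: float
    degenerate: bool = False
    n_solutions: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, representative_id: str) -> list[str]:
        return [s for s, r in self.assignment.items() if r == representative_id]

    def to_dict(self) -> dict:
        return {
            "n_solutions": self.n_solutions,
            "n_clusters": self.n_clusters,
            "threshold_used": self.threshold_used,
            "degenerate": self.degenerate,
            "representatives": [
                {"solution_id": r.solution_id, "score": r.score} for r in self.representatives
            ],
            "assignment": dict(sorted(self.assignment.items())),
        }


def _coord_stack(solutions: list[SolutionRecord]) -> np.ndarray:
    """Stack all traces as (n, L, 3) in the residue-key order of the first.

    Every solution of one puzzle must share the residue key set; the first
    offending solution is named otherwise.
    """
    ref = solutions[0].trace
    ref_index = {key: i for i, key in enumerate(ref.keys)}
    n, length = len(solutions), len(ref)
    coords = np.empty((n, length, 3), dtype=np.float64)
    coords[0] = ref.coords
    for i, sol in enumerate(solutions[1:], start=1):
        trace = sol.trace
        if len(trace) != length or set(trace.keys) != set(ref.keys):
            raise PairingError(
                f"solution {sol.solution_id!r} does not share the ensemble residue keys "
                f"(reference: {solutions[0].solution_id!r})"
            )
        order = np.array([ref_index[key] for key in trace.keys], dtype=np.intp)
        coords[i, order] = trace.coords
    return coords


def greedy_leader_cluster(
    solutions: list[SolutionRecord],
    threshold: float,
    mode: str = "fixed_frame",
) -> ClusterResult:
    """Leader clustering at a fixed CA-RMSD threshold.

    Solutions are visited in descending score (ties broken by ascending
    solution id). A visited solution becomes a representative iff its
    CA-RMSD to every existing representative is >= threshold; otherwise it
    is assigned to the nearest representative existing at that moment.
    """
    if not solutions:
        raise InputError("cannot cluster an empty ensemble")
    if threshold <= 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    ids = [s.solution_id for s in solutions]
    if len(set(ids)) != len(ids):
        raise InputError("solution ids are not unique within the ensemble")

    order = sorted(range(len(solutions)), key=lambda i: (-solutions[i].score, ids[i]))
    coords = _coord_stack(solutions)
    length = coords.shape[1]

    rep_indices: list[int] = []
    assignment: dict[str, str] = {}
    for i in order:
        if not rep_indices:
            rep_indices.append(i)
            assignment[ids[i]] = ids[i]
            continue
        if mode == "fixed_frame":
            diff = coords[rep_indices] - coords[i]
            dists = np.sqrt(np.einsum("klj,klj->k", diff, diff) / length)
        else:
            dists = np.array(
                [kabsch_superpose(coords[r], coords[i]).rmsd for r in rep_indices]
            )
        if np.all(dists >= threshold):
            rep_indices.append(i)
            assignment[ids[i]] = ids[i]
        else:
            nearest = rep_indices[int(np.argmin(dists))]
            assignment[ids[i]] = ids[nearest]

    representatives = [solutions[i] for i in rep_indices]
    return ClusterResult(
        representatives=representatives,
        assignment=assignment,
        threshold_used=threshold,
        degenerate=False,
        n_solutions=len(solutions),
    )


def adaptive_cluster(
    solutions: list[SolutionRecord],
    target_clusters: int = 100,
    start_threshold: float = 1.0,
    shrink_factor: float = 0.8,
    floor: float = 0.05,
    mode: str = "fixed_frame",
) -> ClusterResult:
    """Shrink the leader threshold until more than ``target_clusters`` emerge.

    Clustering runs from scratch at each threshold, starting at
    ``start_threshold`` and multiplying by ``shrink_factor`` (clamped at
    ``floor``). The first result with strictly more than ``target_clusters``
    clusters is returned; if the floor is reached without exceeding the
    target, the floor-threshold result is returned with ``degenerate=True``.
    """
    if target_clusters < 1:
        raise InputError(f"target_clusters must be >= 1, got {target_clusters}")
    if not 0 < shrink_factor < 1:
        raise InputError(f"shrink_factor must be in (0, 1), got {shrink_factor}")
    if not 0 < floor <= start_threshold:
        raise InputError(
            f"need 0 < floor <= start_threshold, got floor={floor}, start={start_threshold}"
        )
    threshold = start_threshold
    result = greedy_leader_cluster(solutions, threshold, mode=mode)
    while result.n_clusters <= target_clusters and threshold > floor:
        threshold = max(threshold * shrink_factor, floor)
        result = greedy_leader_cluster(solutions, threshold, mode=mode)
    if result.n_clusters <= target_clusters:
        result.degenerate = True
    return result


def load_ensemble(ensemble_dir: str | Path, scores_path: str | Path) -> list[SolutionRecord]:
    """Load a directory of PDB files plus a delimited scores table.

    The scores table needs columns ``solution_id`` and ``score``; each
    solution id must resolve to ``<ensemble_dir>/<solution_id>.pdb`` (or the
    id itself if it already carries an extension).
    """
    ensemble_dir = Path(ensemble_dir)
    if not ensemble_dir.is_dir():
        raise InputError(f"ensemble directory not found: {ensemble_dir}")
    try:
        table = pd.read_csv(scores_path, sep=None, engine="python")
    except FileNotFoundError as exc:
        raise InputError(f"scores file not found: {scores_path}") from exc
    missing = {"solution_id", "score"} - set(table.columns)
    if missing:
        raise InputError(f"scores table lacks required column(s): {sorted(missing)}")
    if table.empty:
        raise InputError(f"scores table is empty: {scores_path}")
    records: list[SolutionRecord] = []
    for row in table.itertuples(index=False):
        sid = str(row.solution_id)
        path = ensemble_dir / sid
        if not path.exists():
            path = ensemble_dir / f"{sid}.pdb"
        if not path.exists():
            raise InputError(f"no coordinate file for solution {sid!r} in {ensemble_dir}")
        score = float(row.score)
        if not np.isfinite(score):
            raise InputError(f"non-finite score for solution {sid!r}")
        trace = extract_ca_trace(read_model(path))
        records.append(SolutionRecord(solution_id=sid, score=score, trace=trace, path=str(path)))
    return records


def write_cluster_output(
    result: ClusterResult, out_dir: str | Path, copy_files: bool = True
) -> Path:
    """Write the cluster report as JSON; optionally copy representative files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "clusters.json"
    report_path.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")
    if copy_files:
        rep_dir = out_dir / "representatives"
        rep_dir.mkdir(exist_ok=True)
        for rep in result.representatives:
            if rep.path:
                shutil.copy(rep.path, rep_dir / Path(rep.path).name)
    return report_path
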