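"""Leader clustering and the adaptive threshold schedule.

Small ensembles are cross-checked against an independent brute-force
re-implementation that works from the full pairwise CA-RMSD matrix.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modeltriage import (
    InputError,
    PairingError,
    adaptive_cluster,
    greedy_leader_cluster,
    load_ensemble,
)
from modeltriage.superpose import paired_rmsd
from modeltriage.synthetic import EnsembleSpec, make_clustered_ensemble, make_ensemble_files

from conftest import make_solution


def brute_force_leader(solutions, threshold):
    """Oracle: leader clustering straight from the exhaustive distance matrix."""
    n = len(solutions)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = paired_rmsd(
                solutions[i].trace.coords, solutions[j].trace.coords
            )
    order = sorted(range(n), key=lambda i: (-solutions[i].score, solutions[i].solution_id))
    reps, assignment = [], {}
    for i in order:
        close = [r for r in reps if dist[r, i] < threshold]
        if not close:
            reps.append(i)
            assignment[i] = i
        else:
            assignment[i] = min(close, key=lambda r: (dist[r, i], reps.index(r)))
    return reps, assignment


def offset_solutions(offsets, scores=None):
    base = np.column_stack([np.zeros(10), np.zeros(10), 3.8 * np.arange(10)])
    sols = []
    for i, off in enumerate(offsets):
        score = scores[i] if scores is not None else 100.0 - i
        sols.append(make_solution(f"s{i:03d}", score, base + np.asarray(off, float)))
    return sols


def test_identical_solutions_form_one_cluster():
    sols = offset_solutions([(0, 0, 0)] * 10, scores=list(range(10)))
    result = greedy_leader_cluster(sols, threshold=1.0)
    assert result.n_clusters == 1
    assert result.representatives[0].solution_id == "s009"  # highest score
    assert set(result.assignment.values()) == {"s009"}


def test_well_separated_solutions_stay_apart():
    sols = offset_solutions([(2.0 * i, 0, 0) for i in range(5)])
    result = greedy_leader_cluster(sols, threshold=1.0)
    assert result.n_clusters == 5


def test_three_group_ensemble_matches_brute_force_oracle():
    spec = EnsembleSpec(
        n_residues=25, k_groups=3, n_per_group=8, within_spread_delta=0.2,
        between_separation_Delta=5.0, seed=42,
    )
    solutions, labels = make_clustered_ensemble(spec)
    result = greedy_leader_cluster(solutions, threshold=1.0)
    assert result.n_clusters == 3
    # each representative is its group's top scorer
    by_id = {s.solution_id: (s, g) for s, g in zip(solutions, labels)}
    for rep in result.representatives:
        group = by_id[rep.solution_id][1]
        group_scores = [s.score for s, g in by_id.values() if g == group]
        assert rep.score == max(group_scores)
    reps, assignment = brute_force_leader(solutions, 1.0)
    assert [solutions[r].solution_id for r in reps] == [
        r.solution_id for r in result.representatives
    ]
    for i, sol in enumerate(solutions):
        assert result.assignment[sol.solution_id] == solutions[assignment[i]].solution_id


def test_representatives_pairwise_separated(rng):
    sols = offset_solutions([rng.uniform(-3, 3, size=3) for _ in range(40)])
    result = greedy_leader_cluster(sols, threshold=1.5)
    reps = result.representatives
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            assert paired_rmsd(reps[i].trace.coords, reps[j].trace.coords) >= 1.5


def test_member_scores_never_exceed_representative():
    sols = offset_solutions([(0.1 * i, 0, 0) for i in range(20)], scores=list(range(20)))
    result = greedy_leader_cluster(sols, threshold=1.0)
    by_id = {s.solution_id: s for s in sols}
    for sid, rid in result.assignment.items():
        assert by_id[sid].score <= by_id[rid].score


def test_unmatchable_trace_names_offender():
    sols = offset_solutions([(0, 0, 0), (1, 0, 0)])
    bad = make_solution("odd", 1.0, np.zeros((4, 3)))
    with pytest.raises(PairingError, match="odd"):
        greedy_leader_cluster(sols + [bad], threshold=1.0)


def test_adaptive_returns_start_threshold_when_target_exceeded():
    sols = offset_solutions([(2.0 * i, 0, 0) for i in range(120)])
    result = adaptive_cluster(sols, target_clusters=100, start_threshold=1.0)
    assert result.n_clusters == 120
    assert result.threshold_used == 1.0
    assert not result.degenerate


def test_adaptive_identical_solutions_hit_floor_degenerate():
    sols = offset_solutions([(0, 0, 0)] * 150, scores=list(range(150)))
    result = adaptive_cluster(sols, target_clusters=100)
    assert result.n_clusters == 1
    assert result.threshold_used == pytest.approx(0.05)
    assert result.degenerate


def test_adaptive_shrinks_once_to_exceed_target():
    """50 clusters at 1.0 A, 130 at 0.8 A -> one shrink step."""
    side = 0.85  # equilateral triangle side: below 1.0, at/above 0.8
    tri = [(0.0, 0.0), (side, 0.0), (side / 2, side * np.sqrt(3) / 2)]
    offsets = []
    for g in range(50):
        n_sub = 3 if g < 30 else 2  # 30*3 + 20*2 = 130 sub-centroids
        for s in range(n_sub):
            offsets.append((5.0 * g, tri[s][0], tri[s][1]))
    sols = offset_solutions(offsets)
    assert greedy_leader_cluster(sols, 1.0).n_clusters == 50
    result = adaptive_cluster(sols, target_clusters=100, start_threshold=1.0, shrink_factor=0.8)
    assert result.threshold_used == pytest.approx(0.8)
    assert result.n_clusters == 130


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), t1=st.floats(0.05, 1.0), t2=st.floats(1.0, 3.0))
def test_cluster_count_non_increasing_in_threshold(seed, t1, t2):
    """Empirical monotonicity on planted-cluster ensembles (see the methods
    note: not a theorem for adversarial clouds)."""
    spec = EnsembleSpec(
        n_residues=20, k_groups=2 + seed % 4, n_per_group=6,
        within_spread_delta=0.2, between_separation_Delta=5.0, seed=seed,
    )
    records, _ = make_clustered_ensemble(spec)
    assert (
        greedy_leader_cluster(records, t1).n_clusters
        >= greedy_leader_cluster(records, t2).n_clusters
    )


def test_cluster_input_validation():
    with pytest.raises(InputError):
        greedy_leader_cluster([], 1.0)
    sols = offset_solutions([(0, 0, 0)])
    with pytest.raises(InputError):
        greedy_leader_cluster(sols, -1.0)
    with pytest.raises(InputError):
        adaptive_cluster(sols, shrink_factor=1.5)


def test_load_ensemble_roundtrip_and_errors(tmp_path):
    spec = EnsembleSpec(n_residues=12, k_groups=2, n_per_group=3, seed=5)
    ensemble_dir, scores_path, _ = make_ensemble_files(spec, tmp_path / "ens")
    loaded = load_ensemble(ensemble_dir, scores_path)
    assert len(loaded) == 6
    assert all(len(sol.trace) == 12 for sol in loaded)
    with pytest.raises(InputError):
        load_ensemble(tmp_path / "missing", scores_path)
    bad_scores = tmp_path / "bad.csv"
    bad_scores.write_text("solution_id\nx\n")
    with pytest.raises(InputError, match="score"):
        load_ensemble(ensemble_dir, bad_scores)
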