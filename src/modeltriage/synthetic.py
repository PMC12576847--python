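"""Synthetic study inputs: scored CA ensembles with planted cluster
structure, and paired refinement-metric tables with planted improvement,
significance and selection structure.

The ensemble generator emulates what a reconstruction puzzle produces: many
scored single-conformer models of one protein sharing a crystal frame. The
base geometry is an ideal helix-like curve (3.8 Angstrom consecutive-CA
spacing), not a real protein; the CA-RMSD machinery is indifferent to
realism. Group centroids are rigid translations of the base, so the planted
between-group fixed-frame CA-RMSD is exact; members add isotropic Gaussian
noise calibrated via E[RMSD^2] = 3*sigma^2 per atom.

The metric-table generator stands in for a per-entry refinement statistics
workbook: each entry pairs an original-input run with a challenger-input
run, and the joint structure (which entries improve a designated metric,
which show significant Rfree changes, which are decisively better as
originals) is planted exactly so the tally and selection machinery can be
tested against known counts.

All generators are pure functions of (spec, seed); no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .structio import Atom, CATrace, Model, Residue, ResidueKey, write_model
from .cluster import SolutionRecord
from .report import PairedEntry
from .triage import RefinementMetrics

__all__ = [
    "EnsembleSpec",
    "MetricTableSpec",
    "make_clustered_ensemble",
    "write_ensemble",
    "make_ensemble_files",
    "make_paired_table",
    "synth_metrics_table",
]


@dataclass
class EnsembleSpec:
    """Planted-cluster ensemble: k groups of noisy copies of a base trace.

    ``within_spread_delta`` is the expected fixed-frame CA-RMSD of a member
    to its group centroid; ``between_separation_Delta`` is the exact
    centroid-to-centroid CA-RMSD of adjacent groups. Recovery by leader
    clustering at threshold t is guaranteed when Delta > 2*delta + t.
    """

    n_residues: int = 60
    k_groups: int = 5
    n_per_group: int = 20
    within_spread_delta: float = 0.2
    between_separation_Delta: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_groups < 1:
            raise InputError(f"k_groups must be >= 1, got {self.k_groups}")
        if self.n_per_group < 1 or self.n_residues < 3:
            raise InputError("need n_per_group >= 1 and n_residues >= 3")
        if self.within_spread_delta < 0:
            raise InputError("within_spread_delta must be >= 0")
        if self.between_separation_Delta <= 2 * self.within_spread_delta:
            raise InputError(
                "between_separation_Delta must exceed 2 * within_spread_delta "
                "for well-separated groups"
            )


def _base_trace(n_residues: int) -> np.ndarray:
    """Ideal alpha-helical curve: 2.3 A radius, 1.5 A rise, 100 deg turn.

    Consecutive CA atoms come out ~3.8 A apart, as in real protein chains.
    """
    i = np.arange(n_residues, dtype=np.float64)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def make_clustered_ensemble(spec: EnsembleSpec) -> tuple[list[SolutionRecord], list[int]]:
    """Generate the ensemble and the true group label of each solution.

    Group g's centroid is the base trace translated by g * Delta along x, so
    centroid-centroid fixed-frame RMSD is exactly Delta * |g1 - g2|. Scores
    are drawn uniformly; each group's top scorer is unambiguous.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_trace(spec.n_residues)
    keys = [ResidueKey("A", i + 1) for i in range(spec.n_residues)]
    sigma = spec.within_spread_delta / math.sqrt(3.0)

    records: list[SolutionRecord] = []
    labels: list[int] = []
    n_total = spec.k_groups * spec.n_per_group
    scores = rng.uniform(6000.0, 10000.0, size=n_total)
    # continuous draws collide with probability zero, but be explicit
    assert len(np.unique(scores)) == n_total, "score tie in synthetic ensemble"
    idx = 0
    for g in range(spec.k_groups):
        centroid = base + np.array([g * spec.between_separation_Delta, 0.0, 0.0])
        for j in range(spec.n_per_group):
            coords = centroid
            if sigma > 0:
                coords = centroid + rng.normal(0.0, sigma, size=centroid.shape)
            records.append(
                SolutionRecord(
                    solution_id=f"g{g:02d}s{j:03d}",
                    score=float(scores[idx]),
                    trace=CATrace(keys=list(keys), coords=coords),
                )
            )
            labels.append(g)
            idx += 1
    return records, labels


def _trace_to_model(solution_id: str, trace: CATrace) -> Model:
    residues = []
    for key, xyz in zip(trace.keys, trace.coords):
        atom = Atom(name="CA", element="C", pos=(float(xyz[0]), float(xyz[1]), float(xyz[2])))
        residues.append(Residue(key=key, name="ALA", atoms=[atom]))
    return Model(residues=residues, source=solution_id)


def write_ensemble(records: list[SolutionRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write one PDB per solution plus a scores.csv; returns (dir, scores)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        path = out_dir / f"{rec.solution_id}.pdb"
        write_model(_trace_to_model(rec.solution_id, rec.trace), path)
        rec.path = str(path)
    scores_path = out_dir / "scores.csv"
    pd.DataFrame(
        {"solution_id": [r.solution_id for r in records], "score": [r.score for r in records]}
    ).to_csv(scores_path, index=False)
    return out_dir, scores_path


def make_ensemble_files(spec: EnsembleSpec, out_dir: str | Path):
    """Convenience: generate and write an ensemble; returns (dir, scores, labels)."""
    records, labels = make_clustered_ensemble(spec)
    ensemble_dir, scores_path = write_ensemble(records, out_dir)
    return ensemble_dir, scores_path, labels


@dataclass
class MetricTableSpec:
    """Planted joint structure for a paired refinement-metric table.

    On the designated metric, exactly ``n_improved`` entries improve and
    ``n_deteriorated`` deteriorate (the rest tie). ``n_rfree_deteriorated``
    entries have a positive Rfree change; of these, ``n_decisive_original``
    are decisively better as originals (free log-likelihood margin beyond
    the Bayes threshold AND Rfree margin beyond sigma(Rfree)) and
    ``n_significant_deteriorated`` exceed sigma(Rfree) without the
    likelihood margin. ``n_significant_improved`` improvements exceed
    sigma(Rfree); all remaining Rfree changes stay below it.

    ``decisive_overlap`` fixes how the decisive entries intersect the
    designated-metric categories as (improved, deteriorated, tied) counts;
    None distributes them by permutation.
    """

    n_entries: int = 58
    metric: str = "molprobity_score"
    n_improved: int = 43
    n_deteriorated: int = 13
    n_rfree_deteriorated: int = 29
    n_significant_improved: int = 4
    n_significant_deteriorated: int = 4
    n_decisive_original: int = 0
    decisive_overlap: tuple[int, int, int] | None = None
    bayes_threshold: float = 6.7
    r_free_value: float | tuple[float, float] = (0.18, 0.32)
    n_test_range: tuple[int, int] = (500, 20000)
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_entries
        if n < 1:
            raise InputError("n_entries must be >= 1")
        if self.n_improved + self.n_deteriorated > n:
            raise InputError("metric improvement/deterioration counts exceed n_entries")
        if self.n_decisive_original + self.n_significant_deteriorated > self.n_rfree_deteriorated:
            raise InputError(
                "decisive + significantly deteriorated entries exceed n_rfree_deteriorated"
            )
        if self.n_rfree_deteriorated > n:
            raise InputError("n_rfree_deteriorated exceeds n_entries")
        if self.n_significant_improved > n - self.n_rfree_deteriorated:
            raise InputError("n_significant_improved exceeds the improving entries")
        if self.decisive_overlap is not None:
            imp, det, tie = self.decisive_overlap
            if imp + det + tie != self.n_decisive_original:
                raise InputError("decisive_overlap must sum to n_decisive_original")
            n_tied = n - self.n_improved - self.n_deteriorated
            if imp > self.n_improved or det > self.n_deteriorated or tie > n_tied:
                raise InputError("decisive_overlap exceeds a metric category size")


def make_paired_table(spec: MetricTableSpec) -> list[PairedEntry]:
    """Generate the paired table with the planted joint structure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_entries

    # --- Rfree-side categories -------------------------------------------
    perm = rng.permutation(n)
    n_dec, n_sdet = spec.n_decisive_original, spec.n_significant_deteriorated
    n_det_total, n_simp = spec.n_rfree_deteriorated, spec.n_significant_improved
    decisive = set(perm[:n_dec])
    sig_det = set(perm[n_dec : n_dec + n_sdet])
    small_det = set(perm[n_dec + n_sdet : n_det_total])
    sig_imp = set(perm[n_det_total : n_det_total + n_simp])
    # remainder: small (non-significant) improvements

    # --- designated-metric categories, honouring the decisive overlap ----
    if spec.decisive_overlap is None:
        mperm = list(rng.permutation(n))
        metric_improved = set(mperm[: spec.n_improved])
        metric_det = set(mperm[spec.n_improved : spec.n_improved + spec.n_deteriorated])
    else:
        d_imp, d_det, _d_tie = spec.decisive_overlap
        dec_list = list(rng.permutation(sorted(decisive)))
        rest_list = list(rng.permutation(sorted(set(range(n)) - decisive)))
        metric_improved = set(dec_list[:d_imp]) | set(rest_list[: spec.n_improved - d_imp])
        metric_det = set(dec_list[d_imp : d_imp + d_det]) | set(
            rest_list[spec.n_improved - d_imp : spec.n_improved - d_imp + spec.n_deteriorated - d_det]
        )

    entries: list[PairedEntry] = []
    for i in range(n):
        eid = f"ent{i:03d}"
        if isinstance(spec.r_free_value, tuple):
            rfree_a = float(rng.uniform(*spec.r_free_value))
        else:
            rfree_a = float(spec.r_free_value)
        lo, hi = spec.n_test_range
        n_test = int(rng.integers(lo, hi + 1))
        sigma = rfree_a / math.sqrt(n_test)

        if i in decisive:
            delta_rfree = (1.5 + rng.uniform(0.0, 1.0)) * sigma
            delta_ll = spec.bayes_threshold + rng.uniform(0.5, 5.0)  # original better
        elif i in sig_det:
            delta_rfree = (2.0 + rng.uniform(0.0, 1.0)) * sigma
            delta_ll = rng.uniform(-5.0, 5.0)
        elif i in small_det:
            delta_rfree = rng.uniform(0.2, 0.8) * sigma
            delta_ll = rng.uniform(-5.0, 5.0)
        elif i in sig_imp:
            delta_rfree = -(2.0 + rng.uniform(0.0, 1.0)) * sigma
            delta_ll = rng.uniform(-5.0, 5.0)
        else:
            delta_rfree = -rng.uniform(0.2, 0.8) * sigma
            delta_ll = rng.uniform(-5.0, 5.0)
        rfree_b = rfree_a + delta_rfree

        free_ll_b = float(-rng.uniform(1e4, 5e4))
        free_ll_a = free_ll_b + delta_ll

        mp_a = float(rng.uniform(1.5, 4.5))
        if i in metric_improved:
            mp_b = mp_a - float(rng.uniform(0.2, 1.2))
        elif i in metric_det:
            mp_b = mp_a + float(rng.uniform(0.1, 0.8))
        else:
            mp_b = mp_a

        clash_a = float(rng.uniform(5.0, 80.0))
        rama_a = float(rng.uniform(-6.0, -1.0))
        common = dict(
            n_test=n_test,
            bond_rmsz=float(rng.uniform(0.2, 0.9)),
            angle_rmsz=float(rng.uniform(0.2, 0.9)),
        )
        metrics_a = RefinementMetrics(
            model_id=f"{eid}:a",
            r_free=rfree_a,
            r_work=rfree_a - float(rng.uniform(0.02, 0.05)),
            free_ll=free_ll_a,
            molprobity_score=mp_a,
            clashscore=clash_a,
            rama_z=rama_a,
            rotamer_z=float(rng.uniform(-5.0, -0.5)),
            hbond_fraction=float(rng.uniform(0.5, 0.85)),
            packing_z=float(rng.uniform(-4.0, -0.5)),
            **common,
        )
        metrics_b = RefinementMetrics(
            model_id=f"{eid}:b",
            r_free=rfree_b,
            r_work=rfree_b - float(rng.uniform(0.02, 0.05)),
            free_ll=free_ll_b,
            molprobity_score=mp_b,
            clashscore=clash_a * float(rng.uniform(0.3, 1.1)),
            rama_z=rama_a + float(rng.uniform(-0.5, 2.0)),
            rotamer_z=float(rng.uniform(-5.0, 0.5)),
            hbond_fraction=float(rng.uniform(0.5, 0.9)),
            packing_z=float(rng.uniform(-4.0, 0.0)),
            n_test=common["n_test"],
            bond_rmsz=float(rng.uniform(0.2, 0.9)),
            angle_rmsz=float(rng.uniform(0.2, 0.9)),
        )
        entries.append(PairedEntry(entry_id=eid, metrics_a=metrics_a, metrics_b=metrics_b))
    return entries


def synth_metrics_table(
    n_entries: int,
    improvement_fraction: float,
    sigma_spec: tuple[float | tuple[float, float], tuple[int, int]] | None = None,
    seed: int = 0,
    metric: str = "molprobity_score",
) -> list[PairedEntry]:
    """Paired table where round(n * improvement_fraction) entries improve
    the designated metric and the rest deteriorate; Rfree/n_test/free_ll are
    mutually consistent so sigma(Rfree) is computable on every row.
    """
    if not 0.0 <= improvement_fraction <= 1.0:
        raise InputError(f"improvement_fraction must be in [0, 1], got {improvement_fraction}")
    n_improved = round(n_entries * improvement_fraction)
    kwargs: dict = {}
    if sigma_spec is not None:
        kwargs["r_free_value"] = sigma_spec[0]
        kwargs["n_test_range"] = sigma_spec[1]
    spec = MetricTableSpec(
        n_entries=n_entries,
        metric=metric,
        n_improved=n_improved,
        n_deteriorated=n_entries - n_improved,
        n_rfree_deteriorated=n_entries // 2,
        n_significant_improved=0,
        n_significant_deteriorated=0,
        n_decisive_original=0,
        seed=seed,
        **kwargs,
    )
    return make_paired_table(spec)
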