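"""Picker and selection rules applied to refinement/validation metrics.

Three layers of decision making operate on externally computed refinement
statistics (nothing is ever recomputed from coordinates here):

* ``filter_candidates`` — reject refined candidates with unusual covalent
  geometry (bond/angle r.m.s.Z above 1.0) or clear signs of overfitting
  (Rfree/R ratio or Rfree-R gap above configurable ceilings).
* ``pick_winner`` — among the lowest-Rfree candidates, the surviving model
  with minimal Rfree wins.
* ``select_input_model`` — head-to-head rule between an original deposited
  model and a challenger: keep the original only if its free log-likelihood
  is better by a decisive Bayes factor (6.7 log-likelihood points) AND its
  Rfree is lower by at least one estimated standard deviation
  sigma(Rfree) = Rfree / sqrt(n_test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .errors import IncompleteMetricsError, InputError, NoAcceptableModelError

__all__ = [
    "RefinementMetrics",
    "SelectionDecision",
    "sigma_rfree",
    "filter_candidates",
    "pick_winner",
    "select_input_model",
    "significant_rfree_change",
    "read_metrics_table",
    "write_metrics_table",
    "METRIC_COLUMNS",
]

# canonical column order for delimited metric tables
METRIC_COLUMNS = (
    "model_id",
    "r_work",
    "r_free",
    "n_test",
    "free_ll",
    "bond_rmsz",
    "angle_rmsz",
    "molprobity_score",
    "clashscore",
    "rama_z",
    "rotamer_z",
    "hbond_fraction",
    "packing_z",
)


@dataclass
class RefinementMetrics:
    """Per-candidate refinement and validation numbers (inputs, not computed).

    ``r_work``/``r_free`` are fractions in (0, 1); ``n_test`` is the test-set
    reflection count; ``free_ll`` is the free log-likelihood (larger is
    better). The remaining validation fields are optional.
    """

    model_id: str
    r_work: float | None = None
    r_free: float | None = None
    n_test: int | None = None
    free_ll: float | None = None
    bond_rmsz: float | None = None
    angle_rmsz: float | None = None
    molprobity_score: float | None = None
    clashscore: float | None = None
    rama_z: float | None = None
    rotamer_z: float | None = None
    hbond_fraction: float | None = None
    packing_z: float | None = None

    def __post_init__(self) -> None:
        for name in ("r_work", "r_free"):
            value = getattr(self, name)
            if value is not None and not 0.0 < value < 1.0:
                raise InputError(f"{self.model_id}: {name}={value} outside (0, 1)")
        if self.n_test is not None:
            self.n_test = int(self.n_test)
            if self.n_test < 1:
                raise InputError(f"{self.model_id}: n_test must be >= 1, got {self.n_test}")
        for name in ("bond_rmsz", "angle_rmsz"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InputError(f"{self.model_id}: {name} must be >= 0, got {value}")

    def get(self, metric: str) -> float | None:
        if metric not in {f.name for f in fields(self)}:
            raise InputError(f"unknown metric field: {metric!r}")
        return getattr(self, metric)


@dataclass
class SelectionDecision:
    """A chosen model plus machine-readable reasons for the choice."""

    chosen: str
    reasons: list[dict] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen,
            "reasons": self.reasons,
            "rejected": [list(item) for item in self.rejected],
        }


def sigma_rfree(r_free: float, n_test: int) -> float:
    """Estimated standard deviation of Rfree: r_free / sqrt(n_test)."""
    if not 0.0 < r_free < 1.0:
        raise InputError(f"r_free={r_free} outside (0, 1)")
    if n_test is None or int(n_test) < 1:
        raise InputError(f"n_test must be >= 1, got {n_test}")
    return r_free / math.sqrt(int(n_test))


def filter_candidates(
    candidates: list[RefinementMetrics],
    max_rmsz: float = 1.0,
    overfit_ratio_ceiling: float = 1.30,
    overfit_gap_ceiling: float = 0.06,
) -> tuple[list[RefinementMetrics], list[tuple[str, str]]]:
    """Partition candidates into survivors and rejections.

    A candidate is rejected iff bond or angle r.m.s.Z exceeds ``max_rmsz``
    (strictly), or Rfree/Rwork exceeds ``overfit_ratio_ceiling``, or
    Rfree - Rwork exceeds ``overfit_gap_ceiling``. Candidates missing any of
    the required fields are rejected with rule ``incomplete_metrics`` rather
    than aborting the run.
    """
    if not candidates:
        raise InputError("no candidates to filter")
    survivors: list[RefinementMetrics] = []
    rejected: list[tuple[str, str]] = []
    for cand in candidates:
        required = (cand.r_work, cand.r_free, cand.bond_rmsz, cand.angle_rmsz)
        if any(v is None for v in required):
            rejected.append((cand.model_id, "incomplete_metrics"))
            continue
        if cand.bond_rmsz > max_rmsz or cand.angle_rmsz > max_rmsz:
            rejected.append((cand.model_id, "rmsz"))
            continue
        if (
            cand.r_free / cand.r_work > overfit_ratio_ceiling
            or cand.r_free - cand.r_work > overfit_gap_ceiling
        ):
            rejected.append((cand.model_id, "overfit"))
            continue
        survivors.append(cand)
    return survivors, rejected


def pick_winner(
    candidates: list[RefinementMetrics],
    top_n_by_rfree: int = 10,
    max_rmsz: float = 1.0,
    overfit_ratio_ceiling: float = 1.30,
    overfit_gap_ceiling: float = 0.06,
) -> SelectionDecision:
    """Pick the winning refined model: lowest Rfree among filtered top-n.

    Candidates are first restricted to the ``top_n_by_rfree`` lowest-Rfree
    entries (missing Rfree sorts last), then passed through
    :func:`filter_candidates`; the survivor with minimal Rfree wins. Ties
    break by lower Rwork, then by model id. If every candidate is rejected a
    :class:`NoAcceptableModelError` is raised so that the caller can fall
    back to the original deposited model.
    """
    if not candidates:
        raise InputError("no candidates to pick from")
    if top_n_by_rfree < 1:
        raise InputError(f"top_n_by_rfree must be >= 1, got {top_n_by_rfree}")

    def rfree_key(c: RefinementMetrics) -> tuple:
        return (c.r_free if c.r_free is not None else math.inf, c.model_id)

    shortlist = sorted(candidates, key=rfree_key)[:top_n_by_rfree]
    survivors, rejected = filter_candidates(
        shortlist,
        max_rmsz=max_rmsz,
        overfit_ratio_ceiling=overfit_ratio_ceiling,
        overfit_gap_ceiling=overfit_gap_ceiling,
    )
    if not survivors:
        raise NoAcceptableModelError(
            f"no acceptable model: all {len(shortlist)} shortlisted candidates rejected"
        )
    winner = min(
        survivors,
        key=lambda c: (c.r_free, c.r_work if c.r_work is not None else math.inf, c.model_id),
    )
    reasons = [
        {
            "rule": "lowest_rfree_survivor",
            "model_id": winner.model_id,
            "r_free": winner.r_free,
            "shortlist_size": len(shortlist),
            "n_rejected": len(rejected),
        }
    ]
    return SelectionDecision(chosen=winner.model_id, reasons=reasons, rejected=rejected)


def select_input_model(
    original: RefinementMetrics,
    challenger: RefinementMetrics,
    bayes_threshold: float = 6.7,
    sigma_reference: str = "original",
) -> SelectionDecision:
    """Head-to-head choice between the original model and a challenger.

    The challenger is selected unless BOTH hold:

    (i)  the original's free log-likelihood beats the challenger's by at
         least ``bayes_threshold`` points (a decisive Bayes factor), and
    (ii) the original's Rfree is lower by at least one sigma(Rfree),
         computed by default from the original's Rfree and test-set size
         (both refinements share one test set).
    """
    for m in (original, challenger):
        if m.free_ll is None or m.r_free is None:
            raise IncompleteMetricsError(f"{m.model_id}: free_ll and r_free are required")
    ref = original if sigma_reference == "original" else challenger
    if ref.n_test is None:
        raise IncompleteMetricsError(f"{ref.model_id}: n_test is required for sigma(Rfree)")

    delta_ll = original.free_ll - challenger.free_ll
    sigma = sigma_rfree(ref.r_free, ref.n_test)
    rfree_margin = challenger.r_free - original.r_free
    cond_bayes = delta_ll >= bayes_threshold
    cond_rfree = rfree_margin >= sigma
    chosen = original if (cond_bayes and cond_rfree) else challenger
    loser = challenger if chosen is original else original
    reasons = [
        {
            "rule": "decisive_bayes_factor",
            "delta_free_ll": delta_ll,
            "threshold": bayes_threshold,
            "met": cond_bayes,
        },
        {
            "rule": "rfree_margin",
            "rfree_margin": rfree_margin,
            "sigma_rfree": sigma,
            "sigma_reference": ref.model_id,
            "met": cond_rfree,
        },
        {
            "rule": "original_iff_both",
            "chosen": chosen.model_id,
        },
    ]
    return SelectionDecision(
        chosen=chosen.model_id,
        reasons=reasons,
        rejected=[(loser.model_id, "head_to_head")],
    )


def significant_rfree_change(a: RefinementMetrics, b: RefinementMetrics) -> bool:
    """True iff |a.r_free - b.r_free| exceeds sigma(Rfree) of reference a."""
    if a.r_free is None or b.r_free is None:
        raise IncompleteMetricsError("r_free required on both records")
    if a.n_test is None:
        raise IncompleteMetricsError(f"{a.model_id}: n_test is required")
    return abs(a.r_free - b.r_free) > sigma_rfree(a.r_free, a.n_test)


def read_metrics_table(path: str | Path) -> list[RefinementMetrics]:
    """Read a delimited metrics table (one row per model, canonical headers)."""
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError as exc:
        raise InputError(f"metrics table not found: {path}") from exc
    if "model_id" not in table.columns:
        raise InputError(f"metrics table {path} lacks a model_id column")
    known = [c for c in METRIC_COLUMNS if c in table.columns]
    records = []
    for _, row in table[known].iterrows():
        kwargs = {}
        for col in known:
            value = row[col]
            if col == "model_id":
                kwargs[col] = str(value)
            elif pd.isna(value):
                kwargs[col] = None
            else:
                kwargs[col] = float(value)
        records.append(RefinementMetrics(**kwargs))
    if not records:
        raise InputError(f"metrics table is empty: {path}")
    return records


def write_metrics_table(records: list[RefinementMetrics], path: str | Path) -> None:
    rows = [{col: getattr(r, col) for col in METRIC_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=list(METRIC_COLUMNS)).to_csv(path, index=False)
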