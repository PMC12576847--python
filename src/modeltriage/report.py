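"""Improvement/deterioration tallies over paired per-entry metric tables.

Each entry pairs two refinement runs of the same PDB entry — side "a" using
the original deposited model as input, side "b" using a challenger (e.g. a
crowd-sourced rebuild). For every metric the report counts how many entries
improved, deteriorated or tied, flags significant Rfree changes, and can
re-tally after applying the head-to-head selection rule (entries where the
original wins revert to side "a").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import InputError
from .triage import (
    METRIC_COLUMNS,
    RefinementMetrics,
    select_input_model,
    significant_rfree_change,
)

__all__ = [
    "PairedEntry",
    "TallyRow",
    "TallyReport",
    "LOWER_IS_BETTER",
    "HIGHER_IS_BETTER",
    "default_direction",
    "load_metrics_table",
    "write_paired_table",
    "tally_comparison",
    "tally_report",
    "significant_rfree_entries",
    "apply_selection",
    "selection_tally",
    "scatter_plot",
]

LOWER_IS_BETTER = frozenset(
    {"r_free", "r_work", "molprobity_score", "clashscore", "bond_rmsz", "angle_rmsz"}
)
HIGHER_IS_BETTER = frozenset(
    {"rama_z", "rotamer_z", "hbond_fraction", "packing_z", "free_ll"}
)


def default_direction(metric: str) -> str:
    if metric in LOWER_IS_BETTER:
        return "lower_is_better"
    if metric in HIGHER_IS_BETTER:
        return "higher_is_better"
    raise InputError(
        f"no default direction registered for metric {metric!r}; pass one explicitly"
    )


@dataclass
class PairedEntry:
    """One PDB entry with metrics from both refinement runs."""

    entry_id: str
    metrics_a: RefinementMetrics  # original-input run
    metrics_b: RefinementMetrics  # challenger-input run

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise InputError("entry_id must be non-empty")


@dataclass
class TallyRow:
    metric: str
    direction: str
    improved: int
    deteriorated: int
    tied: int
    excluded: list[str] = field(default_factory=list)  # entries missing the metric

    @property
    def total(self) -> int:
        return self.improved + self.deteriorated + self.tied

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "direction": self.direction,
            "improved": self.improved,
            "deteriorated": self.deteriorated,
            "tied": self.tied,
            "total": self.total,
            "excluded": list(self.excluded),
        }


@dataclass
class TallyReport:
    rows: list[TallyRow]
    significant_rfree: list[dict] = field(default_factory=list)
    n_entries: int = 0

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "metrics": {row.metric: row.to_dict() for row in self.rows},
            "significant_rfree": self.significant_rfree,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def load_metrics_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    suffix_a: str = "_a",
    suffix_b: str = "_b",
) -> list[PairedEntry]:
    """Read a paired delimited table into :class:`PairedEntry` records.

    Expects an ``entry_id`` column plus metric pairs named
    ``<metric><suffix_a>`` / ``<metric><suffix_b>`` (e.g. ``r_free_a``,
    ``r_free_b``). ``column_map`` renames arbitrary source headers to that
    convention first, so spreadsheet exports with free-form headers can be
    ingested unchanged.
    """
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError as exc:
        raise InputError(f"paired table not found: {path}") from exc
    if column_map:
        table = table.rename(columns=column_map)
    if "entry_id" not in table.columns:
        raise InputError(f"paired table {path} lacks an entry_id column (map it if renamed)")

    metric_fields = [c for c in METRIC_COLUMNS if c != "model_id"]
    paired = [
        m
        for m in metric_fields
        if f"{m}{suffix_a}" in table.columns and f"{m}{suffix_b}" in table.columns
    ]
    if not paired:
        raise InputError(
            f"paired table {path} has no recognized metric pair; expected columns like "
            f"r_free{suffix_a}/r_free{suffix_b}"
        )

    entries: list[PairedEntry] = []
    for _, row in table.iterrows():
        eid = str(row["entry_id"])
        kwargs_a: dict = {"model_id": f"{eid}:a"}
        kwargs_b: dict = {"model_id": f"{eid}:b"}
        for m in paired:
            va, vb = row[f"{m}{suffix_a}"], row[f"{m}{suffix_b}"]
            kwargs_a[m] = None if pd.isna(va) else float(va)
            kwargs_b[m] = None if pd.isna(vb) else float(vb)
        entries.append(
            PairedEntry(
                entry_id=eid,
                metrics_a=RefinementMetrics(**kwargs_a),
                metrics_b=RefinementMetrics(**kwargs_b),
            )
        )
    if not entries:
        raise InputError(f"paired table is empty: {path}")
    return entries


def write_paired_table(
    entries: list[PairedEntry],
    path: str | Path,
    suffix_a: str = "_a",
    suffix_b: str = "_b",
) -> None:
    metric_fields = [c for c in METRIC_COLUMNS if c != "model_id"]
    rows = []
    for e in entries:
        row: dict = {"entry_id": e.entry_id}
        for m in metric_fields:
            row[f"{m}{suffix_a}"] = getattr(e.metrics_a, m)
            row[f"{m}{suffix_b}"] = getattr(e.metrics_b, m)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def tally_comparison(
    entries: list[PairedEntry],
    metric: str,
    direction: str | None = None,
    tie_tol: float = 0.0,
) -> TallyRow:
    """Count improved/deteriorated/tied entries for one metric.

    Improvement means side "b" beats side "a" in the metric's direction;
    differences with absolute value <= ``tie_tol`` count as ties. Entries
    missing the metric on either side are excluded and listed, never
    silently dropped.
    """
    if direction is None:
        direction = default_direction(metric)
    if direction not in ("lower_is_better", "higher_is_better"):
        raise InputError(f"unknown direction: {direction!r}")
    if tie_tol < 0:
        raise InputError(f"tie_tol must be >= 0, got {tie_tol}")
    improved = deteriorated = tied = 0
    excluded: list[str] = []
    sign = -1.0 if direction == "lower_is_better" else 1.0
    for e in entries:
        va = e.metrics_a.get(metric)
        vb = e.metrics_b.get(metric)
        if va is None or vb is None:
            excluded.append(e.entry_id)
            continue
        delta = sign * (vb - va)  # positive = b better
        if abs(vb - va) <= tie_tol:
            tied += 1
        elif delta > 0:
            improved += 1
        else:
            deteriorated += 1
    return TallyRow(
        metric=metric,
        direction=direction,
        improved=improved,
        deteriorated=deteriorated,
        tied=tied,
        excluded=excluded,
    )


def significant_rfree_entries(entries: list[PairedEntry]) -> list[dict]:
    """Entries whose Rfree change exceeds sigma(Rfree), with direction."""
    out = []
    for e in entries:
        a, b = e.metrics_a, e.metrics_b
        if a.r_free is None or b.r_free is None or a.n_test is None:
            continue
        if significant_rfree_change(a, b):
            out.append(
                {
                    "entry_id": e.entry_id,
                    "direction": "improved" if b.r_free < a.r_free else "deteriorated",
                    "delta_rfree": b.r_free - a.r_free,
                }
            )
    return out


def tally_report(
    entries: list[PairedEntry],
    metrics: list[str] | None = None,
    tie_tol: float | dict[str, float] = 0.0,
) -> TallyReport:
    """Tally every requested metric and flag significant Rfree changes."""
    if metrics is None:
        metrics = [
            m
            for m in METRIC_COLUMNS
            if m != "model_id"
            and any(
                e.metrics_a.get(m) is not None and e.metrics_b.get(m) is not None
                for e in entries
            )
            and m in (LOWER_IS_BETTER | HIGHER_IS_BETTER)
        ]
    rows = []
    for m in metrics:
        tol = tie_tol.get(m, 0.0) if isinstance(tie_tol, dict) else tie_tol
        rows.append(tally_comparison(entries, m, tie_tol=tol))
    return TallyReport(
        rows=rows,
        significant_rfree=significant_rfree_entries(entries),
        n_entries=len(entries),
    )


def apply_selection(
    entries: list[PairedEntry], bayes_threshold: float = 6.7
) -> tuple[list[PairedEntry], list[str]]:
    """Replay the head-to-head rule on every entry.

    Returns the post-selection view — entries where the original wins have
    side "b" replaced by side "a", as the databank would then carry the
    original-input result — plus the ids of entries where the original won.
    """
    selected_original: list[str] = []
    out: list[PairedEntry] = []
    for e in entries:
        decision = select_input_model(
            e.metrics_a, e.metrics_b, bayes_threshold=bayes_threshold
        )
        if decision.chosen == e.metrics_a.model_id:
            selected_original.append(e.entry_id)
            out.append(replace(e, metrics_b=e.metrics_a))
        else:
            out.append(e)
    return out, selected_original


def selection_tally(
    entries: list[PairedEntry],
    metrics: list[str] | None = None,
    bayes_threshold: float = 6.7,
) -> dict:
    """Before/after-selection tallies plus the selection counts themselves."""
    before = tally_report(entries, metrics=metrics)
    after_entries, selected_original = apply_selection(
        entries, bayes_threshold=bayes_threshold
    )
    after = tally_report(after_entries, metrics=metrics)
    return {
        "n_entries": len(entries),
        "n_challenger_selected": len(entries) - len(selected_original),
        "n_original_selected": len(selected_original),
        "original_selected_entries": selected_original,
        "before_selection": before.to_dict(),
        "after_selection": after.to_dict(),
    }


def scatter_plot(entries: list[PairedEntry], metric: str, path: str | Path) -> None:
    """x = original-input run, y = challenger-input run, diagonal marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys = [], []
    for e in entries:
        va, vb = e.metrics_a.get(metric), e.metrics_b.get(metric)
        if va is not None and vb is not None:
            xs.append(va)
            ys.append(vb)
    if not xs:
        raise InputError(f"no paired values for metric {metric!r}")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xs, ys, s=12, alpha=0.7)
    lo = min(min(xs), min(ys))
    hi = max(max(xs), max(ys))
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8)
    ax.set_xlabel(f"{metric} (original input)")
    ax.set_ylabel(f"{metric} (challenger input)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
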