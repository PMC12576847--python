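# Methods

## Scope and data model

`modeltriage` operates downstream of model generation and refinement: it
consumes (a) ensembles of single-conformer protein coordinate files that
share one crystal frame, each with a scalar solution score (higher is
better), and (b) per-candidate refinement/validation statistics produced by
external engines (R factors, test-set size, free log-likelihood, bond/angle
r.m.s.Z, MolProbity score, clashscore, torsion-normality Z scores, H-bond
satisfaction, packing Z). It never refines, rebuilds, or recomputes a
validation metric from coordinates.

Residue identity is the triple (chain id, residue number, insertion code);
the residue *name* is deliberately excluded so that a register shift — the
same position modelled as a different residue type — still pairs between
models. Alternate locations are collapsed to the highest-occupancy conformer
(ties prefer altloc `A`, then first seen) so that CA-RMSD is well defined
for single-conformer comparison. Hydrogens are dropped. Waters and hetero
compounds without a Cα are excluded; hetero residues inside the chain that
do carry a Cα (e.g. selenomethionine) are kept, so the Cα trace is "every
residue possessing a CA atom, in file order".

## CA-RMSD

The distance between two models is the root-mean-square deviation over
paired Cα atoms. The **default is the fixed-frame form** on raw
coordinates, because all solutions derived from one crystallographic puzzle
live in the same crystal/map frame; superposing first would hide genuine
rigid-body displacement relative to the density. For ensembles from
heterogeneous frames a `superposed` mode applies the optimal least-squares
rigid superposition (Kabsch algorithm via the SVD of the 3×3
cross-covariance matrix, with the determinant correction for reflections)
and reports the minimized RMSD. Degenerate point sets (fewer than three
pairs, or an effectively collinear/coincident configuration, detected by
the second singular value falling below 10⁻⁹ of the first) raise an error
rather than returning an arbitrary rotation. The superposed RMSD is never
larger than the fixed-frame RMSD; both are symmetric, and the fixed-frame
form is a metric (triangle inequality); these invariants are property-tested.

## Leader clustering with an adaptive threshold

Solutions are visited in descending score, ties broken by ascending
solution id for determinism. A visited solution becomes a new cluster
representative iff its CA-RMSD to *every* existing representative is at
least the threshold; otherwise it is assigned to the nearest representative
existing at that moment (nearest-assignment is deterministic and
frame-independent; distance ties go to the earlier, higher-scoring
representative). Consequences: each representative is the top scorer of its
cluster, and representatives are pairwise at least the threshold apart.

The adaptive search starts at 1.0 Å and re-clusters from scratch at
geometrically shrinking thresholds (factor 0.8, clamped at a 0.05 Å floor)
until **strictly more than** the target number of clusters (default 100)
emerge. The geometric schedule reaches fine thresholds in few
re-clusterings; the floor prevents an infinite loop on ensembles of
duplicates, in which case the floor-threshold result is returned flagged
`degenerate`. The floor value itself is evaluated before degeneracy is
declared. Complexity is O(n·k·L) per pass (n solutions, k representatives,
L residues); the exhaustive n² distance matrix is used only as a test
oracle at small n.

Two usage notes. First, when the goal is to recover a small known number of
well-separated conformations (as in the parameter-recovery tests), the
target must be set *below* the expected group count — e.g. `target_clusters=1`
— so the loop accepts the 1 Å result; with the production default of 100 on
a toy ensemble the loop would correctly shrink to the floor hunting for
more than 100 clusters. Second, the cluster count is *empirically*
non-increasing in the threshold for clustered ensembles (verified over
hundreds of planted-structure ensembles), but this is not a theorem of
leader clustering: for adversarial clouds a point absorbed by a leader at a
larger threshold can leave a later point unshielded, creating an extra
leader (1-D counterexample: visit order 0, 1.0, 1.9 plus suitable tails).
The adaptive loop does not rely on strict monotonicity — it simply returns
the first result exceeding the target.

## Picker rules

Refined candidates are first restricted to the `top_n_by_rfree` (default
10) lowest-R_free entries, then rejected if

* bond or angle r.m.s.Z **> 1.0** (strict inequality; a value of exactly
  1.0 survives), or
* R_free/R_work > 1.30, or R_free − R_work > 0.06 ("clear signs of
  overfitting" made concrete as two transparent, overridable ceilings), or
* required fields are missing (`incomplete_metrics`) — a robustness choice:
  one malformed web-service result must not abort a 100-candidate run.

The surviving candidate with minimal R_free wins; ties break by lower
R_work, then model id. If every candidate is rejected, a distinct
`NoAcceptableModelError` signals the caller to fall back to the original
deposited model, which the pipeline does with an explicit
`fallback_no_acceptable_candidate` reason.

## Head-to-head selection and σR_free

With both the original model and the challenger refined against the same
data and test set, the challenger is selected **unless both** of the
following hold:

1. the original's free log-likelihood exceeds the challenger's by at least
   6.7 points — free log-likelihood differences act as log Bayes factors,
   and 6.7 corresponds to a "decisive" Bayes factor in the Kass–Raftery
   grading;
2. the original's R_free is lower by at least one estimated standard
   deviation of R_free, σR_free = R_free/√n_test.

σR_free is computed from the **original** model's R_free and test-set size:
both refinements share one test set and the original is the reference
hypothesis (`sigma_reference="challenger"` switches this). The conjunction
is deliberate: it accepts a sub-σ R_free deterioration in exchange for the
challenger's typically much better geometry. The rule is monotone — raising
the original's likelihood advantage can never flip a decision away from the
original, and lowering the challenger's R_free can never flip a decision
away from the challenger — and this is property-tested.

A change in R_free between two paired runs is called *significant* when it
exceeds σR_free of the reference run. This realizes the significance call
with the same in-package σR_free; the report layer keeps the rule pluggable
since stricter published criteria exist.

## Tally reporting

Paired tables (one row per PDB entry, side "a" = original-input run, side
"b" = challenger-input run) are ingested from delimited text with a
`column_map` for free-form headers; spreadsheet workbooks are converted to
CSV at the CLI layer. The direction registry treats R_free, MolProbity
score, clashscore and bond/angle r.m.s.Z as lower-is-better and the
normality Z scores, H-bond satisfaction and packing Z as higher-is-better.
Ties are exact by default (`tie_tol` configurable per metric); entries
missing a metric on either side are excluded *and listed*. Reversing the
direction exactly swaps improved and deteriorated counts.
`selection_tally` replays the head-to-head rule per entry and re-tallies
with original-won entries reverted to side "a" — i.e. they become exact
ties, modelling a databank that keeps the original-input result.

## Synthetic data

The ensemble generator plants k conformational groups: a base Cα trace (an
ideal helix-like curve — 2.3 Å radius, 1.5 Å rise, 100° turn, hence ~3.8 Å
consecutive-Cα spacing; deliberately not a real protein, so no download is
needed and the distance machinery is exercised without bias), group
centroids translated Δ apart (translation makes the planted centroid
distance exact in fixed-frame RMSD), and members perturbed by isotropic
per-atom Gaussian noise with σ = δ/√3 so the expected member-to-centroid
RMSD is δ (E[RMSD²] = 3σ² per atom). Defaults δ = 0.2 Å, Δ = 5 Å, 60
residues: a tight, well-separated regime in which leader clustering at 1 Å
must recover the groups exactly (guaranteed when Δ > 2δ + threshold).
Scores are continuous uniform draws, so each group's top scorer is almost
surely unique (asserted). Everything is a pure function of (spec, seed).

The metric-table generator plants a joint structure over 58-entry paired
tables: exact counts of designated-metric improvements/deteriorations,
R_free deteriorations, significant R_free changes (about 2σ in magnitude)
versus sub-σ changes (0.2–0.8σ), and "decisively better original" entries
(likelihood margin beyond 6.7 and R_free margin of 1.5–2.5σ), with a
controllable overlap between the decisive set and the metric categories.
What it does **not** emulate: correlations between metrics seen in real
re-refinement, resolution dependence, and — importantly — the run-to-run
variation of a full re-refinement pipeline with rebuilding. Because the
selection rule's condition (ii) forces every original-selected entry to be
a ≥ 1σ R_free deterioration, a clean replay turns all of them into ties; on
real data, re-running the downstream pipeline with the selected input still
moves the numbers slightly. Passing tests on these tables therefore
demonstrate the correctness of the counting and selection *rules*, not
distributional realism.

## Problem sizes and numerical choices

The test suite and the acceptance script run planted ensembles of 25–60
residues with 30–100 members and metric tables of 58 entries — sizes chosen
so the exhaustive pairwise-matrix and brute-force-rotation oracles remain
cheap while exercising every code path; the production code paths are the
same ones that scale to 10⁵-member ensembles (O(n·k) clustering). The
brute-force superposition oracle is a 24-start Nelder–Mead search over
rotation vectors, independent of the SVD solution, and agrees with it to
better than 10⁻⁶ Å on random ≤ 8-point sets. JSON reports are serialized
with sorted keys and no timestamps, so repeated runs on identical inputs
are byte-identical. All randomness flows through explicit
`numpy.random.default_rng(seed)` instances.

## Known limitations

* No symmetry expansion, no map or density handling, no all-atom RMSD, no
  sequence alignment — correspondence is by residue key only.
* The overfitting ceilings are a transparent stand-in for the richer
  R_free/R-gap expectation models used inside production re-refinement
  pipelines; tune them per project if needed.
* The significance rule equates "significant" with "> 1σR_free"; stricter
  multi-criteria definitions from the literature can be swapped in at the
  report layer.
* mmCIF input works through the same reader (format auto-detection), but
  output is PDB only.
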