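# Methods

## Problem

Deep-learning structure predictors now supply models for whole
proteomes, with a per-residue confidence (pLDDT, 0-100) as the only
built-in quality signal. For α-helical membrane proteins that signal is
not sufficient: a model can be locally confident yet place its
transmembrane (TM) helices in a geometry no lipid bilayer could
accommodate. `memqa` implements an orthogonal, topology-aware screen
plus a structural-comparison engine for checking predicted TM folds
against reference architectures.

## The hydrophobic-thickness statistic

A consensus topology predictor (CCTOP-style) annotates each TM helix
with its boundary positions and the membrane side of the flanking loops.
For a correctly built structure the helix endpoints cluster on the two
membrane surfaces. The statistic is

    t = || c(side1) - c(side2) ||

where `c(side)` is the unweighted centroid of the C-alpha coordinates of
the helix endpoints assigned to that side (each segment contributes its
start to the preceding loop's side and its end to the following loop's
side). A biological hydrophobic core spans roughly 15-35 Å, so `t`
outside the closed band [15, 35] Å flags the structure as `suspect`:
with that annotation, its helices cannot all span one membrane slab.

The flag alone cannot say whether the *model* or the *topology
annotation* is wrong. Cross-classifying with the predictor's
reliability score separates the cases: out-of-band thickness with
reliability ≥ 90 (default, configurable, always echoed in output) is
called `likely_af2_error`; with lower reliability the call is
`twilight`; in-band is `consistent`. The 90 cut is a pinned, visible
choice — the notion of "high" consensus reliability is not sharp, and
every output row records the threshold used.

Properties worth knowing:

* `t` is invariant under rigid motion of the structure (it only uses
  internal distances), verified to 1e-6 relative under random rigid
  transforms.
* With i.i.d. coordinate noise σ and n endpoints per side, the error of
  each centroid is σ/√n per axis, so recovery degrades gracefully (the
  tests bound the mean absolute error by 3σ/√n).
* Blind spot: each helix contributes one endpoint to *each* side, so
  rigidly z-shifting a subset of helices moves both centroids equally
  and leaves `t` unchanged. A sheared bundle passes the thickness screen
  and is only caught by structural comparison. Inverted helices and
  collapsed structures, by contrast, strictly shrink `t`.
* All annotated spanning helices enter the statistic; helices are not
  weighted or filtered by confidence. Per-region mean pLDDT is
  residue-weighted (the unweighted arithmetic mean over residues that
  carry a confidence value).

Experimental reference values come from PDBTM-style records, which store
a membrane half-thickness; doubling it makes the experimental and
predicted distributions directly comparable.

## Confidence bookkeeping

Mean pLDDT is reported for the whole chain, the TM region, and the
non-TM region (residue-weighted arithmetic means; residues without a
confidence value are excluded). Bin fractions use the conventional
whole-proteome edges 50/70/90 with half-open bins `[lo, hi)` and the top
bin `[90, 100]` closed.

## Structural comparison

**Kabsch.** Optimal rigid superposition is the closed-form SVD solution
restricted to proper rotations; degenerate (collinear or < 3-point)
inputs are rejected. Cross-checked in the tests against a numeric
rotation-space minimiser (rotation grid + Nelder-Mead polish).

**TM-score.** For an aligned pair list, TM = max over superpositions of
`(1/L) Σ 1/(1 + (d_i/d0(L))²)` with `d0(L) = 1.24 (L-15)^(1/3) - 1.8` Å
floored at 0.5. The maximisation uses the standard fragment-seeded
search: superpose on a seed window, then iteratively re-superpose on the
pairs closer than a cutoff until the inclusion set stabilises (≤ 20
rounds), keeping the best score over all seeds. Pinned numerical
choices:

* Seed windows: lengths L, L/2, L/4 (≥ 4) at offsets strided so each
  length contributes ≤ 40 windows. Chains of ≤ 30 residues are seeded
  exhaustively (every window of every length ≥ 4) — cheap at that size,
  and it removes any dependence on the coarse length schedule exactly
  where single-window basins matter most.
* Inclusion cutoff: starts at d0, shrinks linearly to d0/2 + 1 Å over
  the first five rounds, never below 3 Å.
* Ties between equal-scoring seeds: first seed in scan order wins.
* Normalisation: by the reference (library) chain length by default;
  the score under query normalisation is always reported alongside.
* `rmsd` in a result is the Kabsch-minimal RMSD over all aligned pairs
  (C-alpha only); rotation/translation belong to the TM-optimal
  superposition.

The search is calibrated by three identities the tests enforce: a
self-comparison scores exactly 1.0; a construction with every pair
exactly d0 apart — displacement directions balanced to zero net
translation, zero net torque, and a negative-definite second-order form
over rigid modes, so no rigid move improves on the identity — scores
exactly 0.5; and on short pairs the strided search equals an
exhaustive-seed oracle.

**GDT_TS.** Mean over the 1/2/4/8 Å cutoffs of the maximal percentage
of aligned pairs simultaneously fittable within the cutoff, maximised
with the same seed-and-extend machinery (inclusion set = pairs within
the cutoff).

**Sequence-independent alignment.** TM folds within a family often
share < 20-30% sequence identity, so correspondences are built from
geometry alone: gapless threading at every offset proposes seeds,
ranked by the TM sum after superposing on the overlap; the top three
seeds are refined by iterating superpose → Needleman-Wunsch over
`S_ij = 1/(1 + (d_ij/d0)²)` → superpose, until stable or 30 rounds.
The DP uses affine gaps (open −0.6, extension 0 — a gap of any length
costs 0.6), free terminal gaps, and `d0` of the shorter chain. The
best-scoring monotone correspondence wins. Secondary-structure terms of
the full TM-align heuristic are deliberately omitted: the distance-only
variant is simpler, fully deterministic, and its accuracy is checked by
oracle equivalence and threshold behaviour rather than bit-compatibility
with any external program.

**Fold classification.** A query is aligned and scored against every
reference fold; all scores are recorded and the best decides the
verdict: ≥ 0.5 `same_fold`, ≤ 0.3 `unrelated`, the open interval in
between `twilight`. The boundary assignment (≥/≤) is a pinned choice;
the conventional scale only names the interior regions. Ties break by
fold-name order.

## PFAM target selection

hmmsearch per-domain tables are parsed with Biopython. The stringent
filter keeps domains with E ≤ 0.001 whose HMM-coordinate span covers
≥ 90% of the profile length (both boundaries inclusive; the coverage
comparison carries a 1e-9 slack so exact 90% survives floating-point
rounding), then keeps the lowest-E hit per target. Coverage is measured
in HMM profile coordinates, not alignment coordinates — the two differ
when the domain alignment contains insertions. The domain-level
independent E-value is used by default (configurable to the
full-sequence E-value).

For dimer prediction preparation, two chains are concatenated with a
disordered linker and the 1-based segment ranges recorded for later
chain splitting. The bundled 126-residue linker is a synthetic
glycine/serine-rich stand-in of the same length as the intrinsically
disordered regulatory-domain fragment conventionally used for this
purpose; it is not a natural sequence.

## The synthetic-data generator

All tests run on generated fixtures with known ground truth; nothing is
downloaded.

* **Bundles.** n antiparallel ideal α-helices (rise 1.5 Å/residue,
  100° twist, 2.3 Å C-alpha radius — pinned constants) stand on a
  circle of configurable radius, alternate direction, and may be tilted
  tangentially. The two boundary residues of each helix are placed on
  the helix axis exactly at z = ±thickness/2, and a global z-shear
  cancels any lateral offset between the two endpoint centroids, so the
  generated thickness is *exact* by construction for any helix count or
  tilt; Gaussian noise (per-spec seed) is added afterwards. Loops are
  semicircular arcs outside the slab — only their membrane side matters
  to any consumer. Confidence is painted per region (helix vs loop), and
  the matching annotation carries alternating sides and a configurable
  reliability. Default conditions: 4 helices of 24 residues, 30 Å
  thickness, 8 Å circumradius, loops of 4, pLDDT 90/60 — a plausible
  single-domain α-helical membrane protein at the scale where every test
  runs in seconds.
* **Decoys.** `invert_helix` (reflect one helix through the midplane),
  `collapse` (scale z by 0.4), `shear` (z-shift half the helices) —
  the first two are caught by the thickness flag, the third is its
  documented blind spot.
* **Perturbed copies and coils.** Uniform random rotations (normalised
  Gaussian quaternions), translations in [−50, 50]³ Å, optional noise;
  persistent random walks with 3.8 Å steps as unrelated negatives.
* **Reference library.** Eight synthetic stand-in folds named after the
  conventional membrane-fold families of the ABC transporter
  superfamily, with deliberately distinct helix counts (3-8), lengths,
  radii and tilts. They are geometry stand-ins, not the experimental
  family representatives; cross-fold TM-scores between some stand-ins
  exceed 0.5 (idealised bundles genuinely share architecture), which
  does not disturb classification because self- and near-self scores
  are far higher. A config loader populates a real library from
  structure files and TM-domain ranges when those are available.
* **Domain tables.** Format-valid hmmsearch per-domain fixtures that
  round-trip through the parser.

What the generator does *not* emulate: side chains, sequence-structure
consistency, loop realism, lipids, or the error modes of real
predictors beyond the three decoy transformations. Passing tests
therefore demonstrate the correctness of the statistics and the
comparison engine on controlled geometry, not the field performance of
any predictor.

## Sizes and determinism

Test and acceptance workloads use bundles of ~100 residues, libraries
of eight ~60-150-residue folds, 20-50 replicates per property, and
10⁴-draw binomial checks — sizes chosen so the full suite completes in
well under a minute on one core while keeping every statistical bound
meaningful. Every random draw flows from an explicit integer seed (the
acceptance script derives all of its sub-seeds from `--seed`); there is
no global random state, and batch reports contain nothing
time-dependent, so repeated runs are byte-identical.

## Known limitations

* The thickness statistic needs at least one spanning helix per side
  and inherits any topology-annotation error; re-entrant loops are
  excluded rather than modelled.
* The alignment heuristic handles neither circular permutations nor
  very short chains (< 8 residues), and omits secondary-structure
  scoring; scores on real distant pairs may differ from full TM-align
  by small amounts even though the thresholds behave identically.
* Confidence parsing trusts the B-factor column; experimental entries
  with genuine B-factors simply get no confidence rather than a guess.
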