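# Methods

## Problem and model

Two proteins that interact usually do so through short contiguous sequence
regions — binding sites — and many interactions are mediated by short
polypeptide motifs that re-occur across unrelated protein pairs. `pipesites`
exploits this re-occurrence. Given a query pair (A, B) and a database of
known binary interactions with sequences, it computes a **co-occurrence
landscape**: an integer matrix H over window-start pairs where

    H[i, j] = #{ oriented database pairs (X, Y) :
                 window_i(A) re-occurs in X and window_j(B) re-occurs in Y }

Each unordered database pair is counted in both orientations (once for a
self-pair), so the landscape is invariant to the arbitrary column order of
the pair file, and `H(A,B)[i,j] = H(B,A)[j,i]`. A window "re-occurs" in a
database protein when it appears as an exact substring (default), or, in
similarity mode, when some window of the partner scores at least a
configurable summed substitution-matrix threshold against it. The count is
per oriented pair, not per occurrence position, so each entry is bounded by
twice the database size.

Peaks in H mark candidate interaction sites; the hill around a peak marks
the site's extent on each protein.

## Site delimitation

- **Gate.** A landscape whose maximum is below `min_peak_height` (default
  10 co-occurrence counts) yields no predictions: scattered low counts
  indicate window-match noise, not a discrete site. The gate retains
  landscapes with max ≥ 10.
- **Walk.** From a peak of height h, four independent axial runs (up, down,
  left, right) continue while the height stays at or above
  `percent_peak × h`; the four stopping points bound a window-index
  rectangle containing the peak. `percent_peak` (default 0.30; no canonical
  published value exists) trades site compactness against coverage: larger
  values stop the walk earlier and give more specific sites.
- **Spurious peaks.** A peak from which the walk cannot take at least one
  step toward some in-bounds neighbour (that neighbour already being below
  threshold) is a knife-edge spike without a supporting hill — typically a
  coincidental window match — and is skipped. Directions that fall off the
  matrix count as satisfied, so boundary peaks are not auto-rejected.
- **Ranking.** Up to `max_peaks` (default 3) predictions are extracted by
  repeatedly taking the highest unmasked cell (ties: smallest row, then
  smallest column — a determinism choice), skipping/masking spurious cells,
  walking the rest, and masking each predicted rectangle. Walks of later
  peaks stop at masked cells, and the final rectangle is shrunk toward its
  peak until it contains no previously claimed cell, so ranked rectangles
  are pairwise cell-disjoint and peak heights are non-increasing with rank.
- **Coordinates.** A rectangle (i0, i1, j0, j1) over windows of length w
  converts to residue ranges [i0, i1 + w − 1] on A and [j0, j1 + w − 1] on
  B (the union of residues covered by its windows); all external files use
  1-based inclusive coordinates.

For evaluation runs the query pair itself is removed from the training
database (`exclude_query_pair=True`) so that a validation pair that also
appears among the known interactions cannot trivially match itself.

## Distance Measure

Predicted and lab-confirmed site pairs are rectangles over the two protein
axes. Per protein, the distance is the clamped maximum boundary overshoot

    Δ = max(0, start_lab − start_pred, end_pred − end_lab),

zero exactly when the prediction is contained in the lab range — a
deliberate accommodation of lab ranges that over-estimate the true site
(e.g. whole domains reported by peptide-array screens). Each Δ is scaled by
(protein length − 1) and combined vectorially:

    DM = sqrt(ratio_A² + ratio_B²) / sqrt(2)  ∈ [0, 1].

The (L − 1) denominator makes the extreme case — single-residue sites at
opposite ends of both proteins — score exactly 1, and containment on both
sides score exactly 0; for L = 1 the ratio is defined as 0. The published
algebra for the per-protein distance is not unambiguously printed in text
form; the reconstruction above is fixed by the containment clamp, the two
boundary values, and the √2 normalisation note, and the end-difference is
taken as (end_pred − end_lab) — the only sign consistent with both
differences being negative under containment.

`best_of_k` is the minimum DM among the k highest-ranked predictions,
modelling wet-lab validation of k candidates; it is non-increasing in k.

## Evaluation

For each lab-confirmed pair with at least one prediction (gated pairs are
counted and excluded), the report contains the rank-1..k DMs, best-of-1..k,
and a matched random baseline: per protein, a start uniform on {1..L} and
an end uniform on {start..L}, drawn n_random times per pair from a
mandatory seeded generator; the best-of-m baseline uses the first m random
sites, so m = 1 compares against the first random site alone. Summaries:
mean best-of-k DM for predictions and baseline, DM histograms in 10-point
bins up to 50% plus a single ≥50% bin with per-bin enrichment
(predicted/random), and a two-sample Kolmogorov–Smirnov comparison
(`scipy.stats.ks_2samp`, automatic exact/asymptotic p-value selection) of
the rank-1 DM distributions.

The per-protein audit takes each pair's rank-1 DM breakdown and assigns
protein X the score ratio_X/√2 — the pair DM with the partner's term
zeroed, so per-protein scores live on the DM scale and recombine vectorially
to the pair DM (the audit's aggregation formula is a package choice; only
its purpose, detecting proteins that recur and dominate validation, is
canonical). Output is occurrence count and mean score per protein, most
frequent first.

## Annotation analysis

Each predicted site maps to the domain annotation with maximal residue
overlap (ties: longer annotation, then lexicographic accession). Site pairs
annotated on both sides increment an unordered domain-name pair count
(optionally restricted to high-confidence predictions, DM < 0.20); pairs
clean on both sides are reported as candidate novel motifs with peak height
and literal subsequence; mixed pairs (one side annotated) go to neither
table — the conservative reading of a pairwise filter — and are logged.

## Synthetic data generator

The generator emulates the re-occurring-motif premise with full ground
truth. Defaults: 30 proteins of uniform random composition over the 20
standard residues, lengths uniform on 80–200; one motif pair of random
length-14 motifs planted by overwriting residues (lengths and coordinates
stay fixed) into 6 + 6 disjoint carrier proteins at recorded positions;
all carrier-to-carrier cross pairs enter the database (density 1.0) except
one randomly chosen held-out query pair, whose true insertion ranges form
the lab-sites file; non-carrier combinations enter as background noise at
rate 0.02; planted motifs are optionally written as domain annotations.
Everything derives from a single mandatory seed; identical seeds give
byte-identical files.

The planted motif is deliberately longer than the matching window
(14 vs 10): the true site then appears as a (mlen − w + 1)² plateau — a
peak with a supporting hill, the shape real landscapes exhibit — with
height equal to the number of oriented carrier pairs in the database (35 at
defaults, well above the gate). A motif exactly one window long would
instead produce a single-cell spike that the spurious-peak rule rejects by
design; the test suite asserts this rejection explicitly. Note that the
plateau's *edge* cells are themselves spurious under the one-step rule
(their off-plateau neighbour is below threshold), so the walk starts from
an interior plateau cell: recovery is therefore checked as overlap between
the predicted rectangle and the planted window rectangle, not a single
corner cell.

What the generator does **not** emulate: realistic amino-acid composition,
homology and paralogy (correlated sequences), degenerate/partially
conserved motif copies, multiple true sites per pair, and DOMINO-style
over-estimated lab ranges. Passing the recovery tests therefore shows the
landscape/walk/DM machinery is correct and well-calibrated on idealised
signal plus uniform noise — not that real-proteome accuracy is reproduced,
which would require interactome-scale training data.

## Numerical and design choices

- Exact matching with configurable w is the default; similarity mode
  (substitution matrix + threshold) is provided but no canonical constants
  for it are published, so nothing downstream depends on it.
- 'X' matches only itself in exact mode and nothing (including itself) in
  similarity mode — the conservative treatment of unknown residues.
- `match_profile` is cached per (query sequence, database sequence,
  parameters); results are identical with and without the cache.
- Degenerate inputs: sequences shorter than w give a zero-dimension
  landscape and no predictions; an all-zero landscape has no peak; an empty
  DM list makes best-of-k undefined and excludes the pair from averages.
- Test problem sizes (the package's own choices): landscape oracle
  equivalence on 50 random instances of ≤8 proteins, length ≤30, w ≤4;
  DM behaviour by full four-interval enumeration at protein length 6 plus
  per-protein exhaustive scans at lengths ≤12 combined over the distinct
  per-protein deltas (DM depends on the intervals only through those);
  planted-site recovery over 100 generator seeds at defaults; KS null
  behaviour over 100 replicates of 200 pairs; planted-vs-random comparison
  over 30 generated datasets.

## Known limitations

- Landscape heights depend strongly on database scale; the default gate of
  10 is meaningful for databases of at least a few dozen relevant pairs and
  will gate almost everything on very small databases.
- The walk's bounding rectangle can overstate the site for L-shaped hills
  (axial probes see only the peak's row and column).
- Only the top-k peak heights rank predictions; no peak-shape statistics.
- The interaction-decision step of the upstream screening method is out of
  scope: a landscape-maximum gate stands in for "predicted to interact".
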