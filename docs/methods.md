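# Methods

## Background and model

AFLP genotyping converts electrophoretic fragment profiles into a binary
character matrix: samples × size-ordered bins, each cell scoring fragment
presence (1), absence (0) or a failed call (`?`). Because fragments are
anonymous, artifactual amplifications and amplification failures enter the
matrix silently and degrade downstream phylogenetic inference. The one
direct, per-marker measurement of this technical noise is reproducibility
between *replicate pairs* — two independently generated profiles of the same
individual.

At each bin a replicate pair shows one of nine ordered states (i, j) with
i, j ∈ {0, 1, ?}. (0,0) and (1,1) are reproducible, (0,1)/(1,0) are
unreproducible, and any state containing `?` is ambiguous and excluded from
every ratio below. With N_x(i,j) the count of state (i,j) at bin x over
pairs, and M_y(i,j) the analogous count for pair y over bins:

* **Bin reliability** BR_x = (N_x(0,0)+N_x(1,1)) / (N_x(0,0)+N_x(1,1)+N_x(0,1)+N_x(1,0))
* **Replicate reliability** RR_y = (M_y(0,0)+M_y(1,1)) / (M_y(0,0)+M_y(1,1)+M_y(0,1)+M_y(1,0))
* **Mismatch error rate** r_mis = Σ(N(0,1)+N(1,0)) / Σ(N(0,0)+N(1,1)+N(0,1)+N(1,0))
* **Jaccard error rate** r_jac = Σ(N(0,1)+N(1,0)) / Σ(N(1,1)+N(0,1)+N(1,0))

The Jaccard rate drops shared absences from its denominator — shared absence
is weak evidence (a fragment can be lost in many independent ways) — so
r_mis ≤ r_jac wherever both are defined. Both ratios are undefined (and
raise) on an empty denominator; in masking results an undefined rate is
recorded as NaN.

## Masking loop

Given thresholds BR, RR and a minimum bin spacing BD (bases), one fixpoint
run repeats three steps until a full pass masks nothing:

1. mask every pair with RR_y ≤ RR (a pair with no unambiguous state counts
   as failing — there is no evidence of reproducibility);
2. over the surviving pairs, mask every bin with BR_x ≤ BR, every bin with
   no (1,1) pair, every bin whose unambiguous states are all (0,0) (the
   `mask_all_absent_bins` default), and every bin with undefined BR;
3. among surviving bins, mask both members of any size-adjacent bin pair
   whose centers differ by ≤ BD.

Reliabilities are recomputed over survivors each pass, so step order is
observable: masking a globally unreliable pair first can lift a bin's BR
above threshold and save it. Termination is guaranteed because masks only
grow over a finite set. Masking everything that lacks a (1,1) pair subsumes
the all-(0,0) rule when the flag is on; with the flag off, *pure*
invariant-absent bins are kept while any bin lacking a confirming (1,1) is
still masked — this is the one reading under which the flag changes
behavior.

All threshold comparisons use integer arithmetic over hundredths
(`100·reproducible ≤ threshold_hundredths·total`), so grid values such as
0.70 + 7·0.01 compare exactly and the ≤ semantics of the criteria are never
blurred by floating-point drift. The size-spacing comparison adds a 1e-9
guard because size centers are floats.

The sweep enumerates BR from a user minimum (default 0.70) to 0.95 in steps
of 0.01, crossed with RR ∈ {0.0, …, 0.9}; with the default minimum that is
26 × 10 = 260 fixpoints. Cells whose fixpoint fails (e.g. a strict RR masks
every pair) are recorded as failed, not fatal. Cells with identical masked
sets collapse into one group labelled by its BR and RR ranges, and a group
is *emitted* when its selected error metric (mismatch by default) is
strictly < 0.1 and more than 5 bins survive. The masked bin set is then
projected onto the complete matrix (all individuals, not only replicates);
for a masked pair the second (replicate) profile is dropped by default,
with flags to keep it or to drop both profiles.

## Evaluation suite

To choose among emitted matrices the package computes, per matrix:

* **Distances** — Nei-Li (d = 1 − 2·n_uv/(n_u+n_v) over presence counts) or
  uncorrected (fraction of differing calls), both with pairwise deletion of
  `?`; a pair with an empty denominator raises rather than silently
  returning a pseudo-distance.
* **Neighbor joining** — standard Q-criterion agglomeration, re-implemented
  so tie-breaking is deterministic (lexicographically smallest contained
  label pair) and negative branch-length estimates are clamped to zero after
  recording. The Q matrix is formed as (m−2)·D − (R_i + R_j) with the row
  sums added first; forming it as two successive subtractions makes Q
  asymmetric at the last float bit and the argmin side-dependent.
* **Bootstrap support** — bins resampled with replacement, NJ per replicate,
  support of each internal edge of the point tree = percentage of replicate
  trees containing the same leaf bipartition (canonicalized as the side not
  containing the alphabetically smallest leaf). Support is computed on the
  point-estimate tree, not a consensus, matching the practice of annotating
  the NJ tree. Replicates with undefined distances are skipped and counted.
* **Resolution score** — Σ{support > 50%} / (n_leaves − 3), a percentage;
  `inclusive=True` counts exact-50 edges for workflows that annotate ≥50%.
  The denominator is always n−3 (the maximum internal branch count of an
  unrooted binary tree), including when clamped zero-length edges exist.
* **Stemminess** — internal branch length / total branch length; invariant
  under uniform rescaling; 0 for a star tree.
* **PCoA variance** — classical metric scaling (double-centered squared
  distances, symmetric eigendecomposition); reported as 100 × (top-k
  positive eigenvalues) / (all positive eigenvalues). Negative eigenvalues
  (non-Euclidean input) are excluded from the denominator; eigenvalues below
  1e-10 of the spectral radius are treated as zero.

## Input dialects

Commercial genotyping exports vary; the package defines two versioned
dialects plus a generic CSV (see `matrix_io` docstrings): a samples-as-rows
delimited table whose numeric header labels double as fragment-size centers,
and a bins-as-rows table carrying per-bin `Fragments` and `Samples` counts.
In the latter, `Fragments > Samples` reveals a double peak (two markers
inside one bin) and the bin is pre-masked before any reliability analysis;
`Fragments < Samples` is an impossible count and an error. Multi-primer
matrices are concatenated into a supermatrix with bins namespaced
`sourceTag:binID` and missing samples filled with `?`; concatenating a
single matrix is the identity. Size centers are required to be strictly
increasing only within each source block, and the spacing criterion compares
bins within one source block only, since sizing precision is a property of
one electrophoresis run. Mixing dialect families in one run is rejected.

## Synthetic studies

The generator draws a group-structured study: individuals are assigned
round-robin to groups; each bin carries a per-group presence pattern drawn
with probability `p_presence` per group, conditioned on at least one group
carrying the fragment (a bin only exists because some fragment was
observed — without this conditioning, globally absent bins would be
(0,0)-masked and confound selectivity measurements). Bins split into a
reliable and an unreliable class with flip probabilities `epsilon_good` and
`epsilon_bad`; every observed call flips independently with its bin's rate,
replicate profiles are independent re-observations of the same genotype, and
calls drop out to `?` with probability `dropout`. Defaults describe a
mid-sized study: 100 individuals in 5 groups, 300 bins spaced 1 base apart,
20 replicated individuals (20%, above the recommended >10%), flip rates
0.02/0.30, 20% unreliable bins, 1% dropout.

Because replicate flips are independent, a pair disagrees at a bin with
probability 2ε(1−ε), independent of presence frequency; mixing the two bin
classes gives the closed-form expected mismatch rate, and adding
P((1,1)) = p·(1−ε)² + (1−p)·ε² (with p the presence probability after the
at-least-one-group conditioning) gives the expected Jaccard rate as a ratio
of expectations. These expectations back the parameter-recovery tests at
3σ binomial tolerance.

What the generator does not emulate: peak heights, bin-width definition,
size homoplasy between co-migrating non-homologous fragments, or
within-group polymorphism (genotypes are shared within groups). Passing
tests therefore demonstrate the masking and evaluation machinery under a
clean two-class error model, not performance on the full complexity of real
electropherograms.

## Problem sizes and numerical choices

The test suite uses tables up to ~50 pairs × 300 bins and trees up to ~120
leaves; the reproduction script simulates at the generator defaults and uses
1000 bootstrap replicates, the customary count for publication-grade support
values. A full 260-cell sweep on a 50-pair × 300-bin table runs in well
under a second; the bootstrap dominates the script's ~45 s runtime.

Ties in NJ are broken lexicographically; bins tied at a threshold are masked
(≤ semantics); `NA`, blank and `?` all read as missing; unparseable cells
read as missing rather than erroring, since stray annotations are common in
hand-edited exports.

## Known limitations

* The masking outcome depends on the replicate sample being representative;
  nothing in the method can flag bins whose errors the replicates never see.
* The Jaccard-rate denominator can be empty after aggressive masking with
  `mask_all_absent_bins=False`; the result records NaN.
* The bin-distance criterion checks size-adjacent bins only; for BD smaller
  than the inter-bin spacing this equals the all-pairs check, which is the
  intended regime (BD < 1 base).
* PCoA percentages from other software may differ slightly depending on how
  negative eigenvalues are normalized; this package excludes them from the
  denominator and documents that choice rather than matching any one tool.
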