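# Methods

## Data model

The unit of analysis is a *paired alignment*: two multiple sequence
alignments over the 20-amino-acid + gap alphabet whose rows are matched —
row *i* of both members comes from the same organism or strain pair.
Ambiguity codes (B, Z, J) and the rare residues U/O are collapsed to the
unknown symbol `X` on input; `.` and `*` are normalized to the gap `-`.
All scores, P-values, distances and labels live on the L_A × L_B
inter-protein rectangle of column pairs, indexed 1-based within each
protein's *filtered* alignment; intra-protein pairs are never reported.

Column filtering follows the usual convention: a column is removed when
its gap fraction strictly exceeds the threshold (default 0.75), so a
column with exactly 75 % gaps is kept.  Subsampling of row pairs is
uniform without replacement; each (size, replicate) combination uses an
independent RNG stream seeded by (seed, size, replicate), so any single
sub-alignment is reproducible in isolation.

## Sequence weighting

Redundant sequences are down-weighted by the inverse neighborhood size
`w_s = 1/|{t : pid(s,t) ≥ θ}|` (the set includes s).  Percent identity is
computed over columns where at least one of the two sequences is a
non-gap; both-gap positions are excluded from the denominator so that
shared terminal gap blocks cannot inflate identity.  Two conventional
thresholds are exposed: θ = 0.62 for the reported N_eff statistic and
θ = 0.8 for DCA-style frequency weighting and MI_w.  Both are
configurable; the literature does not pin down a single value for the
weighted-MI variant, and its sensitivity to θ is a known caveat.  The
depth statistic N_eff/L divides the effective sequence count of the
concatenated alignment by the total number of columns in both proteins.

## Information statistics

Entropies and mutual information are computed in bits from (optionally
weighted) joint symbol counts.  The default gap policy is
*pairwise-complete*: for each column pair, rows carrying a gap or `X` in
either column are dropped, and the marginal entropies are recomputed on
the retained rows so that `MI = H(A) + H(B) − H(A,B)` holds exactly per
pair.  The alternative `gap-as-state` policy keeps the gap as a 21st
symbol.  Normalized statistics with zero denominators (MI_j when
H(A,B) = 0, MI_Hmin when a column is constant) are masked rather than
zero-filled: a constant column carries no evidence about coevolution, and
forcing 0 would silently dilute ranked lists and null distributions.  No
pseudocounts are used in the information statistics.  VI is a metric on
row partitions and is oriented *lower = stronger*; every score matrix
carries its orientation so that downstream ranking, null models and
benchmarks treat all statistics through one contract.

The average product correction subtracts `rowmean_i · colmean_j /
overallmean` on the inter-protein rectangle, with masked cells excluded
from all means.  Rank-one (fully factorizable) background is annihilated
exactly.  APC is applied to DI by default and is optional for the
information statistics, matching the usual practice of benchmarking the
raw information scores.

## Mean-field direct information

The concatenated paired alignment is modelled with a q = 21-state Potts
model (gap is an explicit state; `X` is treated as gap).  Weighted counts
(θ = 0.8) are regularized with a pseudocount of total weight λ mixed
uniformly; the default λ = N_eff gives the conventional 50/50 mixture.
The connected-correlation matrix is formed over the first q−1 = 20 states
per site (gap is the gauge reference) and couplings are the naive
mean-field estimate `e = −C⁻¹`.  If the inversion fails, a jitter of
1e-8 is added to the diagonal before declaring the covariance singular.

Direct information for a site pair is the mutual information (bits) of
the two-site distribution `P_dir(a,b) ∝ exp(e_ij(a,b)) h_i(a) h_j(b)`,
whose auxiliary fields are found by a damped fixed point (damping 0.5)
iterated until the marginals of P_dir match the single-site frequencies
to 1e-6.  The residual is measured on that marginal mismatch directly —
not on the movement of the fields, which understates the true error near
slow fixed points.  The iteration cap is 5000; strongly coupled pairs
converge linearly but slowly under damping, and a few hundred iterations
are routinely needed at the 1e-6 tolerance, so a cap of a few hundred
would abort valid computations.  All hyperparameters are recorded in the
score-matrix metadata.

It is worth noting what pseudocounts do *not* do: a fully redundant
alignment (all rows identical) mixed 50/50 with the uniform distribution
is a two-component mixture whose pair distribution does not factorize,
so its connected correlations — and hence the mean-field couplings — are
not zero.  The meaningful invariants are permutation invariance, coupling
block symmetry, DI ≥ 0, DI = 0 exactly at zero couplings, and dominance
of planted couplings over background, and those are what the tests
assert.

## Null models

`P_empirical(S)` is the proportion of unmasked scores strictly more
extreme than S (in the oriented sense), taken over the same inter-protein
cell population for every statistic; the evaluated cell is included in
the denominator, following the literal "proportion of scores" reading.
An add-one variant `(#{S' > S}+1)/(M+1)`, which never returns exactly 0,
is available behind a flag.  Tied scores receive identical P-values, so
small alignments with few attainable score values make predictions in
blocks.  `P_normal` standardizes the same population to Z-scores (sample
SD) and reports upper-tail standard-normal probabilities; it is invariant
to positive affine transformations of the scores.  Per-residue summaries
assign each residue the most significant (minimum) P over the
inter-protein pairs it belongs to.  The precision-maximizing threshold
sweeps all attainable cutoffs (predict positive iff P ≤ α), maximizes
PPV, and breaks ties toward the cutoff making more predictions.  A
"simulated" (parametric-bootstrap) null is reserved in the interface but
not implemented.

## Structure contacts

Alignment columns are mapped to chain residues by globally aligning the
ungapped reference row against the chain sequence (BLOSUM62, affine
gaps); columns opposite indels stay unmapped, and an aligned identity
below 0.9 aborts with a wrong-chain error.  Distances use Cβ atoms with
Cα fallback (glycine, or missing Cβ) — the standard Cβ contact-map
convention — or the minimum over non-hydrogen atom pairs.  Residues
missing both atoms yield masked distances.  Contact definitions use
strict inequalities (`< 8 Å`, `< 6 Å`): a pair at exactly 8.000 Å is a
negative.  For crystals with multiple copies of each chain, the distance
is the minimum over all equivalent chain pairings; the equivalent-chain
groups are user-supplied (no automatic symmetry detection).  Per-residue
values can be written as a Chimera-style attribute file for structure
viewers.

## Benchmark metrics

From a confusion table: TPR = TP/(TP+FN), FPR = FP/(FP+TN),
PPV = TP/(TP+FP), F1 = 2·PPV·TPR/(TPR+PPV), and
φ = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)).  Ratios with zero
denominators are reported as NaN, never as 0, so they drop out of
aggregated medians instead of biasing them.  Curves sweep all distinct
thresholds with ties predicted in whole blocks; auROC is trapezoidal
(equal to the Mann–Whitney U probability), and auPR uses precision steps
(sum of precision × recall increment) rather than linear PR
interpolation, which is known to be optimistic.  FPR-controlled
operating points use a strict bound (empirical FPR < α) and choose the
largest prediction set satisfying it; if even one prediction violates
the bound, the all-negative point is returned with a warning.
Entropy-stratified evaluation splits pairs into four groups by
above/below-median column entropy per protein, with ties assigned to
"below" for a deterministic partition.

## Phylogenetic diversity

PD is the sum of branch lengths; for a leaf subset it is the length of
the spanning subtree, computed edge-wise (an edge counts iff it separates
selected leaves), which makes it rooting-invariant by construction.
Maximum-PD subsets use the classic greedy algorithm — seed with the two
leaves at maximal path distance, then repeatedly add the leaf farthest
from the current subtree — which is optimal for PD on trees; ties are
broken by leaf-name order.  Trees are inputs (newick with branch
lengths); tree inference is out of scope.

## Synthetic data generator

The generator emulates the features of real paired alignments that drive
benchmark behavior: shared-tree row correlation (a random coalescent-style
topology with exponential intervals), per-column gamma rate heterogeneity
(shape 2, mean 1, producing a broad entropy spread across columns),
planted inter-protein couplings, optional coupling chains, and optional
terminal gap runs.  Substitution is deliberately simple — on each branch
a column mutates with probability min(rate × branch length, 0.95) to a
uniformly random amino acid — rather than an empirical substitution
matrix: uniform replacement is sufficient to create tree correlation and
rate heterogeneity while keeping the generator fully self-contained and
exactly reproducible.  A planted pair mutates jointly: whenever the
driver column mutates, the partner follows a fixed random residue
permutation with probability c, else redraws independently; at c = 1 the
two columns induce identical row partitions, at c = 0 they are
independent.  A chain i→j→k (i, j in protein A, k in protein B) couples
i–j and j–k so that the inter-protein pair (i, k) is correlated only
through j, with conditional independence of k from i given j holding
exactly in the generative process.

The matching toy structure places one residue per column on two far-apart
chains and moves planted partners to Cβ distance 5 Å (configurable), with
every non-planted inter-chain distance ≥ 12 Å, so structure-derived
labels recover the planted truth exactly.  The tetramer option adds a
second copy of each chain and realizes every second planted contact only
between chain A and the second copy of B, exercising the
minimum-over-equivalent-chains path.

What the generator does **not** emulate: empirical amino-acid exchange
propensities, indel evolution (gaps are injected as terminal runs, not
evolved), domain architecture, or correlated rate variation between the
two proteins.  Passing tests therefore demonstrate correctness of the
statistical machinery and the qualitative depth/diversity behavior, not
performance levels on real protein families.

## Study conditions

- **Planted-contact recovery**: 3 planted pairs at coupling 0.9 among
  40×40 columns, depths N ∈ {16, 64, 256, 1024}, medians over 10 seeds.
  Detection power (TPR at FPR < 5 %) is non-decreasing in depth and both
  MI and DI reach auROC ≥ 0.95 at N = 1024.
- **Direct vs indirect**: one chain i→j→k at coupling c = 0.4, N = 1024,
  20×20 columns, 10 seeds.  The moderate coupling matters: the mean-field
  estimate is a weak-coupling approximation, and at near-deterministic
  coupling both MI and DI saturate on the indirect pair, while in the
  moderate regime the global model explains the (i, k) correlation away
  and demotes it far below MI's ranking.
- **Null calibration**: coupling-free alignments (N = 128, 20×20), where
  every pair is a true null; empirical-P rank calibration is a
  deterministic property, checked to within 1/M.
- **Subsampling design**: 6 sizes {5, 50, 250, 500, 1000, 5000} × 10
  replicates = 60 paired sub-alignments from a 5000-row alignment.

These sizes keep the full suite and the acceptance script at a few
minutes on a single CPU while leaving the depth trend, the calibration
bounds and the ranking comparisons far from their failure thresholds.

## Known limitations

- The mean-field DI is the classic naive inversion, not pseudolikelihood
  or sparse-inverse-covariance estimation; those stronger estimators are
  deliberately out of scope.
- `P_empirical` assumes most pairs are not coevolving; with many true
  contacts it becomes conservative, and in tiny alignments tied scores
  produce block-wise P-values.
- The column→residue mapper assumes a single ungapped reference row per
  protein and author residue numbering; mmCIF and altloc-rich structures
  beyond highest-occupancy selection are not handled.
- Greedy PD selection is exact for PD but quadratic in leaf count in this
  implementation; it is intended for alignment-culling scales (hundreds
  of leaves), not for very large trees.
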