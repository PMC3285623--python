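# Methods

This note documents the statistical machinery, the defaults, and the
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Genome input and coordinates

Internal coordinates are 0-based half-open; the GenBank convention
(1-based inclusive) is converted only at the parsing boundary.  Features
annotated `join()` across the origin of a circular genome keep
`wraps_origin=True` with `start > end`; their sequence is the concatenation
of the two arcs.  This makes arithmetic uniform: for every coding sequence,
`3 × (codon count) + incomplete_stop_len` equals the feature's nucleotide
length, including origin-wrapping genes.

Gene names are normalized against a packaged, user-extensible synonym
table.  Leucine/serine tRNAs are resolved to isoacceptor tokens from the
anticodon (L1 = Leu(CUN), anticodons UAG/GAG; L2 = Leu(UUR), UAA;
S1 = Ser(AGN), UCU/GCU; S2 = Ser(UCN), UGA); a leucine or serine tRNA
without an anticodon is an error rather than a guess.  Duplicated tRNA
tokens (a second tryptophan tRNA occurs in some bryozoans) receive ordinal
suffixes in genomic order; duplicated protein or rRNA tokens are an error
because the gene-order analysis requires unique tokens.  Translation
defaults to the invertebrate mitochondrial code (NCBI table 5), overridable
per call, since metazoan data sets span taxa with differing codes.  A CDS
whose length is not a codon multiple is accepted only when the remainder is
an annotated incomplete termination codon (1–2 trailing bases completed by
polyadenylation in vivo); the fragment is excluded from the codon list and
flagged.  Ambiguity characters other than N are rejected at parse time —
every downstream statistic assumes the 4-letter alphabet, and N is excluded
from all counts.

## Composition and skews

Strand skews follow Perna–Kocher: `AT-skew = (A−T)/(A+T)`,
`GC-skew = (G−C)/(G+C)`, computed on the plus (deposited) strand for whole
genomes and on the coding strand for genes.  A zero denominator yields NaN
(undefined), not an exception, so batch runs survive degenerate inputs.
Reports round percentages to 1 decimal and proportions/skews to 3 decimals;
full precision is kept internally.  Clade summaries are unweighted
per-genome means — weighting by genome length would change the values.

Codon usage counts complete termination codons and excludes incomplete
ones; codons containing N are tallied separately.  Families follow the
isoacceptor convention (Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN, one
family per remaining amino acid, Stop).  Under the invertebrate code, Ser1
spans four codons (AGN), Stop only TAA/TAG, and ATA belongs to Met — the
family table is derived from the code, never hard-coded, so other
translation tables get consistent families.  Published figures of codon-
family usage have been typeset with inconsistent family labels in more than
one study; keying families by codon sets avoids inheriting any particular
labelling.

### Packaged fixtures

The packaged composition table (50 genomes with printed 3-decimal
proportions and derived columns), the per-gene composition table and the
10×10 breakpoint matrix are checksummed at load.  Because the original
derived columns were computed from unrounded counts, 47 of 150 derived
cells cannot be reproduced exactly from the rounded proportions (the
propagated rounding interval is ±0.001 on proportion sums and up to ~0.003
on skews).  Those cells are enumerated in `fixture_metadata.json`; the
integrity check (`fixture_consistency`) asserts that the deviating-cell set
matches that list exactly and that every printed value lies inside its
rounding interval — deviations are documented, never silently tolerated.
Where the source table and its running text disagree on a value
(one ctenostome AT% cell), the fixture stores the table value.

## Breakpoint distances

Gene orders are circular signed token lists.  The adjacency set contains
each consecutive oriented pair canonicalized under the reading-direction
identification `(x, y) ≡ (−y, −x)`; a circular order of n unique genes has
exactly n adjacencies.  The breakpoint distance is the number of
adjacencies of one order absent from the other — symmetric, zero on
identity, and invariant under rotation and under whole-molecule reversal
with sign flip.  Signed adjacencies match the convention of the standard
rearrangement tools; for data sets in which all genes share one strand the
signed and unsigned counts coincide.  tRNAs are excluded by default
(15-token orders over 13 protein-coding genes plus two rRNAs) because
published breakpoint matrices for mitogenomes are computed on protein and
rRNA genes only.  Shared blocks are maximal runs of consecutive genes
appearing with identical relative order and orientation — or fully reversed
with flipped signs — in both orders; the implementation is brute force over
all runs, which is exact and cheap at n = 15.

## Heterogeneity tests

**Across-taxa chi-square.**  Expected cell = row total × pooled state
frequency; statistic `Σ (obs − exp)²/exp`; df = (taxa − 1)(states − 1);
states with zero pooled count are dropped with a warning.  The test treats
taxa as independent samples, which tree-structured data are not; on
strongly correlated taxa it is conservative.  Type-I calibration in the
acceptance suite therefore uses the stationary simulator on a star tree
with branches long relative to the substitution scale, making leaf
sequences effectively independent draws from the stationary composition —
the regime in which the nominal chi-square reference applies.

**Matched-pairs symmetry (Bowker).**  For one aligned pair, the divergence
matrix N counts site patterns over columns where both sequences carry plain
states; `S = Σ_{i<j} (N_ij − N_ji)²/(N_ij + N_ji)` over pairs with
N_ij + N_ji > 0, with df equal to the number of such pairs rather than a
fixed c(c−1)/2 — the standard treatment of empty cells, which matters for
short tRNA-scale inputs.  A pair with no off-diagonal counts is returned as
degenerate (statistic 0, df 0, p 1).  Reversibility plus stationarity makes
the expected N symmetric for any branch length, so two-taxon stationary
simulations calibrate the test directly.  The pairwise summary reports the
raw fraction of pairs with p below the threshold (default 0.05) without
multiple-testing correction, because that is how such fractions are
conventionally reported for these data.

**Deviation statistics.**  The per-taxon statistic is
`d_t = Σ_a |f_{t,a} − f_a|` over the alphabet, with frequencies computed on
non-gap residues (gap treatment per taxon is the package's choice; the
alternative of dropping gap-containing columns alignment-wide discards far
more data).  The global statistic is `max_t d_t`.  Both are calibrated by
simulation: the replicate source is the package's stationary simulator on a
user-supplied fixed tree, standing in for draws from a fitted reference
model — reproducing any particular published posterior-predictive Z scores
would require the original model posterior, which is out of scope, so the
package's claims about this machinery are self-consistency and power
properties that its own suite computes.  p-values use (r + 1)/(n + 1)
smoothing to avoid zero artifacts; Z = (obs − replicate mean)/replicate sd,
with sd = 0 flagged degenerate; fewer than 20 replicates are refused.

The acceptance property plants a single-taxon composition shift of total
variation 0.2 and asks for power > 0.8 at α = 0.05 with 1,000 columns and
100 replicates, with null taxa flagged below 10%.  The packaged study
conditions use 49 taxa on a balanced tree (terminal branches 1.0
substitutions/site so the shifted regime equilibrates, internal branches
0.2), a uniform 20-state base composition, and replicates simulated at the
*observed* pooled frequencies — the analog of fitting the reference model
to the data.  The taxon count matters: the statistic measures deviation
from the pooled composition, so a 1/n_taxa share of any planted shift leaks
into every null taxon; at the ~50-taxon scale of real mitogenome data sets
this spillover is negligible, which is the regime the property describes.

**Recoding and minmax bins.**  Recoding replaces each residue by its group
symbol (canonical group order, mapping stored in the result's metadata),
preserving gaps and per-taxon residue counts.  The minmax search minimizes
the maximum per-taxon chi-square of binned counts against pooled binned
frequencies (df = k − 1; the df convention is recorded here because
published descriptions of the binning software leave it unstated).  The
optimizer is steepest-descent over single-residue moves from ≥ 50 random
restarts, seeded and deterministic, ties broken by lexicographically
smallest canonical partition; on alphabets of ≤ 8 letters it matches
exhaustive enumeration over all set partitions (an acceptance property).
`select_bin_count` scans k from k_max downward and returns the largest k
whose minimum P exceeds α (default 0.05), returning 1 with a warning when
none qualifies.

## Site rates

Likelihoods come from the pruning algorithm run per discrete-gamma
category, vectorized over sites with per-node log scaling (stable for long
trees).  The discrete gamma uses category means — not medians — with G
defaulting to 8, so the weighted mean category rate is exactly 1; gaps and
N enter as all-ones partials; the root uses the model's stationary
frequencies, and re-rooting does not change likelihoods for reversible
models (a tested invariant).  The sitewise rate is the posterior mean
`r̂_s = Σ_g r_g w_g L_{s,g} / Σ_g w_g L_{s,g}`; a maximum-likelihood
category mode (`ml_category_rates`) is available where a hard assignment is
preferred, since published "sitewise rates" do not always state which
estimator was used.  All-gap columns get NaN and are treated as slowest.
Model parameters (exchangeabilities, frequencies, shape) are user-supplied
or fitted by bounded direct search on the fixed tree; tree search is out of
scope — trees are inputs.  Fast-site removal drops the `round(q × L)`
highest-rate columns — the convention that reproduces both of the
package's removal-arithmetic regression values — with ties broken by
keeping the leftmost columns, preserving survivor order.  Amino-acid rate
estimation takes a user-supplied empirical exchangeability matrix; no
"standard" protein matrix is bundled.

## Synthetic data

The sequence simulator draws root states from the root composition and
evolves each branch by the exact matrix exponential of the current
regime's reversible generator (exchangeabilities × current frequencies,
rescaled to unit mean rate) — not by discretized time steps — so a
stationary configuration is exactly stationary, which the calibration
properties require.  Composition breakpoints switch the regime at a
configured fraction along a branch; descendants inherit the new regime,
mirroring the breakpoint mechanism of nonstationary models.  Per-site
gamma rates (optional) scale every branch and are returned as the truth
for rate-recovery checks.  The gene-order scrambler logs every inversion
and transposition (replay reproduces the result exactly), never spans the
full circle, and redraws operations that are circular no-ops, so `k`
logged operations imply a breakpoint distance in (0, 3k].

What the generator does *not* emulate: indels and alignment error, codon
structure within simulated nucleotide alignments, tRNA secondary
structure, within-site rate change over time (heterotachy), and
correlation between composition and rate.  Passing tests therefore show
the statistics behave correctly under their own model assumptions plus the
planted violations; they do not certify behaviour under every bias real
mitogenome alignments contain.

## Problem sizes and determinism

The acceptance computations use: 2,000 replicates for each type-I
calibration (10 taxa × 300 sites for the homogeneity test, pairs of 2,000
columns for the symmetry test); 1,000 random signed circular orders
(n ≤ 10) for the breakpoint oracle; 10,000 codons for usage recovery; 25
planted-shift trials of 49 taxa × 1,000 columns × 100 replicates; six
alphabet/bin configurations for exhaustive minmax comparison; 200 random
4-leaf model/tree draws for the pruning oracle; and 16 taxa × 2,000 sites
for rate recovery.  These sizes give stable Monte-Carlo estimates (binomial
standard errors ≤ 0.005 on the calibration rates) while keeping a full run
in the low minutes.  Every stochastic step is driven by
`numpy.random.default_rng` seeded from the single `--seed` argument.
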