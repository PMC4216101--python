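# Methods

This note documents the models, conventions and numerical choices behind
each stage, and what the synthetic fixtures do and do not establish about
behavior on real data.

## Coordinates and alignment conventions

All positions are 1-based and expressed in the reference taxon's
coordinates (nucleotide positions in the reference CDS, amino-acid
positions in the reference protein). Alignment columns where the reference
carries a gap are insertions relative to the reference; they are excluded
from reference-coordinate bookkeeping and per-domain counts. Gaps must
occur in codon-sized, codon-aligned runs — a frame-breaking gap is a hard
error, as is an internal stop codon. A terminal stop-codon column (all
ungapped sequences ending in a stop) is stripped on input so protein-length
bookkeeping matches the mature peptide.

Gap runs in non-reference sequences are reported as *deletion events*,
never as substitutions; in percent-homology calculations the denominator is
the reference protein length and deleted positions count as mismatches.
(The alternative — excluding deletion columns — would raise homology by
roughly the deletion length as a fraction of the protein; the choice is
pinned here and applied uniformly.)

## Radical/conservative classification

A replacement is *radical* if it changes at least one of three category
memberships, otherwise *conservative*:

- charge: positive {R, K, H}, negative {D, E}, neutral otherwise;
- polarity: polar {R, N, D, C, Q, E, G, H, K, S, T, Y}, nonpolar otherwise;
- volume: small {G, A, S, C, P, N, D, T}, medium {Q, E, H, V, M},
  large {R, K, I, L, F, Y, W}.

Published category tables vary at the margins (notably G, C, H), so the
tables are user-replaceable via a TSV; the defaults above are shipped and
tested. Classification is symmetric in the two amino acids.

Synonymy of a nucleotide variant is judged as a single substitution in the
reference codon context (the other two positions held at the reference
state). Codons differing from the reference at more than one position are
decomposed into their single-base variants and flagged in the log; each
distinct (position, alternative state) pair yields one record, so a
position with two alternative amino acids contributes two records and
radical + conservative counts can exceed the number of substituted
positions.

## Nei–Gojobori dN/dS

Site counting follows NG86: each codon position contributes one site,
split between synonymous and nonsynonymous in proportion to its nine
single-base mutants. Mutations creating stop codons are excluded from the
denominator, and the fractions renormalized so every codon contributes
exactly n + s = 3 sites. Differences between two codons are averaged over
all minimal mutational pathways; pathways through stop codons are
discarded and the remainder reweighted equally (if every pathway is
blocked, all are used unweighted and a warning logged — this arises for a
handful of codon pairs only). Proportions pN = Nd/N and pS = Sd/S receive
the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported
as saturation, and a ratio with dS = 0 is NaN (undefined), never clamped.

Multi-taxon summaries pool Nd, Sd, N and S over pairs *before* correction
(a pooled estimate, not a mean of ratios). The sliding-window scan
(defaults: 50 codons, step 10, in codon units with an optional
nucleotide-unit switch) pools the same quantities per window over a
configurable pair set — by default every non-reference taxon against the
reference — and always emits the dN track separately so windows with zero
synonymous signal remain usable.

## Distance phylogeny

Pairwise distances use the Tamura three-parameter model: with transition
proportion P, transversion proportion Q and pair-mean GC content θ
(h = 2θ(1−θ)),

d = −h·ln(1 − P/h − Q) − ½(1−h)·ln(1 − 2Q),

and the gamma-rates variant replaces each −ln(x) with a·(x^(−1/a) − 1)
(default shape a = 1, configurable). Neighbor joining uses the Saitou–Nei
Q criterion with two pinned determinism rules: exact ties are broken on
the lexicographically smallest pair of cluster labels (a cluster's label is
its alphabetically first leaf), and negative branch lengths are clamped to
zero with the deficit moved to the sibling edge. Bootstrap replicates
resample whole codon columns (frame preserved) under a seeded generator;
support is the percentage of replicates containing each internal
bipartition of the point-estimate tree. Replicates with saturated
distances are dropped and logged; more than 10% dropped is an error.
Zero-length internal edges are treated as unresolved and receive no
support value. Outgroup rooting places the root at the midpoint of the
outgroup's pendant edge.

NJ on model distances stands in for a full maximum-likelihood tree search:
it is deterministic, fast, provably consistent on additive matrices (tested
against exhaustive ground truth), and reproduces the clade-level structure
the downstream analyses need. An externally estimated ML tree can be
supplied as newick and is used unchanged.

## GY94 site models

The rate matrix over the 61 sense codons assigns single-base exchanges the
rate π_target, multiplied by κ for transitions and ω for nonsynonymous
changes; multi-step exchanges have rate zero. A single matrix is scaled to
mean rate 1 at stationarity. For site-class mixtures (M8/M8a) the classes
share one mixture-averaged scale factor — scaling each class separately
would erase the rate differences between ω classes that the mixture
exists to model — so branch lengths are expected substitutions per codon
under the mixture. Equilibrium frequencies default to F3x4 (position-
specific nucleotide frequencies with a +1 pseudocount, renormalized over
sense codons); F61 and uniform are available.

Likelihoods use Felsenstein pruning over compressed site patterns, with
per-node rescaling against underflow and transition matrices from the
π-symmetrized eigendecomposition. Gap codons are missing data (all-ones
partials).

Model fits use Nelder–Mead on log/logit-transformed parameters with
seeded multi-start (default 3 restarts). M0 optimizes (κ, ω) plus branch
lengths — an NJ starting tree, a global branch-scale line search, then one
coordinate pass over individual branches — and its branch lengths are held
fixed for M8/M8a. M8 discretizes beta(p, q) into K = 10 equal-probability
classes at the class medians plus a free class at ω_s ≥ 1 with weight
1 − p0; M8a fixes ω_s = 1. The M8 optimizer additionally starts from the
M8a optimum (with ω_s just above 1), which enforces lnL(M8) ≥ lnL(M8a) in
practice, not just in expectation. The LRT statistic 2·ΔlnL is referred to
the 50:50 mixture of χ²₀ and χ²₁ appropriate to the boundary null
(p = ½·P(χ²₁ ≥ stat); a pure χ²₁ comparison can be formed from the same
statistic if compatibility with other tools is needed). Site
identification is naive empirical Bayes at the MLEs: the posterior
probability of the ω > 1 class per site, thresholded at 0.95 and reported
in reference coordinates. Bayes empirical Bayes is out of scope.

## Simulator and the receptor fixture

The simulator draws root codons from π and propagates each branch with the
exact transition matrix exp(Qt) of the site's ω class, using the same
matrix construction and mixture scaling as the likelihood engine — truth
model and inference model agree by construction, which is the point of the
fixtures. One named RNG substream is spawned per branch (ordered by a
deterministic branch label, not traversal order), so output is
bit-reproducible for a fixed seed. No indels are simulated.

`make_receptor_fixture` builds the standard test dataset: 20 taxa (three
six-taxon ingroup families, a reference lineage, a divergent outgroup) over
420 codons with a 15-region GPCR-style topology map. ω is 0.1 everywhere
except the N-terminus (codons 1–52), third intracellular loop (235–288)
and C-terminus (354–420), where it is 2.0. Four clade-specific
substitutions are planted at positions 241, 319, 399 and 409 in a
designated "monogamous" four-taxon subclade; that subclade's stem branch
has length zero, and any residual parallel substitution that would mimic a
clade-wide replacement is broken by reverting one clade member to the
reference codon, so the planted records are provably the only clade-wide
ones. Because 41% of sites sit in elevated regions, the fixture's *overall*
ω (≈0.6–0.8 depending on estimator and seed) is far above the purifying
background — the fixture is designed for signal-localization and truth-
recovery checks, not to match any particular empirical genome-wide ratio.

What passing on this fixture shows: correct bookkeeping, correct oracle
agreement, and power/calibration of the tests under the generating model.
What it does not show: robustness to alignment error, indels,
among-site rate variation beyond the ω map, codon-usage bias beyond F3x4,
or non-reversible processes — all absent from the simulator by design.

## Problem sizes and runtime choices

Default analysis sizes were chosen so a full test run and the acceptance
script each complete in minutes on a single core: bootstrap defaults to
200 replicates in the pipeline (1000 via the CLI flag for final trees),
site-model validation uses 8 taxa × 300 codons (power) and 2000 codons
(consistency), and the LRT null calibration uses 20 replicates of 6 taxa ×
100 codons with K = 6 classes. These are stated as the package's standard
validation sizes; all scale up by argument.

## Known limitations

- NG86 with equal pathway weighting and JC correction is the pinned
  counting method; no codon-usage-corrected or ML pairwise variants.
- Branch lengths are not re-optimized under M8/M8a (held at M0 values), a
  documented deviation from joint optimization; in practice the bias on
  the LRT is small and conservative at these divergences.
- The NEB site list at MLEs understates uncertainty in (p0, p, q, ω_s);
  posterior probabilities near the threshold should be read accordingly.
- Frequency classes are computed at the genus level; taxa missing from the
  metadata are a validation error rather than being silently dropped.
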