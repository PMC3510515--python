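# Methods

This note documents the model behind the package, the choices that were
genuinely open when it was built, and what its synthetic benchmarks do and
do not demonstrate.

## Model and assumptions

The method rests on one evolutionary hypothesis: residues in intrinsically
disordered regions are, by default, under no positional constraint and
drift independently, while the few residues of a functional short linear
motif are held by selection. A motif therefore shows up in an orthologue
alignment as a *proximal grouping of residues conserved well above their
local background*. Everything the package computes is a formalisation of
that contrast:

1. **Column conservation C.** Identity-based, sequence-weighted
   information content per query column, in [0, 1]. Conservative
   substitutions are deliberately ignored — rewarding physicochemical
   similarity blurs the contrast between invariant motif residues and
   drifting background. Orthologue rows are weighted by their normalised
   distance to the query (plus a floor of 0.01, normalised to sum 1):
   agreement between divergent sequences is stronger evidence of
   constraint. The query row is excluded from the counts, since it matches
   itself at every column. Gap and ambiguity mass is removed from the
   frequencies and penalises the score multiplicatively,
   C = (1 − H/ln 20)(1 − f_gap), keeping the entropy H over a fixed
   20-letter alphabet.

2. **Relative local conservation.** RLC_i = (C_i − mean_i)/σ_i over a
   window of N residues either side of i (i excluded; truncated at the
   termini, never padded — padding would fabricate conservation). The mean
   and σ share the same disorder weights; σ uses the population
   (divide-by-total-weight) convention. An unweighted-σ variant is
   available (`RLCParams.weighted_sigma=False`).

3. **Disorder weighting.** Window residues at least as disordered as the
   focal residue contribute fully; more-ordered residues (likely under
   structural constraint) are down-weighted continuously and
   asymmetrically, w = exp(−a·deficit). The exponential form is this
   package's concrete choice for a weighting that must be continuous,
   asymmetric, equal to 1 under uniform disorder, and sharpened by a
   single strictness parameter. At the default a = 5 a residue 0.2 less
   disordered than the focal residue contributes with weight
   e^(−1) ≈ 0.37.

4. **Tail probability and combination.** p_RLC = P(Z ≥ RLC) under a
   standard normal; a motif's p_motif is the product of p_RLC over its
   defined positions; Sig_motif is the CDF of a product of n independent
   uniforms at p_motif, computed as the regularised upper incomplete gamma
   Q(n, −ln p). The incomplete-gamma form is authoritative (the explicit
   series loses precision for large n and tiny p and is kept as a
   cross-check); n = 1 and p = 1 are returned exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window halfwidth N | 30 residues | background window either side of the focal residue |
| weight strictness a | 5 (dimensionless) | decay rate of the order-penalty weight |
| σ floor | 0.01 | windows with σ below this are masked "homogeneous" |
| min usable window | 10 residues | shorter truncated windows are masked "short-window" |
| disorder cutoff | 0.3 (strict <) | residues below are masked "ordered" |
| gap fraction | 0.25 (strict >) | columns with more orthologue gaps are masked "gappy" |
| min stretch | 10 residues | shorter unmasked runs are masked whole |
| RLC cutoff c | 0 | minimum RLC to enter the search space |
| max defined l | 5 | motif positions fixed to a residue |
| max gap g | 2 | wildcards between consecutive defined positions |
| indel tolerance d | 2 (strict: runs ≥ d fail) | gap-run length tolerated inside a matching orthologue |
| anchor variance | 0.05 | max variance of a candidate's p_RLC values |
| Sig cutoff | 0.05 | reporting threshold |
| branch distance | 0.9 | orthologues farther from the query are pruned |
| min coverage | 0.8 (strict >) | fraction of query residues an orthologue must align |
| min orthologues | 10 | alignments below are rejected |

Boundary conventions are deliberate: coverage is strict (exactly 80% is
insufficient), the disorder cutoff is strict (exactly 0.3 stays unmasked),
the gap fraction is strict (exactly 25% stays unmasked), and an indel run
of exactly d columns is intolerable.

## Design choices that were open

- **Long-branch pruning.** Implemented as a per-row distance to the query
  (1 − identical/mutually-non-gap columns) with a configurable ceiling.
  This is a cheap, deterministic, monotone proxy for branch length, not a
  tree reconstruction; tree inference is out of scope, and the same
  distance feeds the sequence weights, keeping the two consistent.
- **Column scorer.** The entropy × gap-penalty form above is one concrete
  identity-based scorer with the intended range and weighting behaviour;
  it is a swappable strategy (`scorer` argument of `column_conservation`)
  so an alternative column score can be dropped in without touching the
  rest of the pipeline.
- **Masking is a single pass, after RLC.** Masked residues are excluded
  from the motif search space but still contribute to their neighbours'
  window statistics; RLC is not recomputed after masking.
- **Candidate enumeration.** "Within gap g" is read as *at most g wildcard
  positions between consecutive defined residues*. Duplicates reached by
  different extension orders are merged by position-set identity; on small
  instances the enumeration is verified to equal brute force over all
  position subsets. Defined positions may not cross a masked stretch
  boundary, even via wildcards; wildcard positions inside a stretch may be
  residues below the RLC cutoff.
- **Non-overlap selection.** Greedy best-first by ascending Sig_motif,
  ties broken by fewer wildcards (compact motifs first), then leftmost
  start, then the position tuple — fully deterministic.
- **Indel matching.** Only orthologue rows carrying the exact query
  residue at every defined column are constrained (consistent with the
  identity basis of the score); the gap run is measured strictly inside
  the motif's column span, in either the orthologue or the query row.
- **Variance filter.** Population variance of the candidate's p_RLC
  values, switchable to sample variance. Single-position candidates pass
  trivially.
- **Taxonomy.** The minimum-orthologue rule counts retained rows; no
  taxonomic identity is enforced, since the species composition is a
  property of the user's input set.

## The synthetic generator

`slimprints.synthetic` generates the ground-truth data used by the tests,
the examples and `scripts/acceptance.py`. Its defaults model a mid-sized
disordered protein: length 300, 15 orthologues, per-site per-orthologue
substitution probability 0.5 (a substitution always changes the residue,
drawn uniformly from the other 19), no indels unless requested, uniform
disorder 0.6. Planted motifs (standard shape: 4 defined positions with one
internal wildcard) are held with a per-orthologue conservation
probability; planted positions are never deleted. Orthologues evolve
independently from the query — a star phylogeny.

What this emulates well: independent column drift (the null the statistics
assume), islands of conservation of tunable strength, order/disorder
segmentation, and simple indels. What it does **not** emulate: real
phylogenetic correlation between orthologues, rate variation across sites
and lineages, alignment error in disordered sequence (a major practical
failure mode of conservation-based discovery), compositional bias, and
splice variation. Passing the synthetic benchmarks therefore shows the
statistics and the algorithm behave as designed under their own model —
not that real-proteome precision/recall will match.

## Calibration of the Gaussian-tail heuristic

Reading p_RLC off the exact standard-normal tail is a heuristic, and its
systematic error is measurable. A z-score standardised by the mean and
population σ of a 60-value window is not N(0,1) even for Gaussian inputs —
it is a t variable with m−1 degrees of freedom scaled by √((m+1)/(m−1)),
with overall standard deviation ≈ 1.035 at m = 60 — and the discrete,
bounded, skewed distribution of the identity/entropy column score adds
shape error on top. On the package's own null (20,000 scored residues,
uniform disorder) the empirical picture is: mean RLC ≈ 0.00, sd ≈ 1.04,
fraction positive ≈ 0.48, and a KS distance to uniform of the p_RLC values
of ≈ 0.02 (overwhelmingly significant at that sample size). The
sign-fraction imbalance (a few points below one half) reflects the
right-skew of the column score. Because Sig_motif's uniform-product
combination is exact (verified independently by series, incomplete gamma
and Monte Carlo), null Sig_motif values inherit the same order-of-2%
deviation from uniformity. Practically: p_RLC and Sig_motif are accurate
enough to *rank* candidates and to set order-of-magnitude thresholds, but
they are approximate tail probabilities, not exact p-values, and a strict
uniformity test at large n will detect the difference. Users needing
calibrated error rates should calibrate empirically against the null
generator at their own alignment depth.

## Problem sizes used in the standard checks

The packaged benchmarks use: 20,000 null residues for residue-level
calibration; 2,500 fixed-shape candidates spaced 65 residues apart (wider
than the window, so effectively independent) for motif-level calibration;
10⁶ Monte-Carlo draws per grid point for the significance cross-check; 100
replicates for planted-motif recovery; 25 random small instances for the
brute-force equivalence check; and 20 proteins (6,000 scored residues) for
the discriminator ROC. These sizes make every standard error small
relative to the effects being measured while keeping a full run in tens of
seconds.

## Known limitations

- Orthologue prediction and alignment construction are out of scope; the
  package consumes a ready alignment, and its results are only as good as
  that alignment. Misaligned disordered regions produce false islands.
- Disorder scores are an input (IUPred-style); the package does not
  compute them.
- Sig_motif is a heuristic significance, uncorrected for the number of
  candidates examined; the candidate count is exposed
  (`DiscoveryResult.candidates`) for users who want a multiplicity
  correction.
- The conservation scorer is identity-based by design; motifs conserved
  only at the physicochemical level will score poorly.
- On the synthetic benchmark the background is homogeneous, so raw column
  conservation is itself a strong discriminator there; the local
  standardisation pays off on real proteins with mixed ordered/disordered
  composition, which the benchmark only partially represents (two-state
  disorder generator).
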