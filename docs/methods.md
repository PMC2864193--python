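# Methods

This note records the models implemented, the synthetic study conditions,
and the numerical choices that an analyst replacing the synthetic inputs
with real data should know about.

## Paternity statistics

A mating trial is one doubly-mated female: vial-1 progeny carry the first
(marker) male's recessive phenotype; vials 2–3 mix wild-type offspring of
the second (tester) male with marker offspring of the first.  P2 is the
wild-type fraction of vials 2–3; fecundity is defined as the total vial-2–3
progeny — the denominator of P2 — since no other formula is implied by
"female induced fecundity".  P2 is undefined (and the female excluded)
without post-remating progeny.  The `full` inclusion policy drops females
failing either mating; `restricted` additionally drops females with fewer
than 20 offspring and then lines left with fewer than 10 successfully mated
males.

TP2 = arcsin(√P2), the standard variance-stabilising transform for
proportions, maps [0,1] to [0, π/2] and is the response for all ANOVA.
`fit_ancova` computes sequential (Type-I) sums of squares in the fixed
order fecundity → line → block → line×block via nested least-squares fits;
degrees of freedom come from the realized design-matrix rank, so missing
line×block cells reduce the interaction df rather than breaking the fit.
Type-I SS was chosen because it conserves the total SS exactly (tested) and
makes the term order explicit and reproducible; with other SS types the
line F statistic would differ in unbalanced designs.  F is each term's mean
square over the residual mean square.

Breakdown flags come from per-line one-sided Welch t-tests on TP2 against a
heterospecific baseline sample (H1: line > baseline); the flag is set when
H1 is *not* rejected at α (default 0.05), i.e. the line's males perform no
better than heterospecific males.  Welch rather than pooled variance is the
default because line and baseline samples differ in size and dispersion; a
`equal_var=True` switch restores the pooled test.  No multiple-testing
correction is applied across lines by default (none is implied by the
design; the flag is a screening call, refined downstream by the mapping
stage).  The baseline mean's two-sided 95% CI upper bound (t distribution)
is reported for plotting.

## Interval mapping of co-required loci

Cytogenetic coordinates (division 1–102, letter A–F, optional sub-band) are
ordered lexicographically within the arm; coordinates are taken exactly as
given, with no rearrangement correction.  A band without a sub-band is
read as sub-band 1 when opening an interval and as the maximal sub-band
when closing one, so "77B to 84B" covers all of both bands.

`derive_regions` cuts the mapped span at every distinct interval endpoint,
keeps segments covered by at least one line, merges consecutive segments
with identical covering-line sets, and drops zero-width artifacts (the gap
between "just after sub-band s" and "just before sub-band s+1" contains no
position).  Every input interval is then exactly a union of whole regions
(tested as a round-trip property).  Coverage is *full* coverage: a segment
partially overlapped is not covered, because regions are by construction
delimited by introgression endpoints.

`infer_corequired` enumerates every region subset up to `max_set_size`
(default 3), predicts breakdown for exactly the lines covering the whole
subset, and scores by the number of lines whose prediction matches the
observed flag.  Ties are broken by smaller subset size, then lexicographic
order — the minimal co-required set is preferred, which is what makes the
pair {2,4} beat the equally-scoring triple {2,3,4} when spans of regions
2–3 and 3–4 show no breakdown.  Mismatches are reported per hypothesis:
covering-but-unaffected lines as suppressors, affected-but-not-covering as
extra loci.  The enumeration is exact, so it is its own specification; the
test suite checks it against an independent brute force over all 2^k
subsets for k ≤ 10.  A caveat the ranking cannot resolve: large
introgressions may break down for reasons of size alone, which mimics a
multi-region requirement; near-ties between the top hypotheses should be
read with that in mind.

## Expression screen

ΔCt = Ct_target − Ct_reference within each species; ΔΔCt differences the
two species' ΔCt, and the fold is 2^−ΔΔCt (species 2 relative to species
1).  Replicates are paired across species by replicate index and averaged
on the fold scale (not the ΔΔCt scale).  Reciprocity holds exactly per
replicate; the replicate *average* is direction-dependent, which is the
cost of averaging folds.

The experiment-wise threshold resamples the pooled replicate-level fold
values of all genes: 1,000 bootstrap samples of size 2 (the per-gene
replicate count) are averaged, and the empirical q/2 and 1−q/2 quantiles
of that population bound the null band at tail level q (5% and 10% by
default).  Resampling replicate-level values in groups matching the
per-gene replicate count makes each bootstrap average directly comparable
to a per-gene average; resampling gene-level averages instead is available
through `sample_size`/input choice.  Under a null simulation (all true
folds 1) the per-gene flag rate matches the nominal tail level to within
Monte-Carlo error (tested at ±3 binomial SE over 200 screens).

One property of this self-referential null matters for design: the pooled
sample includes any genuinely differential genes, so the tail quantiles sit
*inside* the contaminated cluster whenever the contaminated fraction of
bootstrap averages exceeds the tail level, and below it the thresholds
slip into the clean distribution and admit false positives.  The synthetic
defaults (10 planted genes among ~81, both directions) put the thresholds
in the density gap between clean and planted folds.  A fixed-magnitude
alternative rule (|log2 fold| ≥ 1) is available as `twofold_rule`.

## Codon models and selection tests

The substitution process is a reversible Markov chain on the 61 sense
codons of the universal code (Goldman–Yang form): single-nucleotide
changes at rate π_target × κ^[transition] × ω^[nonsynonymous], zero
otherwise.  Codon frequencies default to F3×4 from the alignment (observed
frequencies optional), floored at 1e−8 and renormalised so every sense
codon stays reachable.  Each generator is scaled to one expected
substitution per codon per unit branch length; transition probabilities
use the symmetric eigendecomposition that reversibility affords (one
`eigh` per (κ, ω), two matrix products per branch length afterwards).

For site mixtures (branch-site model A and its null) branch lengths are
expected substitutions per codon *averaged over site classes*: since the
un-normalised flow rate is linear in ω (rate = A + Bω), a class runs at
effective length t·(A+Bω)/(A+Bω̄) on a branch with mixture-average ω̄.
This is the standard convention; normalising each class separately would
equalise all classes' substitution counts and destroy essentially all of
the branch-site test's power (a mistake worth documenting).

Likelihoods on the unrooted 3-taxon star reduce to one sum over the
internal node's 61 states per site pattern; patterns are compressed with
counts.  Fits maximise over log branch lengths, log κ, log ω parameters
and logit-transformed mixture proportions with L-BFGS-B under box bounds
(t ∈ [1e−7, 50], κ ∈ [0.01, 100], ω ∈ [1e−4, **999**] — estimates at the
cap are reported as 999 and marked capped).  Starting points: an additive
branch-length heuristic from pairwise codon p-distances, plus seeded random
perturbations (`n_starts`), plus — for nested chains — the null model's
solution mapped into the alternative's parameter space.  Warm starts make
the nesting inequalities (ℓ_M0 ≤ ℓ_branch ≤ ℓ_free; ℓ_null ≤ ℓ_A) hold by
construction up to optimizer improvement; the branch-site warm start puts
ω₂ exactly at its boundary value 1 so the alternative can never terminate
below the null.

Tests: free-ratio vs M0 uses df = branches − 1 = 2 on a trio; branch vs M0
df = 1, with the foreground classified accelerated/decelerated when
significant by the sign of ω_fg − ω_bg; branch-site model A vs the ω₂ = 1
null uses df = 1 (χ²(1), not the 50:50 boundary mixture — the χ²(1)
reference is conservative for this comparison, and the null-calibration
test verifies the realised rejection rate sits at or below α).  2Δℓ is
clamped at zero against optimizer jitter.  No multiple-testing correction
is applied across genes by default.  Alignment validation removes codon
columns containing gaps or ambiguity in any taxon (cleandata-style), strips
a shared terminal stop column, and rejects any internal stop, naming its
codon position.

## Synthetic study conditions

The generator defaults define the conditions everything is tested under;
they emulate the introgression-line design rather than any particular
dataset.

* **Mating trials**: 60 lines × 30 females in 9 blocks; 12 lines
  heterospecific-like.  Line means 0.05 (baseline) vs 0.80 (conspecific-
  like); female-level P2 beta-distributed around the line mean (block
  effects N(0, 0.05) added on the arcsine scale) with concentration 12;
  fecundity negative-binomial (mean 45, size 6); paternity and fecundity
  coupled by a shared Gaussian latent factor mapped through each marginal's
  quantile function at Pearson strength 0.119.  Mating-failure rates
  0.20/0.18 reproduce a realistic ~34% exclusion fraction.  A separate
  heterospecific baseline sample (line `MAU`) is always generated.
* **Panel**: five regions tiling 73A–100F with boundaries chosen so
  regions 2 and 4 echo the 77B–84B and 88B–92E map ranges; lines cycle
  through every contiguous span pattern shorter than the whole map
  (singles, adjacent pairs, triples, four-spans); breakdown ⇔ covering
  regions {2,4}, with optional planted suppressor / extra-locus flips.
* **qPCR**: reference Ct ~ N(16, sd), per-gene base ΔCt shared across
  species, species-2 ΔCt shifted by −log2(fold), replicate noise sd 0.15
  cycles (typical replicate precision; the calibration tests separately
  use sd 0.3), 2 replicates.  Pipeline plants 5 genes at 4× up and 5 at
  5× down among ~81 candidates.
* **Codon alignments**: trio branch lengths (0.2, 0.1, 0.3) substitutions
  per codon, κ = 2, uniform codon frequencies; the planted
  positive-selection gene uses model-A classes with ω₀ = 0.1, ω₂ = 8,
  p = (0.5, 0.1) over 500 codons — a regime where the branch-site test has
  high power while null simulations stay at or below the nominal level.

What the generator does **not** emulate: linkage/recombination within
introgressions, multi-chromosome genomes, sequencing error, qPCR
amplification-efficiency variation, ontology structure in annotations
(terms are flat strings), copulation-duration distributions, and real
divergence times.  Passing tests therefore demonstrate that the inference
machinery recovers truth under its own model assumptions at realistic
sizes — not that those assumptions hold for any particular fly dataset.
Observed P2–fecundity correlations are attenuated relative to the planted
latent correlation by binomial counting noise and the line structure, as
they would be in real data.

## Determinism and reporting

Every stochastic component takes a seed; the pipeline expands one global
seed into per-stage seeds by fixed offsets and logs them, and a rerun with
the same seed is byte-identical (tested).  Tabular artifacts are TSV,
reports JSON with sorted keys.  `scripts/acceptance.py --seed N --out F`
reruns the pipeline and the validation experiments at reduced but
representative sizes (50 ANCOVA designs, 20+20 panels, 100 null screens,
25 likelihood-oracle draws, 15 recovery fits, 30 null + 10 power
branch-site simulations) chosen to keep the full run near one minute.
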