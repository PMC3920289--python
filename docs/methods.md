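# Methods

This note documents the models and procedures implemented in `trflptools`,
the defaults they use, and the choices made where more than one reasonable
convention exists.

## Profile processing

A T-RFLP profile is treated as a composition: per sample, peak heights are
divided by the total height of *all* detected peaks, peaks whose relative
height falls below `threshold_pct` (default 0.5 %) are excluded, and the
survivors are re-normalised to sum to 100 %. The threshold is applied before
re-normalisation; the alternative reading (relativise against retained peaks
only, then threshold) is not used because it makes the retained set depend on
the iteration order of exclusions. Downstream statistics therefore always
operate on a proper composition.

Fragment sizes are binned across samples by single-linkage clustering in one
dimension: sorted sizes are split wherever the gap between neighbours exceeds
`bin_tolerance_bp` (default 0.5 bp, i.e. only sub-bp size-calling jitter is
merged). Each bin is labelled with the rounded mean of its member sizes;
should two adjacent bins round to the same integer, the later label is
incremented — a deterministic tie-break that keeps column labels strictly
increasing. Bin labels are therefore approximate integer fragment sizes, as
fingerprint studies conventionally report them.

Duplicate DNA extractions of the same pot and season are averaged per T-RF,
with a T-RF absent in one replicate contributing 0 % there — the conservative
reading of "mean per peak" — and the mean re-normalised. All community
statistics run on these pot-level profiles; the extraction-level matrix is
retained for replicate-fidelity checks.

Metadata uniqueness is enforced on (pot, season, extraction replicate),
because each pot is sampled repeatedly over the growing season.

## Pareto–Lorenz curve and PL20

The T-RFs of one profile are ranked from most to least abundant (ties broken
by ascending fragment size, for determinism); the cumulative band fraction is
the x-axis, the cumulative abundance fraction the y-axis, with (0, 0)
prepended. Only the T-RFs *present* in the profile count as bands — with
that convention PL20 = 20 exactly when all abundances are equal, which is the
property the evenness interpretation rests on. PL20 is the piecewise-linear
interpolation of the curve at x = 0.20, reported on the 0–100 scale. A
single-band profile is degenerate: by default the curve is taken to jump to 1
at its only band (PL20 = 100, maximal dominance); `single_band="linear"`
yields 20 instead. The flag exists because neither convention is canonical.

## Moving-window turnover (Δt)

Percent change between two samples is 100 × (1 − r), with r the Pearson
product-moment correlation between their abundance vectors over the union of
T-RF bins (absent = 0); the matrix is symmetric, zero on the diagonal, and
bounded by [0, 200]. Δt for a window (g → g+1), e.g. spring → summer within
one treatment, is the mean ± sd of percent change over *all* cross-group pot
pairs (6 × 6 = 36 pairs per window and treatment). Correlations on pot means
rather than extraction replicates follow from the averaging rule above. A
sample with zero variance across bins has no defined correlation and is
reported as an error naming the sample.

## NMDS

Distances are Euclidean on the relative-abundance matrix. For a given
dimensionality k, SMACOF majorization alternates a Guttman transform with
isotonic regression of configuration distances in dissimilarity-rank order
(primary tie approach: tied dissimilarities may receive unequal
disparities). Disparities are rescaled each iteration to the configuration's
size so the transform cannot collapse the solution. Reported stress is
Kruskal's formula 1 multiplied by 100. Iteration stops after `max_iter`
(default 500) or when the stress decrease over the last 10 iterations falls
below `stability_tol` (default 1e-7 on the ×100 scale).

Each fit takes the best of `n_restarts` random starts (uniform in [−1, 1]^k,
centered; default 250) plus one deterministic classical-scaling start, which
makes exact low-rank embeddings converge to stress ≈ 0 immediately.
Dimensionality selection fits k = 1…6 and keeps the smallest k whose step to
k+1 gains less than `stress_gain` (default 5 stress units); the k-solution
padded with a zero column seeds the (k+1)-fit, which enforces monotone
non-increasing best stress. The Monte-Carlo structure test permutes each
T-RF column independently, refits, and reports
p = (1 + #{stress_rand ≤ stress_real}) / (1 + n_rand); the default 50
randomizations bound p from below at ~0.02, and the count is a parameter
because the test repeats the full restart procedure.

## PerMANOVA

Squared distances are Gower-centered (G = −½ H d² H). Sums of squares are
sequential (Type I) traces of G under the orthogonal projections of the
nested design subspaces — intercept, season, treatment, season × treatment —
with degrees of freedom from rank differences, so unbalanced extensions are
handled, although the design here is balanced and then Type I equals the
usual partition. Pseudo-F per term is (SS/df)/(SS_res/df_res). p-values use
unrestricted permutation of whole sample rows (default 4999), the same
permutations re-used for every term of one call;
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm). With a Euclidean matrix the
partition equals the sum of univariate ANOVA partitions over columns, which
is how the implementation is cross-checked (and why a one-column analysis
reproduces the classical F exactly). Pairwise comparisons run a one-way
PerMANOVA per level pair (t = √F), unadjusted by default with Holm or
Bonferroni available. When too few distinct permutations exist, a two-moment
gamma distribution fitted to the permuted pseudo-F values supplies an
asymptotic tail probability; the gamma form is a documented approximation to
the permutation distribution, not an exact theory.

## Indicator value analysis

For T-RF i and group g, A = specificity (share of the T-RF's across-group
mean abundance that falls in g) and B = fidelity (fraction of g's samples
where the T-RF is present after filtering); IndVal_i = 100 · max_g (A·B),
with the arg-max group reported and ties broken by declared group order and
flagged. The permutation test shuffles group labels across samples, one
shared permutation set for all T-RFs per call. T-RFs that are zero everywhere
are excluded with a warning. The follow-up univariate test is the classical
one-way F with a label-permutation p, plus pooled-variance two-sample t
statistics per level pair, also by permutation, two-sided; the responder
table combines indicator statistics, per-group mean ± sd, and these p-values.

## In-silico digestion

Enzyme definitions are standard catalog conventions: MboI ^GATC (cut offsets
0/4), HhaI GCG^C (3/1), FauI CCCGC(4/6) stored as offsets 9/11 from the
recognition start. Recognition sites are searched on both strands with
IUPAC-aware matching (a sequence symbol matches a pattern character when its
base set is contained in the pattern's — the site is then certainly
present); overlapping sites are all reported. A top-strand site at p cuts the
labeled strand before index p + offset_top; a bottom-strand site at q (the
labeled strand carries the reverse complement) cuts it before
q + len − offset_bottom. Only cuts strictly inside the molecule are
realisable. The T-RF length convention is the number of labeled-strand
nucleotides 5′ of the cut, counting from the first base of the labeled
forward primer; records are re-anchored at the primer (inosine X/I matches
any base), reverse-complemented if the primer matches the other strand, and
assumed to start at the primer if no match is found (flagged).

The terminal fragment of a double digest is the minimum cut position over the
enzymes — sequential incubations are equivalent to a combined digest for the
fragment nearest the labeled end. Observed capillary sizes run a few bp below
the sequence-derived prediction, so matching uses a ±5 bp window by default,
with a linear-calibration mode (fit observed ≈ a + b·expected on provisional
matches, re-match on residuals) recommended when several anchors exist.

## Synthetic data generator

The generator emulates the pot experiment the analysis assumes: 2 treatments
× 3 seasons × 6 pots × 2 extractions = 72 profiles over a 39-T-RF community.
Its defaults are calibrated — by simulation through the full pipeline — to
the study conditions: pot-mean PL20 ≈ 87 and a major-peak coefficient of
variation ≈ 6.5 % between duplicate extractions.

- **Dominance preset.** Dirichlet concentration vector with three blocks: 3
  dominant T-RFs (geometric, ratio 0.45) holding 82 % of the community, 12
  minor T-RFs (ratio 0.97) holding 14 % — all sitting safely above the 0.5 %
  detection threshold so their presence is stable across replicates — and 24
  rare T-RFs sharing the remaining 4 % (≈ 0.17 % each), which exercise the
  filtering rule but are essentially never retained. Total concentration
  5000 keeps study-to-study wobble small. A consequence of pairing PL20 ≈ 87
  with a 0.5 % filter is that only ~15–20 distinct T-RFs survive filtering
  per study: if the top 20 % of m detected bands hold 87 % of the signal,
  the remaining 0.8·m bands share 13 %, which caps the number of
  concurrently detectable bands near 26. The 39 nominal T-RFs are the
  community; the retained matrix is smaller, exactly as the filter dictates.
  T-RFs in the 0.4–0.7 % range are deliberately avoided: their
  detection flickers between replicates, which manufactures spurious
  indicator taxa — a real artefact of threshold filtering worth knowing
  about when interpreting IndVal on real fingerprints.
- **Noise model.** Pot compositions multiply the cell composition by
  per-T-RF log-normal noise (σ = 0.15) and re-normalise; extraction heights
  multiply the pot composition by a log-normal total signal (median 50 000
  units, σ = 0.2) and per-T-RF log-normal noise whose σ is set from the
  target CV inflated by 1.15, because expressing heights relative to the
  within-sample total cancels part of the raw noise on major peaks (the
  factor was measured by simulation). Fragment sizes get Gaussian jitter
  (σ = 0.15 bp) so binning is non-trivial, and a Poisson number (mean 4) of
  nuisance peaks below the 0.5 % threshold is added per extraction.
- **Planted effects.** Effects are multiplicative on the composition, then
  re-normalised. Because re-normalisation dilutes a fold applied to a large
  component, effect sizes are specified on the *observed* relative-abundance
  scale and converted (`compositional_fold`): the defaults are a seasonal
  responder on abundance rank 1 (observed ×1.82 in summer, ×1.47 in autumn —
  a dominant peak roughly doubling from spring to summer) and a treatment
  responder on rank 2 (observed ×0.60 under ozone, summer only).
- **Sequence fixtures.** Amplicon-like sequences start with the concretised
  forward primer; recognition sites are stamped so the labeled-strand cut
  lands exactly at the requested positions (either strand, honouring the
  strand-specific offsets), and background bases are re-sampled until no
  watched enzyme cuts anywhere else.

What the generator does *not* emulate: PCR and primer-binding bias, rRNA
operon copy-number variation, pseudo-T-RFs from single-stranded artefacts,
partial digestion, or electropherogram-level effects (the systematic
negative size drift of capillary calling is exercised only in the matching
step, not generated). Passing tests therefore demonstrate the statistical
machinery on data with the declared design, dominance, replicate noise and
effect structure — not robustness to those instrument-level artefacts.

## Numerical and design choices

- Permutation p-values always include the observed statistic
  ((1 + exceed)/(1 + n)), so they are never below 1/(n_perm + 1).
- Permutation batches and shared permutation sets are performance choices
  only; seeds fix all of them, and identical configuration + seed reproduces
  every output byte for byte (no timestamps are written).
- The test suite's heavy checks use the sizes they state: null calibration
  runs 1000 simulated studies × 999 permutations; planted-effect recovery
  runs 200 studies; digest oracle equivalence runs 1000 random sequences of
  200–1500 bp. The acceptance script uses 4999 permutations for the single
  reported study, 50 NMDS restarts for dimensionality selection, and 50
  re-simulated studies for the recovery rate.
- Degenerate inputs fail loudly: all-identical samples (zero total SS),
  single-level factors, zero-variance profiles in the correlation step,
  empty profiles after filtering, and gamma fits to degenerate permutation
  distributions all raise typed errors rather than returning numbers.

## Known limitations

- Restricted permutation schemes (within-block permutation, residual
  permutation under a reduced model) are not implemented; all terms use
  unrestricted row permutation.
- The Gower/projection partition is Type I sequential; for the balanced
  design it equals the unique partition, but unbalanced data depend on the
  declared factor order (season, treatment, interaction).
- NMDS per-axis variance shares ("% of information") reported by some
  desktop packages are not computed; stress and coordinates are.
- Indicator analysis implements the original two-factor-free formulation
  only (no site-group combinations, no abundance-corrected variants).
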