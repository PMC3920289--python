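# trflptools

Analysis toolkit for terminal restriction fragment length polymorphism
(T-RFLP) community fingerprints, built around a pot-experiment design —
soil microbial communities sampled across seasons under two treatments,
with duplicate DNA extractions per pot. It covers the full chain from raw
fragment-analysis peak tables to community-level statistics, plus in-silico
prediction of the terminal fragments that clone or isolate sequences would
produce.

## Who it is for

Microbial ecologists working with fingerprint data (T-RFLP and similar
peak-profile methods) who need a reproducible, scriptable version of the
classic analysis stack: profile clean-up, evenness and turnover descriptors,
unconstrained ordination, permutation tests for factorial designs, and
indicator taxon analysis — without stitching together three GUI programs.

## What it computes

**Profile processing** — peak heights are expressed relative to the total
peak height within a sample; peaks below 0.5 % are excluded and survivors
re-normalised; fragment sizes are binned across samples by single-linkage
clustering (0.5 bp gap tolerance); duplicate extractions are averaged
(absent T-RF = 0) into pot-level profiles.

**Descriptors** —

- *Pareto–Lorenz evenness*: T-RFs ranked by abundance; the curve's height at
  the 20 %-of-bands line (**PL20**, in %) scores dominance: 20 for perfect
  evenness, →100 for single-peak dominance.
- *Moving-window turnover*: Δt between consecutive harvests is the mean ± sd
  of 100 × (1 − r) over all cross-group sample pairs, with r the Pearson
  product-moment correlation of the two abundance vectors.

**Ordination** — non-metric multidimensional scaling (NMDS) on Euclidean
distances, minimising Kruskal's stress formula 1 (×100),
`stress = 100·sqrt(Σ(d − d̂)² / Σd²)`, by SMACOF majorization with isotonic
disparities; 250 random restarts plus a metric-scaling start; a dimension is
kept only if it lowers the best stress by ≥ 5; a Monte-Carlo test against
column-permuted data checks the solution is stronger than chance.

**PerMANOVA** — two-way crossed partitioning (season × treatment with
interaction) of the Gower-centered squared-distance matrix;
`pseudo-F = (SS_term/df) / (SS_res/df_res)`; p-values from 4999 unrestricted
permutations of sample rows, with pairwise level comparisons (t = √F) and a
two-moment gamma approximation when too few distinct permutations exist.
On univariate Euclidean data the pseudo-F equals the classical ANOVA F
exactly.

**Indicator analysis** — per T-RF, specificity `A = mean_g / Σ_g mean_g`,
fidelity `B = presence fraction in g`, `IndVal = 100·max_g(A·B)`, tested by
label permutation; significant indicators are followed up with a permutation
one-way ANOVA and pairwise comparisons.

**In-silico digestion** — IUPAC-aware recognition-site search on both strands
for MboI (^GATC), HhaI (GCG^C) and the offset cutter FauI (CCCGC(4/6));
cut offsets are mapped onto the 5′-labeled strand, the terminal fragment of a
(double) digest is the cut nearest the labeled end, coordinates are anchored
at the forward primer, and predictions are matched to observed sizes with a
drift tolerance or a linear size calibration.

**Synthetic studies** — `generate_study` builds peak tables with the design
above: Dirichlet-drawn dominance (pot-mean PL20 ≈ 87), log-normal replicate
noise calibrated to a ~6.5 % major-peak CV, sub-threshold nuisance peaks, and
planted season/treatment responders with known ground truth, so every stage
of the pipeline is testable against what was actually put in.

## Worked example

```python
import trflptools as t
from trflptools.io_profiles import build_profile_matrix

spec = t.StudyDesignSpec(seed=1)                     # 2 treatments x 3 seasons x 6 pots
peaks, meta, truth = t.generate_study(spec)          # raw peak table + ground truth
extractions, pots = build_profile_matrix(peaks, meta, threshold_pct=0.5,
                                         bin_tolerance_bp=0.5)

print(f"{len(pots.samples)} pot profiles x {len(pots.trfs)} T-RFs after filtering")

pl20 = t.pl20_table(pots)
print(f"mean PL20 = {pl20.mean():.1f} +/- {pl20.std(ddof=1):.1f}")

for d in t.moving_window_delta(pots, ["spring", "summer", "autumn"], within="treatment"):
    print(f"dt({d.group_pair[0]}/{d.group_pair[1]}), {d.stratum}: "
          f"{d.mean_pct_change:.1f} +/- {d.sd_pct_change:.1f} (n={d.n_pairs})")

dm = t.euclidean_distances(pots)
ord2 = t.nmds(dm, k=2, n_restarts=50, seed=0)
print(f"NMDS 2-D stress = {ord2.stress:.2f} (Kruskal formula 1 x 100)")

perm = t.permanova_two_way(dm, pots.meta, n_perm=4999, seed=0)
print(perm.table.to_string(index=False))

iv = t.indval_test(pots, "season", n_perm=4999, seed=0)
top = iv["indval"].idxmax()
planted = sorted({e["size"] for e in truth["planted"]})
print(f"top indicator: T-RF {top} (IndVal {iv.loc[top,'indval']:.1f}, "
      f"p = {iv.loc[top,'p']:.4f}); planted responders at {planted} bp")
```

prints:

```
36 pot profiles x 15 T-RFs after filtering
mean PL20 = 86.4 +/- 1.8
dt(spring/summer), ambient: 6.0 +/- 3.3 (n=36)
dt(summer/autumn), ambient: 1.3 +/- 1.5 (n=36)
dt(spring/summer), ozone: 9.2 +/- 5.2 (n=36)
dt(summer/autumn), ozone: 2.1 +/- 3.0 (n=36)
NMDS 2-D stress = 0.46 (Kruskal formula 1 x 100)
            term  df          SS  pseudo_F      p
          season   2 2404.971229 26.636787 0.0002
       treatment   1   51.984520  1.151532 0.2920
season:treatment   2   61.261616  0.678516 0.5324
        residual  30 1354.313824       NaN    NaN
           total  35 3872.531189       NaN    NaN
top indicator: T-RF 332 (IndVal 41.9, p = 0.0002); planted responders at [72, 332] bp
```

Reading the output: the community is strongly dominated (PL20 ≈ 86, i.e. the
top 20 % of bands carry 86 % of the signal); turnover is concentrated in the
spring→summer transition (Δt ≈ 6–9 vs ≈ 1–2 for summer→autumn); the season
term dominates the distance partition (p = 0.0002 at 4999 permutations,
the smallest attainable value) while this seed's treatment effect (a single
T-RF depressed by ozone in summer only) is too subtle for the global
two-way test; the indicator analysis nevertheless flags both planted
responders — the top-ranked indicator, T-RF 332, is the planted ozone
responder and T-RF 72 the planted seasonal one.

The same pipeline runs from the shell:

```sh
trflp simulate --outdir study --seed 3
trflp run --config run.cfg          # flat key = value file; see trflp run --help
trflp digest --fasta clones.fasta --primer CGCGGCCTATCAGCTTGTTG --observed 102,226
```

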