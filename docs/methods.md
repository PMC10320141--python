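# Methods

## Model

The population is assumed strictly asexual over the observation window:
no recombination and no mutation reversal, so clonal lineages nest into
the clades of a phylogeny of sequenced isolates, and each clade can own
synapomorphic alleles — present in every member, absent outside. Each
marker m of lineage l contributes an expected metagenomic allele
frequency g_m · F_l, where F_l is the lineage's *inclusive* frequency
(the genome-copy fraction of the clade and all its descendants) and
g_m ∈ {½, 1} (diploids) or {⅓, ⅔, 1} (triploids) is the copy fraction at
which all members carry the allele. Markers carried at unequal copy
numbers across members are excluded outright, because ploidy otherwise
convolves lineage frequency with per-genome dosage.

Read sampling is modeled as binomial: x_lm ~ Binomial(d_lm, p) with
p = clamp(g_m F_l, ε, 1−ε). The ε floor/ceiling (default 0.002) absorbs
sequencing and mapping error at markers whose true expected frequency is
0 or 1 and keeps boundary likelihoods finite. No overdispersion term is
fitted; the residual misfit at high depth is visible in the optimizer
diagnostics rather than silently reweighted.

### Frequencies are genome-copy fractions

Reads measure DNA, so all inferred frequencies are genome-copy
fractions. A post-hoc converter to cell fractions (divide each exclusive
frequency by its lineage's ploidy, the residual by an assumed ploidy,
renormalize) is provided but never applied by default, since the
residual's ploidy composition is unknowable.

### Constrained optimization

Nesting requires F_child sums ≤ F_parent per family and top-level sums
≤ 1. The feasible polytope is mapped to the unit box by stick-breaking:
in a fixed (topological, sibling-sorted) order, each lineage takes a
fraction u_l ∈ [0,1] of what remains of its parent's frequency (virtual
root = 1). Bounded L-BFGS-B then runs unconstrained in u. The map is
surjective onto the feasible set, so no optimum is excluded; it is
many-to-one only on measure-zero boundaries (a parent at zero). Against
exhaustive 0.005-step grid search on ≤3-lineage problems, the
multi-start optimizer never fell 1e-3 log units short in 25 seeded
instances (it typically beats the discretized grid).

Multi-start defaults to 5 restarts: one from pooled moment estimates
F̂_l = Σx / Σ(d·g) clamped into the feasible set top-down, the rest from
uniform random points of a seeded generator. Timepoints are fit
independently — smoothness of the resulting trajectories is evidence,
not an imposed prior — and a failed timepoint (no marker above the
per-timepoint depth gate, default 10×) is reported without disturbing
its neighbors.

## Ploidy classification

Diploid and triploid spectra are compared as equal-weight binomial
mixtures over their peak locations, {0, ½, 1} vs {0, ⅓, ⅔, 1}, each
peak error-adjusted as p′ = g(1−e) + (1−g)e. Only sites with 0 < x < d
and d ≥ 10 enter the sum: strictly homozygous observations carry no
signal. The 0 and 1 mixture components are retained nonetheless because
sequencing error leaks a tail of homozygous sites into 0 < x < d (e.g.
x = 1 at d = 25), and without shared boundary components that tail is
absorbed asymmetrically by the ⅓ peak, flipping true diploids to
triploid. Gates: ≥50 informative sites (otherwise the call is "unknown",
never a guess) and a confidence flag when |Δlog L| < 10, which is also
where out-of-model ploidies (≥4n) surface. On simulated clones at ~25×
with 0.5% error, classification is exact across 50 replicates.

## Genotype calling

Copy numbers use the same error-adjusted binomial with a uniform prior
over the k+1 states — maximally neutral and exactly reproducible by
enumeration (the test suite checks log-space agreement to 1e-12). Calls
below the 0.95 posterior or the 8× depth gate are missing, and
missingness is budgeted downstream rather than imputed: a site qualifies
as a marker only if the missing fraction among members and among
non-members are each ≤ 0.2.

## Marker selection choices

Markers are polarized on the alternate allele only (g > 0 inside the
clade, g = 0 outside). Sites whose defining state would be the reference
allele are simply unusable; this loses marker density, never
correctness, and avoids the genuinely ambiguous polarization of
reference-vs-alternate. A site whose carrier set matches no clade
(homoplasy, old recombination, reversal) is left unassigned and
reported. When a site qualifies for more than one nested clade through
missingness, it is assigned to the most specific one, keeping marker
sets disjoint. Singleton (one-clone) lineages are allowed but flagged:
their markers may include clone-private artifacts. Clades below
min_markers (default 10; several tests use 5 on small simulations) are
discarded with a recorded reason — enough markers are needed to average
binomial noise at ~90× metagenomic depth.

## The simulator

The generator emulates the study conditions: ~8-month seasons observed
at 15 timepoints (configurable up to ~40), metagenomes at 90× mean
Poisson depth and clonal isolates at 25× (the study reports 87× and 26×
respectively), 8 nested lineages with 20 planted markers each plus 500
background sites, ploidy 3 with probability 0.4 assigned per top-level
subtree, a 0.5% per-read error rate, clone picks of 3 per timepoint, and
one invader entering at 2% frequency ~40% into the season. Trajectories
follow discrete-time logistic competition — exclusive frequencies update
as e′_l ∝ e_l·exp(s_l) with per-lineage log-fitnesses (default
N(0, 0.2²), overridable) and the residual riding along neutrally —
with optional Wright–Fisher multinomial jitter, off by default since the
inference assumes no dynamical model anyway. Background sites are
carried by random subsets of lineages (15% each) at random valid copy
fractions, generating the homoplasic patterns the marker rules must
reject, plus lineage-private variation.

Per-site random streams are keyed by (seed, timepoint, site id). Two
scenarios sharing a site therefore draw identical counts wherever the
expected frequency coincides, which lets the unmodeled-diversity check
compare paired simulations free of sampling-noise differences: an extra
lineage carved out of the residual leaves every modeled lineage's true
trajectory, and hence its inferred estimate, exactly unchanged.

What the simulator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: GATK-style haplotype-aware AD
estimation, mapping bias and non-uniform error, structural variation and
segmental aneuploidy, de novo mutation accumulation during the season,
true recombination histories, and bacterial reads. The phylogeny handed
to the model builder in simulations derives from the truth tree; on real
data it comes from an external phylogeny program, whose errors add a
failure mode not measured here (the neighbor-joining builder included
here is convenience plumbing, not a substitute).

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite in minutes on one CPU: ~660–5,000 sites, 15 timepoints, 45–60
clones, 10–50 seeded replicates per property. Headline checks: recovery
RMSE < 0.05 at 100× depth over 10 seeds (observed ≈ 0.01); grid-oracle
shortfall < 1e-3 log units over 25 instances; unmodeled-diversity shift
< 0.01 (observed 0 by the pairing argument above); ploidy accuracy
100/100 calls; rarefaction RMSE at 5 clones ≥ RMSE at 40 clones in ≥8/10
seeds. Numerical details: optimizer tolerance 1e-9 on the objective,
constraint slack 1e-6 on the nested-sum invariants, frequencies written
at 6 decimals.

## Season arithmetic conventions

Generations per season are n_cycles · log2(1 + r); the printed ~66 uses
8 months × 30 days × 2 cycles × log2(1.1) — months are converted at 30
days by convention. The mutation-supply figure uses a 1.2×10^7 bp
haploid genome (S288c scale; an assumption, the study prints only the
result). The per-site substitution supply divides the per-bp rate by 3
(one specific alternate base of three) and multiplies by ploidy and
population size.
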