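# Methods

## Part mutual information

`pminet` measures the direct association of two expression variables X and Y
given a conditioning variable (or small set) Z with part mutual information,

    PMI(X;Y|Z) = D( p(x,y,z) || p*(x|z) p*(y|z) p(z) ),

where D is the extended Kullback–Leibler divergence `sum p·log(p/q)` (q need
not be normalised) and the partially conditioned marginals are

    p*(x|z) = sum_y p(x|z,y) p(y),    p*(y|z) = sum_x p(y|z,x) p(x).

PMI is zero exactly when X and Y are conditionally independent given Z, and —
unlike conditional mutual information — does not collapse when Z is strongly
dependent on X or Y, which is the regime of co-expression data. All values
are in nats.

### Estimation

Probabilities are plug-in estimates on discretized data. Variables are binned
by equal-frequency quantiles (configurable to equal width), default 3 bins —
a small-sample-robust choice that keeps the 3×3×k table well populated at
cohort sizes of a few hundred samples. Degenerate (constant) variables are
rejected. Zero-probability conventions: terms with p(x,y,z)=0 contribute 0;
p(x|z,y) is undefined where p(z,y)=0 and that term contributes 0 to p*; a
cell with p>0 against q=0 returns a +inf sentinel, which the elimination loop
treats as "retain edge". No pseudocounts are applied by default, so
small-sample estimates equal the exact empirical table (a Laplace `alpha` is
available).

Two refinements matter when absolute PMI values are compared rather than
thresholded:

* **Finer conditioning bins** (`n_bins_z`, default 5 inside the network
  builder). Conditioning on a coarsely binned Z leaves residual within-bin
  dependence: for the unit-coefficient chain X1→X2→X3 with noise sd 0.5 the
  large-sample conditioned PMI is ≈0.056 at 3 conditioning bins but ≈0.012
  at 5 and ≈0.002 at 8. Finer bins shrink this leak; x and y keep the coarse
  grid so the table stays estimable.
* **Shuffle bias correction** (`shuffle_correction=B`, default 10 inside the
  network builder, 0 in the bare `pmi()` primitive). The plug-in estimator
  has a positive small-sample bias that grows with table size, and the p*
  construction amplifies noise from sparse (z,y) cells. Permuting x within
  each z stratum produces data in which X and Y are exactly conditionally
  independent given the binned Z while all (X,Z) and (Y,Z) margins are
  preserved; the mean PMI over B such permutations estimates the spurious
  part and is subtracted. The permutation generator is seeded
  (`shuffle_seed`, default 0), so every call — and therefore every network
  build — is deterministic. The bare primitive defaults to the raw plug-in
  so that it matches direct summation of the defining formula on the
  empirical table exactly.

On the chain benchmark, the corrected estimator leaves direct edges at ≈0.4
nats while the mediator-conditioned indirect pair drops to ≈0.02, under a
fifth of its unconditioned value in ≥90% of simulation seeds.

## Network construction

The build starts from the fully connected network over the input genes.
Order 0 removes every pair whose unconditioned PMI falls below the threshold.
At order k ≥ 1 each surviving edge (X,Y) is re-tested against all k-subsets
of the *common network neighbours* of X and Y (a path-consistency-style
bound on the otherwise intractable scan over all variable combinations); the
edge's retained strength is the **maximum** PMI over the candidate
conditioning sets, and the edge is removed when even that maximum is below
the threshold. Orders rise until `max_order` (default 1) or until a pass
removes nothing. Passes are synchronous — neighbour sets are frozen at the
start of each order — and candidates are enumerated in sorted order, so the
result is independent of edge enumeration order and fully reproducible.
Whether conditioning sets should extend beyond common neighbours is left as
a strategy question; common-neighbour subsets are the implemented default.

The *optimal* network is chosen by scanning an ascending threshold grid and
watching when the edge sets stabilise: the chosen network is the first whose
Jaccard similarity with the next threshold's network reaches
`stability_tol` (default 0.95); if the scan never stabilises the last
(sparsest) network is used and a warning logged. The default grid
(0.02–0.30, finer at the low end) matches the scale of the bias-corrected
estimator, where noise pairs sit near 0 and direct edges above ≈0.1. PMI
evaluations are memoised across the scan, so the grid costs little more
than a single build.

Genome-scale inputs are out of scope by design: optimal networks are meant
for gene sets of tens of genes (the regime in which the threshold scan is
affordable), mirroring how the analysis splits the genome into functional
modules first.

## Comparable PCC networks

Three Pearson-correlation constructions make a PCC network comparable to a
given PMI network: type 1 matches the edge count (pairs by descending
|PCC|), type 2 matches node coverage (shortest descending-|PCC| prefix
covering the PMI network's edge-bearing genes), and type 3 works per PMI
edge — any third gene whose |PCC| with *both* endpoints exceeds the edge's
own |PCC| contributes its two edges. Type-3 edges absent from the PMI
network are the **PCC-only** edges: pairs that plain correlation ranks above
a retained direct edge but that PMI elimination discarded as indirect. Ties
in |PCC| break lexicographically on the sorted pair name; zero-variance
genes are excluded with a warning. The type-3 result includes the PMI edges
themselves so both networks live on one universe for recall comparison;
PCC-only extraction is unaffected.

## Correlation change networks

Four single-stage networks (normal plus three cancer stages, numbered 1–4)
over one gene universe combine into a union network. Each edge carries a
4-bit existence pattern (`0-1-1-1` = present in all three cancer stages but
not normal). Edges whose set bits do not form one contiguous run are treated
as unstable and filtered *before* node statistics are computed. Each node's
mean stage value averages the stage numbers over all of its (edge, stage)
incidences — each incidence counted once — placing genes early or late along
the progression.

## Omics-defined gene-pair relationships

* **CoTR** — per pair, the number of common upper regulators, with TF and
  miRNA regulators counted in separate tables, never mixed.
* **PPI** — curated interaction pairs, weight 1.
* **SCGD** — |TSS1 − TSS2| for same-chromosome pairs; coordinates are BED
  dialect (0-based half-open), TSS = interval start on +, end on −.
* **CoCNV** — per pair and sample: GG/LL/GL/LG by the signs of the two
  GISTIC-style calls, NC when either call is 0. GL/LG are oriented by the
  pair's canonical (sorted) gene order, recorded in output so reversals are
  recoverable. Pair weights per status: sample count, sample fraction, and
  the level-product-weighted count using |cnv1·cnv2|.
* **CoDM** — per gene and sample, counts of low/high-methylation CpG islands
  (beta < 0.3 low, > 0.7 high by default — the standard hypo/hyper
  conventions, configurable); per pair, the four cross products LL, HH, LH,
  HL (which always satisfy HH·LL = LH·HL). Island counts are per sample, as
  required for a per-sample CoDM status.

## Recall statistics

A network *recalls* a relationship record when the record's pair is a
network edge (order-insensitive). Significance is a permutation Z-score:
draw the same number of pairs uniformly without replacement from all pairs
of the universe (default: the network's gene set, matching comparisons
within a fixed PMI gene set), count recalls, repeat `n_perm` times (default
100), and standardise. For weighted relationships each weight column yields
a labelled weighted variant (weight sums replace counts). A degenerate null
(sd 0) returns NaN with a warning. The null mean/sd agree with the exact
hypergeometric moments, which the tests verify at large `n_perm`. Weight
distributions of two recalled sets are compared with a two-sided
Mann–Whitney U (distribution-free; Welch's t behind a flag). Depletion
(e.g. mixed gain/loss statuses) simply appears as a negative Z.

## Survival factors and scoring

For each candidate pair, CoCNV statuses partition patients into five groups;
every unordered group pair with both sizes strictly greater than `min_n`
(default 20) is log-rank tested. CoDM values with normalized mean absolute
deviation — mean(|v − mean v|)/mean(v), the formula being this package's
reading of the filter — above 0.25 are median-split (high = strictly above
the median) and tested. Comparisons with p < 0.05, uncorrected (an optional
BH flag exists but is off to mirror the uncorrected design), become factors
written `better > worse`, oriented by the larger area under the
Kaplan–Meier curve (restricted mean survival time to the last observed
time).

Each factor-bearing pair contributes I_gp ∈ {−1, 0, +1} per patient: for
CoCNV, +1 if the patient's status appears only on the better side of the
pair's factors, −1 only on the worse side, 0 for NC or unmentioned statuses;
a non-NC status on both sides raises an error rather than silently summing.
For CoDM, each factor contributes ±1 by the patient's median-group side, and
a pair with several CoDM factors contributes the sign of the sum — keeping
I_gp in {−1, 0, +1}. The patient Score is the sum over pairs; patients are
split into low/mid/high Score tertiles with ties assigned downward (fixed
cutpoints are also supported). Cox proportional-hazards fits (lifelines)
take the score(s) — CoCNV and CoDM scores may enter one model together —
plus simplified integer clinical covariates, and `subsample_stability`
refits on 100 random 80% subsets reporting the mean and sd of each
regressor's p-value. A single-gene mode encodes per-gene CNV statuses as
G/L/NC and reuses the same grouping/testing machinery; this is an
interpretation, flagged as such.

## Synthetic data

The generator plants known ground truth for every stage:

* **Expression** — linear-Gaussian structural cascades: roots N(0,1),
  children = coefficient-weighted parent sums + N(0, noise_sd²), sampled in
  topological order. Chosen because path correlations have closed forms
  (products of edge correlations), giving independent oracles. Defaults
  follow the benchmark conditions used throughout: unit coefficients, noise
  sd 0.5, n=1000–2000. A quadratic link exercises non-monotonic dependence
  (Y = X² + noise is uncorrelated with X yet strongly dependent).
* **Staged expression** — the base graph restricted to four per-stage edge
  masks, with per-stage seeds derived deterministically from one seed.
* **CNV** — planted pair co-mutation at stated per-status rates (levels from
  {1,2} with status signs) over independent background mutations (default
  rate 0.05, calls uniform in {−2,−1,+1,+2}).
* **Methylation** — island betas from a three-component uniform mixture
  (low [0,0.25], mid [0.35,0.65], high [0.75,1]) with per-gene weights, so
  component fractions are recoverable by moments.
* **Survival** — exponential times with per-sample hazard = baseline × the
  product of planted status multipliers (group medians therefore have the
  closed form ln2/hazard); each sample is independently censored with
  probability `censor_rate` at a uniform fraction of its event time.

What the generator does *not* emulate: microarray noise models, batch
effects, copy-number segmentation, probe-level methylation artefacts, or
competing risks. Passing tests therefore certify the algorithmic pipeline —
estimator correctness, elimination behaviour, calibration, scoring — not
robustness to real-cohort technical variation.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to exercise
each property cleanly: 3-gene chains at n=2000 (50 seeds) for suppression,
20 genes/10 edges at n=1000 (10 seeds) for recovery, a 50-gene universe
(200 replicates, 100 permutations) for Z calibration, and cohorts of
200–500 patients for the survival properties. Tolerances: oracle equality
to 1e-9; symmetry to 1e-12; probability-table normalisation to 1e-9;
stochastic properties asserted at ≥80–90% success rates or within ~4
standard errors. Tie-breaks are everywhere lexicographic on sorted gene
names; all randomness flows through seeded NumPy generators.

## Known limitations

The binning estimator is a declared substitute for the original
kernel/grid-based PMI estimators, whose details are not restated here; the
binning scheme, bin counts and correction are exposed as configuration.
Conditioning candidates are restricted to common-neighbour subsets of order
≤ `max_order`. Edge-set containment across thresholds is guaranteed only at
order 0 (conditioning makes higher-order removal non-monotone; edge counts
in practice still fall with the threshold). The scan's stability rule
(consecutive Jaccard ≥ 0.95) is a design choice — no canonical criterion
exists. Whole-genome optimal networks are explicitly out of scope.
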