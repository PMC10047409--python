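# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, the numerical choices, and what the synthetic-data
validation does and does not establish.

## Synthetic study generator (`simdata`)

The generator emulates a staged small-RNA experiment: by default 3
developmental stages (labelled D85/D105/D135) × 3 replicates, 200 mature
miRNAs (lengths 20–24 nt with a mode at 22 nt), 300 lncRNAs and 2,000 mRNA
3'UTRs of 500 nt, and 20 contaminant decoys standing in for rRNA/tRNA
filter databases. All sequences are uniform-random over their alphabet with
planted binding sites overwritten; GC content is not controlled, which is
sufficient for seed-match testing but not for thermodynamic realism.

**Temporal profiles.** A fraction `frac_de` (default 0.3) of miRNAs is
differentially expressed. Each DE miRNA gets one of four non-flat shapes,
planted as per-stage log2 offsets relative to stage 1 (effect size *e*,
default 2):

| shape          | offsets            | consecutive log-ratio signs |
|----------------|--------------------|-----------------------------|
| incremental    | (0, e/2, e)        | (+, +)                      |
| decreasing     | (0, −e/2, −e)      | (−, −)                      |
| high–low–high  | (0, −e, 0)         | (−, +)                      |
| low–high–low   | (0, +e, 0)         | (+, −)                      |
| irregular      | (0, 0, 0)          | flat ⇒ not DE               |

The extreme-stage contrast of the monotone shapes equals *e* (stage-3/stage-1
mean ratio 2^e); the classifier in `diffexp` uses exactly the same sign-pattern
definition, so generator and classifier share one convention. "Irregular" is
simulated as flat: it is the absence of a planted pattern, not a fifth
pattern.

**Sponge triplets and repression.** `n_triplets` (default 50) triplets are
planted on distinct DE miRNAs, distinct lncRNAs and distinct mRNAs. Each
arm receives `sites_per_target` (default 2–3) non-overlapping 8mer seed
sites — competing transcripts in the ceRNA literature carry multiple
response elements, and a single 8-nt match is statistically
indistinguishable from a chance hit on a 500-nt transcript. Repression is a
mean shift, not a kinetic titration model (the downstream analysis is
correlational): a target's stage offset is the regulator's offset times
log2(1 − r), i.e. the target drops by the fraction `repression_strength`
(default 0.5) for every two-fold rise of its miRNA, and symmetrically
rises when the miRNA falls. Multiple regulators compound additively in log
space.

**Counts.** Relative abundances are lognormal (σ = 1, normalized);
per-sample library sizes are drawn uniformly from `lib_size_range` (default
0.3–0.6 M for the count-level study). Counts are gamma–Poisson draws with
`var = μ + φμ²`; `nb_dispersion` φ defaults to 0.1, a typical value for
bulk RNA-seq biological replicates. φ → 0 recovers Poisson sampling.

**Reads.** Each miRNA contributes exactly its count of reads — mature
sequence (U→T) plus the TruSeq small-RNA 3' adapter, truncated to
`read_length` (50 nt) with Phred-40 qualities. Noise reads are injected so
that each class makes up its configured fraction of the raw total:
contaminants (decoy + adapter), low-quality (Phred-10), N-containing,
short fragments (5–17 nt) and adapter dimers; counts are deterministic
(rounded expectations, not binomial draws) so the accounting identity
`raw = signal + Σ noise` is exact by construction and every planted noise
read trips exactly the filter it was made for. Reads are shuffled with the
seeded generator. The generator does not emulate sequencing errors inside
inserts, 5' isomiRs, adapter mismatches, or genome alignment.

All outputs are pure functions of (config, seed) via independent named RNG
streams; identical inputs give byte-identical files.

## Read processing (`readproc`)

The adapter is located by the longest prefix of the adapter matching the
read's 3' end with ≥ 6 nt overlap and no mismatches; unmatched reads are
kept untrimmed and a warning is logged if > 90 % of reads lack the adapter.
Filters apply in a fixed order — dimer, low quality (mean Phred < 20,
a declared convention), N-containing, short (< 18 nt), contaminant
(exact or substring match against user-supplied decoys) — so each read is
counted in exactly one category. Quantification assigns a collapsed read to
a mature if it equals it or differs only by ≤ `allow_3p_trim` (default 2)
nt of 3' trimming/extension, mirroring the `_R + 2`-style 3' variants of
small-RNA profiling; ties resolve to the smallest length difference, then
the lexicographically first name, with collisions logged. An exhaustive
reference × variant scan serves as the test oracle.

## Differential expression (`diffexp`)

**Normalization.** TMM-style: the reference sample is the one whose upper
quartile of relative expression is closest to the mean upper quartile (ties
lexicographic); per-sample factors are the doubly trimmed mean (30 % of
log-ratios, 5 % of average log-expression, trimmed from each side,
unweighted) of per-feature log2 ratios against the reference, over features
positive in both samples, rescaled to geometric mean 1.

**Exact test.** A single common dispersion is shared across features —
with three replicates per stage, per-feature (tagwise) estimation is too
unstable without empirical-Bayes machinery, which is deliberately out of
scope. It is estimated by pooled moments on library-size-adjusted counts:
φ̂ = Σ df·(s² − ȳ) / Σ df·ȳ² over features and groups, clipped at 0, with
two refinement passes. Counts are quantile-adjusted to the geometric-mean
effective library size by moment-matched quantile mapping (the count's
percentile under a normal and under a gamma approximation with NB variance
is re-expressed at the output mean and the two estimates averaged) — exact
when library sizes are equal and preserving the first two NB moments
otherwise. The test conditions on the pooled adjusted count per feature:
group sums are NB with size n/φ, and the two-sided p-value sums the
probabilities of all splits no more likely than the observed one (the
binomial split test in the Poisson limit; the implementation switches to
the binomial form below φ = 1e−10, and restricts the summation range to a
±50 SD window only for pooled counts above 20,000, where the truncated
mass is far below double precision). Fold changes use a 0.5 pseudo-count
on adjusted group means. BH-adjusted FDR is emitted but calling uses raw
p-values at inclusive thresholds (p ≤ 0.05, |log2FC| ≥ 1).

Null calibration (20,000 features, 3 vs 3, φ = 0.1) puts the fraction of
p ≤ 0.05 at ≈ 0.046–0.049 — slightly conservative, as expected for a
discrete exact test.

**Profiles.** Stage means of CPM (0.5 pseudo-count), consecutive log2
ratios thresholded at `tau`: default log2 1.5 ≈ 0.585, a conventional
minimal fold change. When scoring recovery of planted patterns with a known
step size e/2, the decision-theoretic threshold is the midpoint e/4; with
the default e = 2 and φ = 0.05 this recovers ≈ 96 % of planted shapes
(the residual loss is replicate-level biological variance, irreducible by
sequencing depth), while the stricter default trades recall of weak
monotone patterns for robustness on real data where e is unknown.

**Overlap.** The Venn partition is exact set algebra over the three
comparisons; the triple intersection is the core set carried forward.
Sequence-identical matures merge under the lexicographically first id.

## Target prediction (`targets`)

Canonical classes follow the standard seed taxonomy (6mer, 7mer-m8,
7mer-A1, 8mer; 'A' anchors are literal transcript adenines, not pairing).
Matching is exact string matching of the window patterns; a window nested
inside a stronger-class window is reported once under the stronger class.
The noncanonical mode reports, per alignment anchor, the longest run of
consecutively paired positions against miRNA positions 1–10 (WC, plus G:U
wobble outside the 2–7 core when enabled) of length ≥ `noncanonical_min_run`
(default 7, the smallest run that keeps the chance-hit rate below one per
few kb); runs overlapping a canonical site are suppressed. Scoring is a
transparent additive proxy (WC pair 1.0, wobble 0.5, class bonus
3/2/1.5/1/0) — deliberately not a free-energy model; it only needs to be
monotone over classes. Coordinates are 0-based half-open on the transcript
sense strand, with a 1-based closed conversion for browser-style output.

This single matcher replaces the multi-database prediction of typical
ceRNA studies. The pair-evidence rule used by the pipeline — at least two
canonical sites of which at least one is an 8mer — stands in for
multi-predictor intersection: on 500-nt random sequence the chance of a
single 7mer-class hit is ~3 % per pair and of an 8mer ~0.8 %, far too
common to separate signal from noise at hundreds of DE features, while the
conjunction drops the chance rate to ~5 × 10⁻⁴.

## ceRNA network (`cerna`)

A (miRNA, transcript) pair is kept only if both are DE in the comparison
at hand with strictly opposite directions and carry site evidence. Triplets
join a lncRNA pair and an mRNA pair over their shared miRNA (counts
multiply: #lncRNA partners × #mRNA partners per miRNA); direction
consistency between the two pair lists is enforced. The network is
layered bipartite by construction (lncRNA–miRNA and miRNA–mRNA edges only;
anything else raises), regulation attributes are carried from the DE calls,
per-comparison networks are unioned with a `comparison` edge attribute and
conflicting node regulations across comparisons become "none". Degree
counts all incident edges in the union graph; hubs sort by (degree desc,
id asc); module extraction is the radius-1 induced neighborhood (community
detection is out of scope). GraphML and TSV edge lists are exported for
graph viewers.

## Assays (`assays`)

2^−ΔΔCt: per sample, ΔCt = mean target Ct − mean reference Ct; ΔΔCt
subtracts the calibrator group's mean ΔCt, so the calibrator's geometric
mean RQ is exactly 1. With two reference genes (e.g. U6 and β-actin) one RQ
series is emitted per reference; no geometric averaging across references.
Dual-luciferase: ratio = hluc/hRluc, normalized to the NC-treatment mean of
the same construct. Group-level inference (ANOVA, t-tests) is deliberately
left to the user; only means ± SD are emitted. Ct values are validated to
(0, 45) cycles.

## Validation design and problem sizes

The test suite checks every stage against an independent oracle: exhaustive
window-by-window seed matching, exhaustive read-to-reference scanning,
direct set enumeration for the Venn partition, incidence counting and BFS
for the network, the exact binomial split test in the Poisson limit, and
hand-computed assay tables. End-to-end, the pipeline is scored against the
planted truth at the study scale (200/300/2,000 features, 50 triplets,
e = 2, r = 0.5, φ = 0.1): precision 0.93–0.98 and recall 1.0 across seeds.
Simulation sizes were chosen to make these checks sharp yet quick: 20,000
features for null calibration, 1,000 random pairs for matcher oracle
agreement, 2,000 features at 5–8 M library depth for profile recovery, and
~30 k-read libraries for the FASTQ stage.

Passing these checks shows the implementation is faithful to its stated
models and recovers structure it is designed to detect. It does not show
that the models capture real small-RNA data: the simulator omits isomiR 5'
heterogeneity, sequence-composition bias, expression-dependent dispersion
trends, correlated replicates and genuine multi-database target evidence,
so performance numbers on synthetic data are upper bounds, not forecasts.

## Known limitations

* Common dispersion only; no tagwise shrinkage or GLM/quasi-likelihood
  testing. No multiple-testing correction in the calling rule (an FDR
  column is provided).
* The seed matcher scores by additive pairing weights; no duplex folding,
  conservation or site-context features.
* Profile classification is defined for exactly three stages.
* The directionality rule needs every feature to be up or down in the same
  comparison; features significant in no shared comparison cannot enter
  triplets even if they carry sites.
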