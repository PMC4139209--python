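# Methods

## The inference

The package's core claim structure is: a miRNA's biologically relevant
targets are those genes that (i) carry a seed-complement site in their
3′UTR with a favorable net binding energy, (ii) are transcriptionally
down-regulated in the condition where the miRNA is induced, and (iii) have
an expression profile anticorrelated with the miRNA's own profile across
conditions. Each filter alone is weak — sequence-based prediction has a
high false-positive rate, and down-regulation alone is mostly the
transcriptional atrophy program — but their conjunction, intersected
across two co-induced miRNAs, yields a small high-confidence set.

## Models and statistics

**Normalization.** Two-channel spots are transformed to
M = log2(Cy5/Cy3), A = ½(log2 Cy5 + log2 Cy3); spots with a nonpositive
channel are masked, never errors. Within-array bias removal subtracts a
lowess fit of M on A (locally linear, tricube weights, 3 robustifying
iterations, span 0.3 — the span limma uses for within-array loess; the
package's bias-removal contract, median |M′| < 0.05 under a planted
0.5·sin(A) dye curve, is met at 0.3 and not at wider spans). Between-array
normalization defaults to median centering per array; a pseudo-array
variant (lowess of each array against the across-array median profile,
then centering) is available as `loess_pseudo` — a documented local
stand-in for published pseudo-array loess schemes, contracted on bias
removal rather than tool equivalence. Replicate spots are averaged
mask-aware; a feature is masked only when all its spots are.

**Permutation ANOVA.** Per feature, the classical one-way F statistic on
unmasked values; significance by permuting condition labels, p =
(1 + #{F* ≥ F})/(B + 1) with the same B permutations shared across
features in a call (B = 1000 by default; full enumeration replaces
sampling when the total number of label orderings is ≤ B). Features
lacking two groups with two observations are reported untested. No
multiple-testing correction is applied by default, matching the original
screen's raw α = 0.05; calls additionally require a linear fold change
outside [0.8, 1.2]. Degenerate separations (zero within-group variance)
give F = +∞ and participate in the permutation comparison by ≥.

**SAM-style two-class statistic.** d = (x̄₁ − x̄₂)/(s + s₀) with s the
pooled standard error and s₀ the median of per-feature s — a deliberate
simplification of the original fudge-factor search, stated as such. The
FDR at threshold Δ is the median over permutations of #{|d*| ≥ Δ} divided
by the observed #{|d| ≥ Δ}; a feature's q is the minimum FDR over
thresholds ≤ |d| (any such threshold still calls the feature), which also
makes q monotone in |d|. The down-regulated set used by the integration
defaults to the day-3 vs day-7/14 denervation contrast (q ≤ 0.1, d > 0),
matching the kinetics of the system: the transcriptional program peaks at
day 3, the miRNA response at day 7.

**Clustering.** Profiles with missingness are compared by the rescaled
pairwise-complete Euclidean distance d = √((m/m_obs)·Σ_obs (xᵢ−yᵢ)²);
dropping whole features instead would discard most of the matrix.
Complete-linkage agglomeration is delegated to scipy on the precomputed
distance matrix; items are sorted lexicographically by label first, so
minimum-distance ties break identically regardless of input order and
repeated runs give one topology. Branch lengths in the Newick export are
merge-height differences.

**Target scoring.** A site is a match of the reverse complement of the
seed (mature nucleotides 2–8) on the UTR sense strand only — 3′UTRs are
single-stranded, so no reverse-strand sites; coordinates are 0-based
half-open. Policies: exact 7mer (default), 7mer with one G:U wobble, 6mer.
Each site's ΔΔG = ΔG_duplex − ΔG_open, where ΔG_open follows the
accessibility-score sign convention (free energy of the unconstrained
ensemble minus the site-open ensemble, ≤ 0; backends return the
nonnegative opening cost and it is stored negated). The default duplex
model is a simplified stacking table (GC −3.0, AU −2.0, GU −1.0 per pair,
−2.0 per adjacent paired pair) and the default accessibility backend is
null — both deliberately simple, clearly labeled stand-ins: reproducing
published per-gene scores would require the original folding engine and
UTR build, so the published score table is consumed as a fixture and the
contract here is the scoring *structure*. Optional backends: a local
GC-content proxy and a ViennaRNA ensemble-opening backend (used only when
its bindings are importable). Per-gene aggregation is
ΔΔG_total = −ln Σᵢ exp(−ΔΔGᵢ) via a shifted log-sum-exp; a single site
reduces to its own score and additional sites strictly strengthen.

**Template matching.** The template is the miRNA's per-condition mean
profile standardized to zero mean and unit (population) variance. Each
candidate gene's per-condition mean profile is scored by Pearson r over
jointly observed conditions (≥ 3 required); significance is a one-sided
permutation test for anticorrelation (permute condition labels, add-one
p). A gene passes for a miRNA iff r ≤ r_max (default −0.8) and p ≤ 0.05 —
the threshold and the permutation choice are package decisions (the
original publication names the algorithm but not its cutoff), exposed in
config. Filtering is per miRNA independently; the shared set is the
intersection.

**Enrichment.** Exact hypergeometric upper tail P(X ≥ k) per term,
members intersected with the expression universe (default: all genes on
the platform), BH adjustment across tested terms, top-10 report. The
EASE-style modified score of web annotation tools is intentionally not
replicated, so published enrichment p-values are fixtures, not targets.

## The synthetic-data generator

`simulate_expression` emulates the study design: 8 conditions (control,
denervation days 3/7/14, starvation 24/48 h, streptozotocin diabetes, C26
cachexia) × 3 replicates; 400 miRNA probes and 2,000 mRNA probes (scaled
down from the ~13,400-probe platform) of log2(atrophy/control) values with
i.i.d. Gaussian noise (sd 0.25) on the log2 scale. Planted structure:

* **Focal miRNAs** (default miR-206- and miR-21-like, with their real
  mature sequences) up in late denervation (+1.5 at Den7, +1.0 at Den14 —
  response peaking at day 7), each with 30 targets of which 10 are shared;
  targets carry −1 log2 repression in every condition where their miRNA is
  up, additive when both miRNAs repress the same gene.
* **Condition signature blocks** (25 miRNAs each, |log2FC| 1.0): one block
  shared by Den7/Den14, one by STV24/STV48, a mostly-up STZ block, a
  mostly-down C26 block and a mild mostly-down Den3 block. The real study
  reports that each catabolic state has its own signature and that
  denervation time points group together, but no counts; these defaults
  were chosen once as realistic for a ~400-probe platform and are
  config-exposed.
* **A transcriptional atrophy program** among the mRNAs (200 genes, ±1
  log2 at Den3 decaying through Den7/Den14) reproducing the kinetic shift
  between transcript and miRNA regulation.

Detection: each spot's log2 abundance is a per-feature baseline
(N(8, 1.5)) plus the planted effect plus per-spot hybridization noise
(sd 1.0); spots below the detection limit (5.0) are masked
deterministically. The spot-level term matters: without it, missingness is
all-or-none per (gene, condition) and systematically erases the most
strongly repressed genes — the generator instead produces the sporadic
below-detection pattern arrays actually show. The effect-size default
(|log2FC| up to 1.5) straddles the 0.8/1.2 linear calling thresholds; no
effect-size distribution is claimed from the source study.

`simulate_utrs` writes a uniform-composition 3′UTR per gene (default
300 nt): planted targets receive exactly their requested number of exact
seed-complement sites (1–3) at recorded positions, and every other
position — and all non-target UTRs — is rejection-sampled to contain zero
seed matches for any planted miRNA, so prediction can be scored exactly
against ground truth.

**What the generator does not emulate:** dye-swap designs and spatial
artifacts; correlated noise between genes; partial seed sites and
3′-supplementary pairing in non-target UTRs; secondary structure of real
UTRs (relevant only to non-default accessibility backends). Passing
recovery tests therefore shows the pipeline's logic is sound under its own
assumptions, not that the simplified energy model ranks real sites as the
full folding model would.

## Numerical and design choices

* Permutation p-values use the add-one estimator (never 0); minimum
  attainable p is 1/(B+1).
* One top-level seed derives per-stage sub-seeds through a seed sequence,
  so stages can be rerun in isolation; identical config + seed gives
  byte-identical output files.
* Clustering tie-breaks: lexicographic label sort before agglomeration.
* The aggregation log-sum-exp is shifted, so a dominant site (e.g. −100
  among −1s) neither overflows nor loses precision.
* Masked values are never imputed anywhere; operations either skip them
  (means, distances, correlations) or mark the feature untested/untestable
  and say so in their outputs.
* Degenerate inputs: empty UTRs scan to empty site lists; an all-masked
  array or a zero-variance template is an error naming the offender; a
  fold change for an absent condition is an error; α = 0 yields all-
  unchanged calls and an empty (warned) integration result, not a crash.

## Known limitations

* The duplex/accessibility energies are structural stand-ins; absolute
  ΔΔG values are not comparable to scores from the original folding-based
  implementation (the packaged score table is used as a fixture, not
  reproduced).
* SAM's s₀ is the median-s simplification; q-values are permutation
  medians, slightly conservative for small permutation counts.
* Genes repressed below the detection limit in every replicate of the
  informative conditions are unrecoverable by design — the integration can
  only test what the array detected. At the default design this costs
  roughly one to three of ten shared targets depending on the draw.
* The between-array `loess_pseudo` method is contracted on bias removal,
  not equivalence to any published implementation.
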