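# Methods

This note documents the models implemented in `metphos`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Experimental design assumed

A panel of L cell lines (default 12, the colorectal-cancer lines
C2BBe1, COLO205, HT115, LoVo, MDST8, NCI-H747, RKO, SNU-61, SW48,
SW837, SW948, T84), each measured in four conditions — control at 0 h,
treated at 30 min, control at 24 h, treated at 24 h — with three
replicates, i.e. 144 phosphoproteomic MS runs. Differential
comparisons always use the time-matched control (30 min vs 0 h, 24 h vs
24 h) so that medium exhaustion over 24 h of culture is not attributed
to the drug.

## Preprocessing

**Two-report localization filter.** Site identities come from a strict
report (localization probability > 0.75 in at least one sample, the
class-I criterion; the comparison is strictly greater) while
quantities come from a loose report exported without a probability
cutoff, which carries more valid intensities for the same precursors.

**Representative precursor.** One precursor represents each unique
modified peptide: most valid values first, then the larger summed raw
intensity, then the lexicographically smallest precursor id. Valid
values are counted after the intensity floor, since the floor defines
what "quantified" means downstream.

**Floor and log2.** Raw intensities strictly below 500 become missing
(never zero, never imputed); the rest are log2 transformed.

**Normalization.** Cyclic LOESS against a median pseudo-reference: per
sample, the difference to the per-feature median is smoothed against
the average (an MA-regression) with span 0.7 and subtracted, for 2
iterations. This removes intensity-dependent distortions the way
MA-plot normalization does in microarray/proteomics practice. Samples
with fewer than 30 valid values fall back to median centering with a
warning. The exact LOESS variant and span are design choices of this
package; missingness patterns are never altered.

**Net phosphorylation (optional).** Per phosphopeptide, OLS of its
log2 values on the matched protein's log2 values; residuals are
phosphorylation not explained by protein abundance. Features with < 3
complete pairs, or a constant protein profile, are mean-centered and
flagged instead. Downstream analyses use the phospho layer directly by
default — in the motivating dataset protein abundance explained almost
none of the phospho variation, and the regression is opt-in
(`--use-residuals` semantics at the library level via
`regress_out_protein`).

## Differential statistics

**Plain t.** Pooled-variance two-sided Student *t* per feature, ≥ 2
valid values per group (below that the feature's call is *missing*).
Pooled rather than Welch: the procedure this mirrors is described as a
Student test, and with triplicates Welch's df estimate is too unstable
to be preferable. Calls use p < .01 and |log2FC| > log2(1.5); the
fold-change gate is symmetric on the log scale. BH correction is
applied across features within one line/comparison.

**Moderated t.** Empirical-Bayes variance shrinkage in the limma
style: the prior (d0, s0²) is estimated by method of moments on the log
sample variances (digamma/trigamma moment equations, trigamma inverted
by Newton iteration), each feature's variance becomes
s̃² = (d0·s0² + d·s²)/(d0 + d), and the moderated t is referred to a t
distribution with d + d0 df. When the observed spread of log variances
is no larger than expected under a single common variance, d0 = ∞ and
every feature uses s0². The plain-t calls feed the MetScore; the
moderated t-values feed kinase inference, where stabilized variances
matter more than hard calls.

**Loose fold changes.** For enrichment-style analyses a permissive
companion: replicate means per condition (≥ 1 value suffices),
difference of means as log2FC. More complete, less protected — never
used for significance calls.

## MetScore

Signed count of significant per-line calls over the panel, over the
complete matrix (a valid call in every line — sites missing anywhere
are excluded and counted in a report). Segments G1 = [4, 12],
G2 = [2, 3], G3 = [-1, 1], G4 = [-3, -2], G5 = [-12, -4] tile the
score range; printed interval orderings elsewhere are normalized to
ascending. The consensus signature is |score| ≥ 10, sorted by |score|
then key. The packaged 55-site reference signature table (43 up, 12
down) is used for bookkeeping tests; its G3 percentage in the source
material is internally inconsistent with its own count
(8344/14032 = 59.46%), so counts are authoritative here.

## Enrichment and sequence analyses

* **Fisher:** two-sided exact test on the 2×2 membership table, per
  term; both by-site counting (phosphorylation events) and by-protein
  counting (collapse to unique accessions first) are exposed, because
  multiply-phosphorylated proteins otherwise dominate.
* **1D rank enrichment:** two-sided Mann-Whitney U of member vs
  non-member values with rank-score effect
  2·(mean member rank − mean non-member rank)/n ∈ [−1, 1]; terms with
  fewer than 5 scored members are excluded.
* **Rank-shift set test:** two-sided Wilcoxon rank-sum for one set,
  reporting the median difference; pairwise application across groups
  with BH correction is provided for segment comparisons.
* **Positional residue enrichment (iceLogo-style):** per 15-window
  position × 20 residues, the foreground frequency is tested against
  the background proportion; normal approximation by default, exact
  binomial when the background has fewer than 30 windows; padding
  characters are excluded from denominators; cells with p < .05 are
  flagged enriched/depleted with the frequency difference as effect.
* **Motif extraction (motif-x-style):** S/T- and Y-centred windows are
  processed separately; greedily fix the (position, residue) pair with
  the smallest upper-tail binomial p given the current sets, require
  p < 1e−6 and ≥ 20 foreground occurrences, filter both sets to
  matching windows and recurse (depth ≤ 5); completed motifs remove
  their supporting windows, so supports are disjoint and re-running on
  the remainder reproduces the remaining motifs.

## Kinase activity

Raw score S = Σ sign·t/√n over a kinase's measured prior targets;
dephosphorylation edges contribute with inverted sign, so a
phosphatase's activity rises when its targets fall. The NES
standardizes S against a permutation null (the t-vector permuted over
all measured sites; permutations shared across kinases within a cell
line so NES values are comparable), with a two-sided permutation p
(+1 pseudocount). Kinases with fewer than 5 measured targets are
omitted. This is a deliberate reduction of regulon-weighted enrichment
(viper-style) to its testable core: the sign and ranking semantics are
preserved, and on null regulons the NES is approximately N(0, 1)
(asserted empirically). The reported activity matrix keeps kinases
significant (p < .05) in ≥ 1 line and estimated in all lines.

## Drug networking and connectivity

Per signature site the 50 smallest-p site~drug associations are kept
(ties broken by drug name), unioned into a bipartite network; drugs are
ranked by degree = number of distinct signature sites. The
connectivity score between a query signature and a reference profile is
the Spearman rank correlation over shared sites (≥ 5 required),
keeping the documented [−1, 1] semantics; the proprietary reference
algorithm it emulates is unspecified, and rank correlation is the
declared choice.

## Loewe synergy

Viability is normalized to the untreated-control mean and converted to
inhibition. Monotherapies are fitted with a 4PL curve (asymptotes
bounded to [0, 100], sign-free Hill slope; response ranges under 5
percentage points are flagged flat and summarized by their mean). The
Loewe-expected effect at (d1, d2) solves d1/D1(y) + d2/D2(y) = 1 by
bisection on the achievable effect range to 1e−6, clamping (flagged)
when no root exists; a flat partner contributes nothing. The synergy
surface is observed − expected per non-margin dose pair; the summary is
the exact (linearly interpolated) 75th percentile over the dose range,
and significance comes from a two-sided bootstrap over replicate wells
(default 1000 resamples, curves refitted per resample). Known
limitation: the 75th-percentile statistic is upward-biased under exact
additivity, so the bootstrap p is calibrated for effect detection, not
as a strict null test — on additive surfaces the summary stays within
±1 percentage point but can be flagged nominally significant.

## Consensus clustering

Features are first restricted to complete cases and the top 30% by
MAD. Monti-style resampling: per k in 2..6, 1000 resamples (tests use
100) draw 80% of the samples, hierarchically cluster
(1 − Pearson, average linkage) and cut at k; consensus = co-clustering
frequency among co-sampled pairs. The area under the consensus CDF
equals 1 − mean consensus; the cluster number is the largest k whose
relative area gain is ≥ 0.1 (the elbow rule — the literal "maximal
relative change" always selects the smallest k, since the first
increment is the entire area). Final assignments cluster 1 − consensus.

## Synthetic data

The generator emulates: the 12 × 4 × 3 run structure; Gaussian log2
intensities (baseline mean 16, sd 2 across sites; per-line offsets sd
0.5; replicate noise sd 0.25); planted 24-h effects — a consistent
signature block (default 8 up / 4 down at ±2 log2) plus a
heterogeneous background where each line regulates its own ~20% of
sites at 1–2.5 log2 units, mirroring a mostly line-specific response
with a small shared core; zero acute (30-min) effects by default;
logistic intensity-dependent dropout calibrated to 15% overall; 1–3
precursors per peptide with decreasing intensity; localization
probabilities from a Beta mixture with ~10% poorly localized peptides.
All randomness flows from one seed through NumPy's PCG64 generator, so
runs are bit-reproducible.

It does **not** emulate: mass-spectrometer physics, retention times,
interference, realistic peptide sequences (motif tests use dedicated
window generators), correlated missingness across precursors of one
peptide, batch structure, or heavy-tailed noise. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under idealized panel-structured data — not robustness
to every artefact of real DIA data.

Problem sizes in the shipped tests (hundreds of sites, hundreds of
permutations/resamples) are scaled-down stand-ins chosen so the whole
suite runs in minutes while keeping every distributional check
well-powered; defaults in the library (5000 sites, 1000 permutations,
1000 resamples, 1000 bootstraps) reflect desk-scale analysis practice.

## Degenerate inputs and tie-breaks

Zero-variance t-tests return t = 0, p = 1 when means agree and ±∞ with
a vanishing p otherwise; BH is applied only over tested features;
representative-precursor and top-n association ties break
lexicographically; segment bins must tile the score range exactly or
are rejected; consensus matrices are symmetrized with unit diagonal by
construction.
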