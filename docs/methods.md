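# Methods

## The measurement model

A dual-barcode expression reporter couples two RNAs on one integrated
construct. The oBC is transcribed by Pol III and stabilized by circularization,
so it accumulates to thousands of copies per cell regardless of cell type; its
capture in a single-cell library is therefore close to deterministic and its
UMI count per (cell, barcode) is strongly bimodal. The high mode (~10²–10³·⁵
UMIs) marks bona fide integrations; the low mode (1–10 UMIs) consists of
chimeric amplicons — PCR products that attached a barcode to the wrong cell's
primer. The mBC sits in the 3′ UTR of the Pol II reporter mRNA and is captured
like any transcript, at counts proportional to CRE-driven expression and to the
cell's overall library depth.

Quantification is *detection-conditioned*: an mBC count contributes only in
cells where the matched oBC passes the detection threshold, and a detected oBC
with no captured mBC contributes an exact zero. Per-cell expression is
normalized by transcriptome depth,

    norm_expr = mBC_UMI / GEx_UMI × mean(GEx_UMI),

where the rescaling by the mean keeps the unit interpretable as "UMIs per
cell at average depth".

## Counting stage

Reads are validated against the exact flanking constant region (mBC:
`TCGACAA` immediately after the 15 nt barcode; oBC: `GCTTTAA` after the 16 nt
barcode) and all-G "empty" barcodes are discarded. Within each (cell, UMI),
target barcodes receiving a read fraction strictly below 0.2 are treated as
chimeric re-assignments and dropped (a tie at exactly 0.2 is kept). The
error-corrected molecule count per (cell, barcode) is the number of connected
components of the graph linking distinct UMIs at Hamming distance ≤ 1. The
production implementation indexes UMIs by their single-position wildcard masks
(O(n·L) instead of all-pairs); an all-pairs BFS oracle is kept in the test
suite and checked for exact agreement on randomized instances. `N` bases count
as mismatches against every base, including another `N`. The chimera filter
runs before collapse; the order is configurable for sensitivity analysis.

## Detection and thresholding

The default detection rule is umi_count ≥ 12, sitting in the valley of the
bimodal oBC distribution. `estimate_threshold` automates the choice: a
Gaussian KDE of log10 counts (bandwidth 0.25, wide enough to smooth the
integer teeth of the low mode) is scanned for its two dominant modes and the
threshold is placed at the density minimum between them (middle of the plateau
when the minimum is flat); unimodal inputs fall back to the default with a
warning.

## Clonotypes and quality metrics

Cells from one transfected clone share an integration set, giving internal
replicates. Cells are linked when the Jaccard similarity of their detected oBC
sets is ≥ 0.6; connected components with ≥ 2 cells become clones; the
consensus is the set of oBCs detected in > 50% of member cells; every cell is
then re-assigned to its best-matching consensus, with assignment scores < 0.3
flagged unassignable (doublet-like). The published experiments cite external
clone-calling software without formulas, so this scheme is a reconstruction
validated purely by simulation recovery (adjusted Rand index ≥ 0.95 at 100
clones / 2,000 cells / MOI 5 under the default noise channels).

Precision–recall treats consensus sets as ground truth: at each count
threshold, detected consensus oBCs are true positives and detected
non-consensus oBCs false positives, tallied per (cell, oBC) over clones with
more than two cells. The dropout (1 − recall) at the threshold achieving
FDR ≤ 1% is the headline capture metric; on simulations with 2% injected
capture dropout it is recovered within ±1 percentage point.

The per-integration capture rate is estimated from detected counts with a
zero-truncated Poisson mean inversion, m = λ/(1 − e^(−λ)), solved by
safeguarded Newton iteration to |f| < 1e-10. At λ = 1 and n = 10⁴ the
estimator's sampling SE is ≈ 1.2% of λ, so recovery checks use the median
over several draws.

Per-(clone, reporter) precision is summarized as CV = sd/mean across member
cells with the Poisson floor 1/√mean alongside (the floor is what a pure
counting measurement would give). Positional effects are quantified per
reporter by a one-way random-effects decomposition over clones
(method-of-moments: σ²_between = max(0, (MSB − MSW)/n₀)), reported as the
between-clone share of total variance.

## CRE statistics

The resampling unit is the *integration event* — one detected reporter
occurrence with its normalized expression and cluster label, true zeros
included.

**Activity.** For each CRE, B = 10⁴ bootstrap resamples of its events are
compared with equally sized resamples from the pooled basal-promoter events
(minimal + no promoter; equal size controls for representation differences).
The statistic is the maximum per-cluster mean over eligible clusters (≥ 5
events by default, so single-event clusters cannot win the max); an
unstratified all-cells mean is computed in parallel (more power, no cell-type
resolution). The empirical p-value is P(CRE statistic < basal statistic) over
all bootstrap pairs, ties counted ½ — a rank-sum-style comparison under which
degenerate all-zero contrasts give p = 0.5, never significant. CRE and basal
draws are independent. The bootstrap is implemented as multinomial event
weights (identical in law to index resampling, vectorizable in B) and p-values
use sorted-search counting over the B × B pairs; both are exact, not
approximations. p-values of 0 should be read as < 1/B.

**Specificity.** The observed statistic is the fold change between the
maximum-expression eligible cluster and all remaining events of a bootstrap
resample; the null applies the same computation to an independent resample
with cluster labels permuted. p = P(null ≥ observed) over all pairs, ties
counted toward the null (conservative). A fold change of +∞ (zero expression
outside the winning cluster) is an explicit sentinel that exceeds any finite
threshold. The denominator uses reporter-carrying cells only; a mode using
all profiled cells is available.

**Pleiotropy.** The same machinery on all pairs of clusters versus the rest;
the pleiotropy ratio compares the median best-pair fold change to the median
single-cluster fold change, with a permutation p-value for the pair statistic.

**Calling.** Per replicate, Benjamini–Hochberg correction is applied across
CREs separately for the activity and specificity families. A CRE is *active*
when max-cluster FDR < 10% in every replicate or all-cells FDR < 1% in every
replicate; *cell_type_specific* when additionally fold change > 5 and
permutation FDR < 10% in every replicate; *pleiotropic_specific* when the
pair/single ratio further exceeds 3× with full permutation support. Reported
activity and specificity are medians across replicates. Whether the original
procedure drew one shared basal resample per iteration or independent draws is
not documented; independent draws are used here (both arms are exposed).

## Bulk MPRA

Per-mBC UMI counts (restricted to the a priori reporter pool, Hamming-1
collapsed) are normalized to sum to one within each library; expression is
norm_RNA / norm_DNA, quantified only where DNA UMIs ≥ 100. CRE-level
expression is the median over quantified member mBCs — robust to a single
chimeric mBC; the original analyses report per-mBC values and state no
CRE-level rule. Time courses with ≥ 3 points are classified
increasing/decreasing by a Mann–Kendall sign statistic at α = 0.05 (a strict
full-trend pattern is accepted below threshold at very small n),
nonmonotonic when the trajectory splits at an interior extremum into two
strictly opposing monotone limbs, and flat otherwise (including ranges below
5% of scale). The classification procedure is this package's own
formalization.

## Subassembly

oBC–mBC pairs are valid at > 500 reads, with any barcode appearing in more
than one surviving pair removed as conflicted. oBC–CRE alignment summaries
are filtered in order: expected strand; median mapping position within
[30, 300] bp; > 95% of the oBC's reads on a single CRE; > 30 reads;
positional dispersal (p90 − p10, linear interpolation) within [30, 300] bp.
Diagnostics partition dropped pairs by first failing filter. Positions are
1-based read starts within the CRE; the expected strand is a per-CRE input
(cloning orientation metadata). The final map joins the two subassemblies on
oBC and drops any triplet whose oBC or mBC occurs twice, so the published
uniqueness invariants hold by construction.

## The simulator

`scqer.sim` generates every pipeline input with known truth:

* **Library**: `n_cre × pairs_per_cre` triplets with pairwise-distinct 16 nt
  oBCs and 15 nt mBCs (rejection sampling; explicit failure when the sequence
  space is too small).
* **Clones**: integrations per clone ~ zero-truncated Poisson(`moi_mean`),
  drawn without replacement from the library; per-integration positional
  multiplier ~ log-normal(0, `positional_sd_log`). Within-clone duplicate
  triplets are not modeled — at the study regimes the per-cell duplicate
  probability is ≤ a few percent (computed exactly in `scqer.design`).
* **Cells**: clone and cluster assignments independent (clones span cell
  types); transcriptome depth log-normal around `gex_mean`; per integration,
  oBC UMIs ~ Poisson(`obc_capture_mean`, default 2,500, optionally zeroed at
  `obc_dropout_rate`) and mBC UMIs ~ Poisson(activity × multiplier × relative
  depth).
* **Chimeras**: each barcode absent from a cell fires independently at the
  configured per-cell rate (default 0.01), with zero-truncated Poisson(1)
  UMIs — reproducing the rising sub-10-UMI low mode. The defaults give > 30×
  separation between modes and chimeric mBC detection rates of tens of
  percent, the regime where detection conditioning matters. The biochemical
  mechanism of chimera formation is not modeled; this channel is
  phenomenological.
* **Reads**: each molecule's UMI is drawn from a distance-2 parity code
  (last base = mod-4 checksum), so distinct molecules never sit at Hamming
  distance 1 and only sequencing errors create mergeable neighbors; reads per
  UMI ~ geometric (mean `reads_per_umi_mean`, the "saturated library" skew);
  a configurable fraction of reads is re-emitted under a wrong barcode with
  the same (cell, UMI) (read-level chimeras); UMI substitution errors are
  applied per read at `umi_error_rate` per base. A sidecar table flags every
  emitted molecule real/chimeric with its pre-error UMI.
* **Bulk**: DNA UMIs multinomial over integration copy number, RNA UMIs over
  copy × multiplier × population-averaged activity, at requested depths.

`simulate_counts` is a faster entry point that emits error-corrected count
tables directly (what a noiseless counting stage would return), used for
statistics-level experiments where read-level channels are off.

Fixing `SimConfig.seed` fixes all outputs bit-exactly; the CLI's `run`
command hashes the configuration into the run directory name and reproduces
outputs byte-identically.

**What the simulator does not emulate.** Real transcriptomes (depths and
cluster labels are inputs in practice), 10x chemistry (cell-barcode
whitelists, base transformations), doublets, ambient RNA, cluster-correlated
capture efficiency, amplification jackpotting beyond the geometric read model,
and any sequence-composition effects. Passing tests therefore demonstrate the
pipeline's correctness under the stated statistical structure, not robustness
to every artifact of real libraries.

## Problem sizes in tests and validation

Validation experiments run the simulator at reduced scale so the full suite
completes in minutes on one CPU: hundreds to 2,000 cells, 10–22 CREs with
6–20 barcode pairs each, oBC capture means of 50–300 UMIs (keeping the > 30×
mode separation), MOI 4–5 with 100 clones, and B = 2,000 resamples for the
calibration screens (the per-test default remains B = 10⁴). The spiked-screen
calibration repeats 10 independent simulations of 3 replicates each. Library
construction is additionally exercised once at full screen scale
(204 × 145 = 29,580 triplets).

## Known limitations

* Clonotype inference is a reconstruction; with very low MOI (1–2) the
  Jaccard graph fragments, and clones sharing most integrations can merge.
* The specificity denominator choice (carrier cells vs all cells) changes
  fold changes when carriage is cell-type-biased; both modes are exposed.
* The valley-based threshold estimator assumes a genuinely bimodal count
  distribution; shallow low modes fall back to the fixed default.
* Empirical p-values are bounded below by 1/B; the B × B pairing sharpens
  granularity but cannot create resolution beyond the resample count.
* The bulk time-series classifier is rank-based and unreplicated per time
  point; subtle nonmonotonic trajectories at ≤ 4 points classify as flat.
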