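# scqer

Deconvolution and quantification of **dual-barcode single-cell expression
reporters** — a massively parallel reporter assay (MPRA) read out in single
cells.

## The problem

Classical MPRAs quantify cis-regulatory element (CRE) activity as bulk RNA/DNA
barcode ratios and therefore average over cell types. Single-cell readouts of
reporter mRNAs alone are defeated by two artifacts: *dropout* (a reporter
present in a cell but not captured) and *chimeric amplicons* (PCR products
that swap barcodes between molecules, attaching counts to the wrong cell).

Dual-RNA reporters solve both with two barcodes per construct:

* an **oBC** ("detection" barcode) — a Pol III-driven, circularized RNA
  expressed at ~2,500 UMIs per cell per integration, making the presence of an
  integrated reporter nearly deterministic to detect;
* an **mBC** ("quantification" barcode) in the 3′ UTR of the Pol II reporter
  mRNA, whose UMI count measures CRE-driven expression.

An a priori subassembled **triplet map** (oBC ↔ CRE ↔ mBC) links the two: an
mBC count is trusted only in cells where its matched oBC is detected, and a
detected oBC with zero mBC UMIs is a *true zero* of expression. The per-cell
expression unit is the transcriptome-normalized count

```
norm_expr = mBC_UMI / GEx_UMI × mean(GEx_UMI)
```

This package implements the full computational side of such an experiment:

| module | what it does |
|---|---|
| `scqer.sim` | generative simulator with known ground truth (clonal integrations, bimodal oBC counts, chimeras, UMI errors, bulk libraries) |
| `scqer.counts` | read validation, chimeric-UMI filtering (read fraction < 0.2), Hamming-distance-1 UMI collapse |
| `scqer.quant` | integration detection (≥12 UMI), detection-conditioned quantification with true zeros, bulk comparison |
| `scqer.clones` | clonotype inference from oBC co-detection, precision–recall (dropout/FDR), zero-truncated Poisson capture estimate, clonal CV, positional variance split |
| `scqer.stats` | 10⁴-bootstrap activity tests vs basal promoters, cluster-permutation specificity tests, pair-cluster pleiotropy tests, BH FDR, multi-replicate CRE classification |
| `scqer.bulk` | bulk MPRA UMI counting and normalized RNA/DNA expression, time-series classification |
| `scqer.subassembly` | oBC–mBC pair calling, oBC–CRE alignment filtering, conflict-free triplet map |
| `scqer.design` | closed-form duplicate-integration (birthday) probabilities |

A `scqer` command-line interface exposes each stage (`sim`, `count`,
`quantify`, `clones`, `stats`, `bulk`, `subasm`) plus `run` for an end-to-end
reproducible pipeline.

## Worked example

Simulate a small screen (one cell-type-specific CRE, one constitutive, two
basal controls), process it end to end, and classify the CREs:

```python
import numpy as np
from scqer import sim, counts, quant, stats

cfg = sim.SimConfig(
    n_cre=4, pairs_per_cre=6, n_clusters=3, moi_mean=4, n_clones=25,
    obc_capture_mean=50, chimera_rate_obc=0.02, chimera_rate_mbc=0.02,
    umi_error_rate=0.005,
    activity_matrix=np.array(
        [[8.0, 0.3, 0.3],      # specific to cluster 0
         [2.0, 2.0, 2.0],      # constitutive
         [0.2, 0.2, 0.2],      # basal control
         [0.2, 0.2, 0.2]]),    # basal control
    seed=3,
)
triplets = sim.build_library(cfg)
truth = sim.simulate_population(triplets, cfg)
data = sim.simulate_cells(truth, 250, cfg)

obc, _ = counts.process_reads(data["obc_reads"], "obc")
mbc, _ = counts.process_reads(data["mbc_reads"], "mbc")
det = quant.detect_integrations(obc, threshold=12)
expr, qc = quant.quantify_reporters(det, mbc, triplets, data["cells"])
print(quant.summarize_cre(expr)[["cre_id", "activity", "specificity"]])

res = stats.run_replicate(expr, ["cre_002", "cre_003"], B=2000, seed=7)
print(stats.call_cres([res])[["cre_id", "class"]])
```

Output:

```
    cre_id  activity  specificity
0  cre_000  9.502864    34.433047
1  cre_001  2.353852     1.137593
2  cre_002  0.316737     1.374236
3  cre_003  0.280941     1.154511

    cre_id               class
0  cre_000  cell_type_specific
1  cre_001  active_nonspecific
```

The specific CRE is recovered with activity ≈ 9.5 normalized UMIs per cell and
~34-fold enrichment in its cognate cluster; the constitutive CRE is active but
nonspecific; the basal controls are left uncalled. In this run
`qc["chimeric_detection_rate"]` is 0.209 — about a fifth of mBC detection
events would have been spurious without oBC conditioning.

The same pipeline is available from the shell:

```bash
scqer run --config run.yaml --seed 3   # sim → counts → quantify → clones → stats → bulk
```

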