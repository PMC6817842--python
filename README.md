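# cardioreg

Analysis toolkit for multi-transcription-factor chromatin occupancy and
cardiac enhancer identification. It re-implements, as a tested and reusable
library, the computational pipeline of a cardiac bioChIP-seq study design:
seven cardiac transcription factors (GATA4, MEF2A, MEF2C, NKX2-5, SRF,
TBX5, TEAD1) are profiled in fetal and adult heart, and their co-occupancy
is related to tissue-selective H3K27ac, composite DNA-motif grammar,
gene expression, and in-vivo reporter (MPRA) enhancer activity.

**Who it is for:** computational biologists who have per-TF peak/summit
calls (narrowPeak), signal tracks (bedGraph), gene models and expression
tables, and want the downstream co-occupancy / enhancer analyses without
re-deriving the bespoke statistics. Every stage also runs end-to-end on
built-in synthetic data with planted, recoverable structure.

## What it computes

- **Co-bound regions** — pooled TF summits are merged by single-linkage at
  distance *d* (default 300 bp, where the inter-summit distance histogram
  separates its clustered mode from the dispersed ~10 kb background). A
  panel of *n* TFs admits 2^n membership patterns (128 for 7 TFs, 64
  for 6).
- **Cardiac H3K27ac score** — per region,
  CHS = heart / max(liver, forebrain) on RPM-normalized signal (with a
  0.5 RPM pseudocount); regions in the top two CHS quintiles are cardiac
  H3K27ac regions (cHRs).
- **Composite motifs** — two PWMs joined in all 4 strand orientations with
  0–8 uniform spacer bases (36 arrangements); arrangement preference of a
  TF pair is the dispersion, variance²/mean, of per-arrangement enrichment.
- **Permutation enrichment** — observed overlap of query regions with gene
  TSS ± d windows versus randomized placements in the mappable genome
  (mappability < 0.3 runs longer than 500 bp excluded), with add-one
  permutation p-values.
- **Gene annotation** — each gene is labeled by the region within
  TSS ± 100 kb carrying the most distinct TFs, plus an H3K27ac
  present/absent flag; DEGs are selected by strict |log2FC| > 2 and
  −log10 p > 3.
- **MPRA activity** — RNA RPM / DNA RPM per element (fragments filtered to
  395–405 bp, DNA floor 5 RPM); elements above the 95th percentile of the
  ESC negative-control activities are called active (5% empirical FDR).
- **Enhancer-feature evaluation** — recall/precision, threshold-swept ROC
  and midrank AUC for chromatin features as enhancer predictors, plus
  min–max feature export for external classifiers.

## Worked example

```python
import numpy as np
from cardioreg.simulate import SimConfig, make_tf_summits, make_h3k27ac_tracks
from cardioreg.cooccupancy import (merge_cobound, inter_summit_distances,
                                   enumerate_patterns)
from cardioreg.chs import chs_score, quintile_classify

cfg = SimConfig(seed=1)                      # 2 x 10 Mb genome, 7 TFs
peaks, truth = make_tf_summits(cfg)          # planted co-bound clusters
regions = merge_cobound(peaks, d=300)        # single-linkage summit merge

n_patterns, _ = enumerate_patterns(list(cfg.tf_panel))
pooled = [p for v in peaks.values() for p in v]
dist = inter_summit_distances(pooled)
multi = sum(r.n_tf >= 2 for r in regions)
print(f"{len(pooled)} summits -> {len(regions)} co-bound regions "
      f"({multi} with >= 2 TFs; {n_patterns} possible patterns)")
print(f"median inter-summit distance: {np.median(dist):.0f} bp")

tracks, h3k_regions, h3k_truth = make_h3k27ac_tracks(cfg)
scored = quintile_classify(chs_score(
    h3k_regions, tracks["heart"], tracks["liver"], tracks["forebrain"]))
sens = np.mean([c.is_chr for c, s in
                zip(scored, h3k_truth["heart_specific"]) if s])
print(f"{sum(c.is_chr for c in scored)} / {len(scored)} regions called "
      f"cardiac H3K27ac regions (cHRs); "
      f"planted heart-specific recovery: {sens:.2f}")
```

Output:

```
5600 summits -> 2291 co-bound regions (1198 with >= 2 TFs; 128 possible patterns)
median inter-summit distance: 120 bp
200 / 500 regions called cardiac H3K27ac regions (cHRs); planted heart-specific recovery: 1.00
```

5,600 pooled summits collapse to 2,291 regions because 80% of summits were
planted in multi-TF clusters; the 120 bp median distance reflects the
clustered regime. The cHR call takes exactly the top two quintiles
(200 of 500), and every planted heart-specific region lands there.

A CLI mirrors the library (`cardioreg cobind | chs | motifs | enrich |
genes | mpra | eval | simulate`); see `cardioreg --help`.

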