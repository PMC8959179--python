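# mapscall

Target calling for bacterial small regulatory RNAs from **MAPS**
experiments (MS2-affinity purification coupled with RNA sequencing),
with downstream regulon statistics and per-gene evidence integration.

In a MAPS experiment an sRNA is tagged with the MS2 aptamer, pulled down
via the MS2 coat protein, and the co-purified RNAs are sequenced. Direct
targets reveal themselves as transcripts whose coverage is enriched in
the pull-down (MS) library relative to an untagged control. `mapscall`
implements that inference for bacterial genomes:

* **Region model.** Each gene gets three scored regions: a 5′UTR
  (anchored at an experimentally determined TSS when one at least
  100 nt upstream is known, otherwise the 100 nt immediately upstream of
  the start codon), the annotated gene body, and a fixed 3′ window of
  250 nt running from 50 nt inside the annotated 3′ end to 200 nt
  downstream. ncRNA features are treated exactly like CDS.
* **Stranded coverage.** Paired-end alignments are split by SAM flag
  (99/147 → forward orientation class, 83/163 → reverse, everything
  else excluded), binned at 1 nt, and each region is scored by summing
  coverage in its expected transcript orientation. Region sums are
  RPM-scaled: `rpm = raw_sum × 10⁶ / library_total`.
* **Candidate calling.** A region is called when
  `log2((ms_rpm + pc) / (control_rpm + pc)) ≥ 2` — a 4-fold linear
  increase — **and** its MS RPM exceeds the lower-quartile floor
  (nearest-rank 25th percentile of all MS region RPM values), which
  suppresses ratio artifacts at negligible coverage. A gene is a
  candidate if any of its three regions is called.
* **Motif and TF-box statistics.** Presence of a seed motif (default
  `GGGG`, the reverse complement of a C-rich sRNA loop) in candidate
  5′UTRs is compared against randomly sampled background UTRs; genomes
  are scanned with a position weight matrix at 70% of its maximum score,
  sites within 250 nt upstream of an ATG are assigned to the closest
  gene; both analyses are tested with the one-sided upper-tail exact
  binomial test, `P(X ≥ k), X ~ Bin(n, p0)`, with `p0` the background
  fraction.
* **Integration.** DEGs are selected from an externally produced
  differential-expression table at adjusted `p < 0.01` (no fold-change
  filter by default), ChIP coverage is averaged over the promoter window
  `[ATG−200, ATG+50)`, and everything is fused into one row per gene
  (DEG status/direction, pull-down calls, TF boxes, upstream motif
  counts, ChIP means, essentiality/cell-cycle/methylation/COG side
  annotations).
* **Synthetic studies.** `mapscall.simulate` generates a complete study
  with known ground truth — genome, annotation, TSS table, stranded
  Poisson coverage libraries with planted fold-enrichment, planted
  motifs and TF boxes, DE table, side tables — so every stage is
  verifiable without any sequencing data.

## Worked example

```python
from mapscall import SimulationConfig, simulate_dataset, MapsCallerConfig, call_candidates
from mapscall.coverage import compute_region_coverages
from mapscall.simulate import simulate_library
from mapscall.motif import MotifQuery, motif_enrichment, sample_background_utrs
from mapscall.regions import RegionKind, region_sequence

ds = simulate_dataset(SimulationConfig(seed=1))          # 150 genes, 12 planted targets
ms = compute_region_coverages(ds.region_set, simulate_library(ds, "ms"))
ctrl = compute_region_coverages(ds.region_set, simulate_library(ds, "control"))
calls, genes = call_candidates(ms, ctrl, MapsCallerConfig())
print(f"{len(genes)} candidate genes of {len(ds.annotations)}")

top = max(calls, key=lambda c: c.log2_ratio)
print(f"top region: {top.gene_id}/{top.region.kind.value} "
      f"ms_rpm={top.ms_rpm:.1f} control_rpm={top.control_rpm:.1f} log2={top.log2_ratio:.2f}")

fg = [region_sequence(ds.region_set.get(g, RegionKind.UTR5), ds.genome) for g in sorted(genes)]
bg = sample_background_utrs(ds.region_set, ds.genome, 150, seed=1)
res = motif_enrichment(fg, bg, MotifQuery())
print(f"GGGG in 5'UTRs: {res.k}/{res.n} vs background p0={res.p0:.3f}, p={res.p_value:.2e}")
```

prints

```
12 candidate genes of 150
top region: gene107/UTR5 ms_rpm=3998.1 control_rpm=511.2 log2=2.96
GGGG in 5'UTRs: 6/12 vs background p0=0.100, p=5.41e-04
```

All 12 planted targets are recovered (the caller's 4-fold boundary sits
well below the planted 8-fold enrichment), and the planted motif excess
in candidate 5′UTRs (6 of 12 versus a 10% background) is highly
significant under the exact binomial test.

The same pipeline runs from the shell on real or simulated files:

```sh
mapscall simulate --seed 1 --outdir study/
mapscall all --config config.yaml     # regions -> call -> motif -> pwm -> integrate
```

Stage outputs are deterministic, sorted TSVs; `manifest.json` records
the configuration hash and output checksums.

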