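# zfdelta

Tools for asking, on two matched conditions (a wild-type and a point-mutant
of a zinc-finger DNA-binding protein), *which binding sites are lost, what
sequence feature marks them, and what happens to the surrounding 3D genome*.

The package was built around the biology of CTCF, the 11-zinc-finger
organizer of chromatin loops and TAD boundaries.  CTCF reads a ~19-bp core
consensus with its central zinc fingers, while fingers 9–11 engage a second,
peripheral **upstream (U) motif** within ~20 bp 5′ of the core.  A mutation
in ZF11 (such as R567W) is expected to weaken binding selectively at sites
that carry a U motif, and to reorganize TADs and enhancer–promoter contacts
locally.  `zfdelta` implements the complete quantitative chain needed to
test that picture, plus a seeded synthetic-data generator whose planted
ground truth makes every step verifiable.

## What it computes

1. **Spike-in normalized differential binding** (`zfdelta.chip_quant`).
   With an equal amount of exogenous chromatin added to every ChIP, sample
   *s* gets the scale factor

   ```
   factor(s) = summit(reference spike profile) / summit(spike profile of s)
   ```

   applied after RPGC (reads-per-genome-coverage) normalization; the
   reference factor is 1.  Per-site strength is the scaled coverage at the
   reference summit, and sites are ranked by
   `log2FC = log2((strength_ref + ε) / (strength_alt + ε))`, split into
   four equal-count groups (group 4 = strongest loss) and flagged
   *downregulated* when `log2FC > 1`.

2. **Upstream-motif subclustering** (`zfdelta.motif_u`).  The core motif is
   located in each peak by a PWM scan with *exact* p-values (dynamic
   program over integer-discretized log-odds scores; threshold 1e-4); the
   20 bp 5′ of the core on the match strand is extracted, clustered by
   Hamming distance (k-medoids, k = 10), and clusters with a run of ≥ 6
   informative positions are labeled U motifs — U1 when similar to the
   canonical U model, U2…Un otherwise.  Per-fold-change-group U
   percentages quantify the selective-loss signature.

3. **TAD-change taxonomy** (`zfdelta.insulation_tads`).  Contact matrices
   are masked (zero plus lowest-5% coverage bins), balanced to uniform row
   sums (Knight–Ruiz-style symmetric scaling), and scored with a 400-kb
   sliding-square insulation profile at 50-kb bins.  Boundaries are
   insulation minima with drop ≥ 0.7; the region between two nearby
   boundaries is a TAD.  Comparing conditions, each region between shared
   boundaries is classed **stable**, **fusion** (boundary lost),
   **separation** (gained) or **confusion** (both).

4. **4C viewpoint interaction change** (`zfdelta.viewpoint_4c`).
   Fragment counts around a viewpoint are normalized to reads-per-million
   (viewpoint ± 2 fragments excluded), smoothed by a running mean, and
   enhancer–promoter change is reported as the alt/ref signal ratio per
   target.

5. **Synthetic ground truth** (`zfdelta.simgen`).  Seeded genomes with
   planted core/U motifs, two-condition coverage with a configurable
   occupancy loss δ restricted to U sites, a condition-invariant spike-in
   contig, contact maps whose boundary sets differ by explicit edits, and
   decaying 4C profiles with planted interaction loss.  The truth registry
   is the oracle for every recovery test.

## Worked example

```python
from zfdelta.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=11, outdir="run11"))
print(round(report.scale_factor, 3))
print(report.u_table.to_string(index=False))
print(report.tad_agreement)
```

prints (seed 11):

```
0.888
        group  n_sites  n_u  percent_u  percent_u1
            1      100    2   2.000000    0.000000
            2      100    3   3.000000    1.000000
            3      100   22  22.000000   12.000000
            4      100   88  88.000000   48.000000
downregulated      122  102  83.606557   45.901639
100.0
```

Reading this: the mutant track needed a spike-in scale factor of 0.888;
of the 400 planted sites, the 100 with the strongest binding loss
(group 4) are 88% U-motif-positive versus 2% in the stable group 1 — the
selective-loss signature the pipeline is designed to detect — and all
planted TAD boundary edits were classified correctly (100% agreement).
The same stages are available from the shell:

```bash
zfdelta simulate --seed 11 --outdir data/
zfdelta chip-quant --ref data/coverage_ref.bedgraph --alt data/coverage_alt.bedgraph \
    --peaks data/peaks.bed --spike-peaks data/spike_peaks.bed --egs 400000 --out out/
zfdelta run-all --seed 11 --outdir run11/
```

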