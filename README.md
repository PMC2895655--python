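# coregmap

Combinatorial transcription-factor occupancy rarely maps onto a single
regulatory outcome: two factors bound to the same enhancer can act
additively, cooperatively, or antagonistically depending on the element.
`coregmap` is a tested, reusable pipeline for the analysis that
establishes this, built for the two-factor ChIP-on-chip + mutant
expression-profiling study design used in *Drosophila* myogenesis (a
tissue-specific zinc-finger factor modulating a MADS-box activator):

1. **ChIP enrichment calling** on replicated two-colour tiling arrays by
   the rank-product statistic. Fragment *i* with descending enrichment
   ranks r<sub>i1</sub>…r<sub>ik</sub> across *k* replicate IPs scores
   RP<sub>i</sub> = (∏<sub>j</sub> r<sub>ij</sub>)<sup>1/k</sup>, with a
   permutation FDR from independently shuffled rank vectors. Binding
   calls (FDR < 2 %, fold > 1.5) must agree between two independent
   antibodies, and significant fragments merge into unique bound regions
   whose two-factor co-occupancy is measured at the interval level.
2. **Differential expression** across a six-timepoint mutant-vs-wild-type
   timecourse: print-tip loess normalisation, then a one-class SAM
   statistic d = m̄/(se + s₀) with sign-flip permutation q-values
   (q < 1 %, fold > 1.6).
3. **Direct-target integration**: a gene is a high-confidence direct
   target iff it has an assigned bound region AND is differentially
   expressed in the matching mutant AND carries the tissue annotation.
   Target-set overlap between factors is scored by a one-sided
   hypergeometric (Fisher exact) test; dual-mutant response profiles are
   grouped by k-means.
4. **Co-regulation logic** from dual-luciferase titrations: with
   single-factor fold changes f_A and f_B, the baseline-corrected
   additive expectation is E_add = f_A + f_B − 1. An enhancer is
   *cooperative* if f_AB significantly exceeds E_add, *repressive* if an
   inactive factor significantly and dose-dependently pulls the combined
   activity below the active factor's, and *additive* otherwise
   (unpaired two-tailed t-tests on log activities; stars at
   p < 0.05/0.01/0.001).

Because the original microarray data are not bundled, a first-class
synthetic-data module generates every input with planted ground truth
matching the study design — 2 timepoints × 2 antibodies × 4 IP
replicates + 4 mocks on overlapping 3 kb tiles; 6 one-hour timepoints ×
4 replicate hybridisations; 1/10 ng reporter titrations — so every stage
is benchmarked by parameter recovery and null calibration.

## Worked example

```python
from coregmap import (
    SimulationConfig, PipelineConfig, simulate_all,
    write_fixture_bundle, run_pipeline,
)

config = SimulationConfig(
    genome_length=500_000, n_genes=250, n_bound_A=12, n_bound_B=12,
    n_offtarget_per_antibody=4, n_enhancers=9, seed=7,
)
write_fixture_bundle(simulate_all(config), "demo/fixtures")
report = run_pipeline(
    PipelineConfig(fixture_dir="demo/fixtures", out_dir="demo/run", seed=7)
)
```

The report (also written to `demo/run/report.json`) prints:

```json
{
 "n_fragments": 332,
 "bound_counts": {"A": 12, "B": 12},
 "venn": {"A_only": 4, "B_only": 4, "cobound": 8},
 "pct_A_cobound": 66.7,
 "n_targets": {"A": 12, "B": 12},
 "target_overlap": 8,
 "target_overlap_pct": 66.7,
 "fisher_p": 6.831165217010574e-10,
 "n_downstream": {"A_mut": 64, "B_mut": 42},
 "cluster_sizes": {"0": 9, "1": 3, "2": 3, "3": 1},
 "mode_tally": {"cooperative": 5, "repressive_A_on_B": 4}
}
```

All 12 planted regions per factor are recovered; 8 of the 12 factor-A
regions are co-bound (66.7 %, close to the planted co-binding fraction
of 0.69); the 8-gene target overlap is far beyond chance
(p ≈ 7×10⁻¹⁰); the 64 genes downstream of the A mutant split into the
four k-means response clusters; and the 9 simulated enhancers are
classified by co-regulation mode (this seed happened to draw no
additive enhancer from the mode mixture).

The same stages are available from the shell:

```sh
coregmap simulate --out fx --seed 7
coregmap run-all --fixtures fx --out run --seed 7
coregmap chip-call --matrix fx/chip_A.tsv --fragments fx/fragments.bed \
    --out bound_A.bed --fdr 0.02 --min-fold 1.5 --n-perm 1000 --seed 7
coregmap classify-modes --reporter fx/reporters.tsv --out modes.tsv
```

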