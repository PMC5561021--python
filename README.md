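# refstab

Reference-gene stability analysis for RT-qPCR experiments.

Relative quantification by qPCR stands or falls with the normaliser: a
"housekeeping" gene assumed constant across treatments. That assumption must
be validated per experiment, and the field does so by scoring a panel of
candidate genes with four complementary statistics and merging their
rankings. `refstab` implements that whole workflow as a tested Python
library with a thin CLI — for people validating reference genes in new
species or stress conditions, and for people who want the statistics
scriptable instead of behind web forms and spreadsheets.

## What it computes

Given a table of quantification cycles Cq (sample × gene, with biological
and technical replicates), with lower value = more stable throughout:

- **Comparative ΔCt** — gene *j*'s stability is the mean over partners *k*
  of SD_i(Cq_ij − Cq_ik), the spread of within-sample pairwise differences.
- **geNorm** — on log2 relative quantities y = log2 E^(Cq_min − Cq), the
  M value M_j = mean_k SD_i(y_ij − y_ik); the least stable gene is excluded
  stepwise until the best pair remains. Pairwise variation V_n/n+1 between
  normalisation factors (geometric means of the top-n genes) is also
  provided.
- **BestKeeper** — descriptive dispersion of raw Cq: SD [±CP] as the mean
  absolute deviation about the geometric mean, CV [%CP], and each gene's
  Pearson r with the per-sample BestKeeper index. Deliberately *not*
  invariant to loading differences.
- **NormFinder** — additive model y_ig = gene_g + sample_i + ε_ig with
  gene-specific noise variance estimated from sample-centred residuals
  (small-panel k/(k−2) correction, floored at 0); stability = √σ̂²_g.
  A grouped variant combines intragroup variance with shrunken intergroup
  differences.
- **Consensus** — the geometric mean of the four per-method ranks
  (the aggregation popularised by web consensus tools), ascending order,
  ties broken by mean rank then input order.
- **Amplification efficiency** — per-well E = 10^slope from a baseline-
  corrected window-of-linearity on raw fluorescence curves, and
  dilution-series E = 10^(−1/slope) from standard curves.
- **2^−ΔΔCt** — fold change of a target gene versus chosen reference(s)
  and a calibrator condition, per biological replicate, mean ± SE.

A synthetic-data module generates Cq tables and raw amplification curves
with known ground truth (designed-stable genes, condition effects, loading
and technical noise), so the entire pipeline is testable end to end without
any instrument data.

## Worked example

```python
from refstab import (SimulationConfig, simulate_cq,
                     aggregate_technical_replicates, run_all_methods,
                     reffinder_consensus)

table, truth = simulate_cq(SimulationConfig(seed=42))   # 9 genes, G1/G2 designed stable
agg = aggregate_technical_replicates(table)
ranking = reffinder_consensus(run_all_methods(agg))
print(ranking.to_frame().round(3))
```

```
    rank_delta_ct  rank_genorm  rank_bestkeeper  rank_normfinder  geomean  geomean_2dp  final_rank
G2            2.0          1.5              1.0              1.0    1.316         1.32           1
G1            1.0          1.5              2.0              2.0    1.565         1.57           2
G9            3.0          3.0              3.0              3.0    3.000         3.00           3
...
G8            9.0          9.0              9.0              9.0    9.000         9.00           9
```

Each row is one candidate gene: its rank under each method, the geometric
mean of those ranks (full precision and 2-dp display), and the final
comprehensive rank. Here the two designed-stable genes (G1, G2) head the
consensus — geNorm's final pair carries the tied rank 1.5. The same
analysis runs from the shell:

```sh
refstab simulate --seed 42 --out cq.csv
refstab consensus cq.csv --out consensus.csv
refstab quantify cq.csv --target G9 --references G1,G2 --calibrator control
```

and `refstab run --config run.yaml` orchestrates summary → stability →
consensus → quantification into a report directory with a JSON manifest.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it simulates a default candidate panel and ranks it with all four methods
plus the consensus, estimates amplification efficiency from simulated raw
curves, and recovers a known fold-change profile by 2^−ΔΔCt.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.
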