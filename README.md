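# refstab

Reference-gene (housekeeping-gene) selection and validation for RT-qPCR,
with a transcriptome screening step and a ground-truth synthetic data
generator.

Quantitative PCR reports a target gene's abundance relative to one or
more reference genes assumed stable across the conditions studied. When
that assumption fails — the classic offenders being *actin*, *β-tubulin*
and *EF-1α* under stress or developmental series — every downstream fold
change inherits the reference gene's own regulation. `refstab`
implements the standard toolkit for choosing references rationally:

- **Screening** of RNA-seq candidates by mean FPKM (MF), standard
  deviation (SD) and coefficient of variation (CV = SD/MF, in %), with
  the customary MF ≥ 10, CV ≤ 20 % filter.
- **Four stability statistics** over a genes × samples Ct matrix
  (lower = more stable in all four):
  - *comparative ΔCt*: mean over partner genes of
    SD<sub>samples</sub>(Ct<sub>i</sub> − Ct<sub>k</sub>);
  - *BestKeeper*: per-gene SD and CV of raw Ct, plus Pearson correlation
    against the BestKeeper index (per-sample geometric-mean Ct);
  - *geNorm*: M<sub>j</sub> = mean<sub>k≠j</sub>
    SD(log₂ Q<sub>j</sub>/Q<sub>k</sub>) on relative quantities
    Q = E^(minCt − Ct), with iterative worst-gene exclusion, and the
    pairwise-variation rule V(n/n+1) < 0.15 for the optimal number of
    reference genes;
  - *NormFinder*: a variance decomposition into intragroup noise
    σ̂²<sub>ig</sub> and shrunken intergroup differences d̃<sub>ig</sub>,
    combined as ρ<sub>i</sub> = mean<sub>g</sub>(|d̃<sub>ig</sub>| +
    √(σ̂²<sub>ig</sub>/n<sub>g</sub>)).
- **Comprehensive ranking** by the geometric mean of the four ranks
  (the RefFinder aggregation) and selection of the optimal-n top genes.
- **Quantification**: standard-curve efficiency fits
  (E = 10^(−1/slope)), multi-gene normalization factors (geometric mean
  of reference quantities) and 2^(−ΔΔCt) fold changes versus a
  calibrator, under multi-gene / single-best / least-stable strategies.
- **Simulation**: Ct = baseline + group shift + per-sample loading
  effect + noise, with the designed stability ordering as ground truth.

## Worked example

```python
from refstab import ReferenceGeneStability
from refstab.simulate import preset_config, generate_ct_dataset

ct, design, truth = generate_ct_dataset(preset_config("corm_growth", seed=7))
res = ReferenceGeneStability(ct).fit()
print(res.summary())
```

prints (abridged):

```
Comprehensive ranking (geometric mean of ranks):
       rank_delta_ct  rank_bestkeeper  rank_genorm  rank_normfinder  geomean  final_rank
gene
UBC9               1                7            1                1   1.6266           1
GAPDH              3                3            1                3   2.2795           2
...
EF1A               9               10            9               10   9.4868           9
TUBB              10                9           10                9   9.4868           9

geNorm pairwise variation: V2/3=0.0658  V3/4=0.0449  ...
optimal reference-gene count: 2
recommended set: UBC9, GAPDH
```

The two designed troublemakers — TUBB (progressively regulated across
stages) and EF1A (high scatter) — land at the bottom of every ranking;
V2/3 is already below 0.15, so two reference genes suffice, and their
names are the recommended normalization set. The same analysis is
available from the shell:

```sh
refstab simulate --preset corm_growth --seed 7 --out ct.tsv
refstab stability --ct ct.tsv --out results/
refstab quantify --ct ct.tsv --target UBQ10 --rgs UBC9,GAPDH \
    --calibrator stage1 --out folds.tsv
```

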