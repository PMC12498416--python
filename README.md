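# seedkin

Quantitative analysis of polymorph-specific amyloid aggregation inhibition,
from seeded kinetics to an active-learning screening loop.

`seedkin` is built for the workflow used to discover and optimize small
molecules that block the self-replication of disease-derived tau fibril
polymorphs: seeded ThT aggregation assays are modelled with moment-closure
kinetics to expose the microscopic mechanisms (elongation, secondary
nucleation, fragmentation); inhibitor effects are deconvolved into per-dose
perturbations of the elongation rate constant k₊ and the secondary-process
rate constant k₂; binding to fibrils is quantified by
fluorescence-polarization titrations; and compound selection is driven by
an iterative machine-learning loop (random forest + Gaussian-process
residual model with an uncertainty-weighted acquisition).  A synthetic-data
module generates every assay with known ground truth, so the entire
pipeline is testable end to end without laboratory data.

## The models

**Aggregation kinetics.** Fibril number `P` and fibril mass `M` (molar,
monomer equivalents) evolve under free monomer `m = m_tot − M` as

```
dP/dt = k_n mⁿᶜ + k₂ mⁿ² / (1 + (m/K_M)ⁿ²) · M + k₋ M
dM/dt = 2 k₊ m P
```

Primary nucleation (k_n), saturating secondary nucleation (k₂, K_M) and
fragmentation (k₋) create growth-competent ends; elongation (k₊) converts
monomer.  Half-times t½ are midpoints of four-parameter logistic fits; the
scaling exponent γ = d log t½ / d log m₀ diagnoses the dominant mechanism
(γ ≈ −½ for secondary-process-dominated seeded aggregation).

**Inhibition metrics.** Potency is the half-time normalized to the DMSO
control (strictly >1.5 = potent "hit", >2 = highly potent); mechanism comes
from per-dose global refits with only {k₂, k₊} free; KIC₅₀ is the dose
halving the normalized approximate rate 100·(1/t½)/(1/t½,ctrl); binding is
a one-site fit ΔmP = B_max[F]/(K_D+[F]).

**Screening loop.** Morgan-fingerprint features → random-forest regression
of normalized t½ → Gaussian process on the residuals → upper-confidence-
bound acquisition (mean + β·sd) → batch selection → measurement → retrain.
Chemotypes are grouped by Butina clustering at Tanimoto 0.78 and libraries
pre-filtered by the six-component CNS multiparameter-optimization score.

## Worked example

Run a three-iteration screening campaign on the packaged 2,000-molecule
synthetic library (hidden structure–activity landscape, ~3% base hit rate):

```python
import pandas as pd
import seedkin as sk
from seedkin.io import report

cfg = sk.GeneratorConfig(rng_seed=7)
records, oracle, truth = sk.gen_library(cfg)
state = sk.run_campaign(records, oracle, batch_sizes=(32, 45, 49),
                        beta=1.0, rng_seed=1)
table = pd.DataFrame([{"compound": m.id, "t12_norm": m.measured_t12_norm}
                      for m in state.tested])
print(report(campaign_history=state.history, compound_table=table)[1])
```

prints

```
Per-iteration hit rates
iter  tested  potent  high  hit rate
   0     105       2     0     1.9%
   1      32       6     4    31.2%
   2      45      13     2    33.3%
   3      49      20     1    42.9%

Top 10 compounds by normalized t1/2
  M00295       t1/2 norm = 3.09
  M00440       t1/2 norm = 3.07
  ...
```

Iteration 0 is a random initial draw (105 compounds, ~2% hit rate — the
base rate of the library); the surrogate then concentrates testing in the
active chemotype and the hit rate climbs to ~40%.  The same stages are
available from the shell:

```bash
seedkin synth library --seed 7 --size 2000 --out lib.smi
seedkin screen --library lib.smi --iters 3 --batches 32,45,49 --beta 1.0 \
    --seed 1 --out history.jsonl
seedkin synth kinetics --seed 1 --out plate.csv
seedkin synth fp --compound I1.21 --kd-um 1.58 --seed 2 --out fp.csv
seedkin bind fp.csv --out binding.json
```

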