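# dock1433

Rank the candidate phospho-Ser/Thr residues of a protein by their
likelihood of mediating 14-3-3 docking.

14-3-3 adaptor proteins regulate hundreds of clients by binding
phosphorylated Ser/Thr residues, but finding *which* phosphosite on a
client mediates binding usually takes months of mutagenesis and co-IP:
clients carry many phosphosites, and the classical consensus motifs
(mode I `RXXpS/TXP`, mode II `RXF/YXpSXP`) are loose and full of
red herrings. `dock1433` is for researchers triaging candidate docking
sites before going to the bench. It integrates, per site:

* the **PTM score** `n_obs(site) / Σ n_obs(protein)` — the site's unbiased
  MS observation count normalized by all phosphorylation observations on
  that protein;
* a per-residue **intrinsic disorder** score (external profile, or a
  built-in FoldIndex-form composition score);
* three **consensus-sequence** scores (external ANN/SVM/PSSM tables, or a
  built-in position-specific scoring matrix over window −5…+4).

Three random-forest ensembles (all features; PTM+disorder; sequence only)
plus a learning-free mean-of-sequence-scores baseline each produce a rank
list per protein, so outputs are directly comparable and there is no score
cutoff to tune. The package also ships the full validation machinery
(leave-one-protein-out, repeated protein-level holdout, non-canonical
subset analysis, feature enrichment) and a seeded synthetic-data generator
so every protocol runs offline.

## Worked example

```bash
# generate a synthetic cohort of 14-3-3 client proteins
dock1433 --seed 8 --out-dir sim simulate --n-proteins 6
# train the ranker and inspect Gini importances
dock1433 --seed 8 --out-dir run train sim/proteins.fasta sim/observations.tsv sim/labels.tsv
# rank every candidate S/T; keep the top 5 per protein
dock1433 --out-dir run predict sim/proteins.fasta sim/observations.tsv \
    --model run/model.joblib --top 5
# held-out validation
dock1433 --seed 8 --out-dir run evaluate loo \
    sim/proteins.fasta sim/observations.tsv sim/labels.tsv
```

The evaluate step prints, for this cohort and seed:

```
protocol: loo  (7 evaluated sites)
  total         top-10%: 6/7 = 0.857   top-25%: 6/7 = 0.857
  ptm_disorder  top-10%: 7/7 = 1.000   top-25%: 7/7 = 1.000
  sequence      top-10%: 6/7 = 0.857   top-25%: 6/7 = 0.857
  adapted       top-10%: 6/7 = 0.857   top-25%: 6/7 = 0.857
```

Reading: each of the 7 validated docking sites was hidden in turn (its
whole protein left out of training), the tool retrained, and the site's
rank among its protein's 60 candidate S/T recorded (a top-10% hit means
rank ≤ 6 of 60). On this tiny 6-protein cohort every column does well and
PTM+disorder is perfect; the gap between the columns widens on larger
cohorts and on sites that match the consensus poorly (see
`docs/methods.md`). `predictions.tsv` carries one row per candidate with all
four score/rank column pairs; `report.json` has per-site records and both
site-level and protein-level hit tables.

Python API mirrors the CLI:

```python
from dock1433 import SimulationConfig, simulate_dataset, ForestConfig
from dock1433 import train_ranker, assemble_features, predict_table

ds = simulate_dataset(SimulationConfig(seed=8, n_proteins=6))
ranker = train_ranker(ds, ForestConfig(seed=8))
ranked = predict_table(ranker, assemble_features(ds))
```

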