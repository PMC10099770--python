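# Methods

## Problem and model

14-3-3 proteins dock onto phosphorylated Ser/Thr residues of client
proteins. Identifying *which* phosphosite on a client mediates binding is
the expensive step in the wet lab: clients carry tens of phosphorylated
residues, consensus motifs (mode I `RXXpS/TXP`, mode II `RXF/YXpSXP`) are
loose, and many validated docking sites match them poorly.

`dock1433` ranks every Ser/Thr of a protein by its likelihood of mediating
14-3-3 docking using five per-site inputs:

1. **PTM score** — the site's count of independent MS observations divided
   by the total observation count of all phosphosites on that protein.
   It lives in [0, 1]; over a protein's observed sites the scores sum to 1.
   A never-observed site scores 0 and is flagged `missing_ptm` rather than
   excluded, because unobserved sites are still legitimate candidates.
2. **Disorder** — a per-residue intrinsic-disorder propensity in [0, 1],
   taken at the phosphosite itself. Externally computed profiles (e.g.
   IUPred2A output re-shaped to `protein_id/position/score` TSV) are used
   verbatim when supplied.
3-5. **ANN / SVM / PSSM** — consensus-sequence scores. External tables
   (14-3-3Pred-style) are ingested verbatim; otherwise the built-in PSSM
   score is replicated into all three slots (flag `builtin_seq`) — the
   forest sees the same information either way.

Three random forests are trained on nested feature subsets — all five
inputs ("total"), PTM+disorder, and the three sequence scores — and a
fourth, learning-free column ("adapted") ranks sites by the arithmetic mean
of the three sequence scores. Output is rank lists per protein (rank 1 =
most likely), not thresholded calls. Ties are broken deterministically by
higher PTM score, then lower position.

## Built-in scorers

**PSSM.** Log-odds over window offsets −5…+4 (0 excluded), covering the
mode I determinants (−3 Arg, +2 Pro) and mode II (−4 Arg, −2 Phe/Tyr):
`cell(j, a) = log2(((count_j(a) + c·bg(a)) / (N + c)) / bg(a))` with
pseudocount `c = 1` and uniform background by default. Out-of-range and
unknown (X) positions score 0 (background). A window drawn from background
scores 0 in expectation in the pseudocount-free limit.

**Disorder proxy.** When no external profile is given, a windowed
composition score with the FoldIndex closed form: over a clipped window of
±25 residues, `foldindex = 2.785·⟨H⟩ − |⟨q⟩| − 1.151` where ⟨H⟩ is mean
Kyte–Doolittle hydropathy rescaled to [0, 1] and ⟨q⟩ the mean net charge
(K/R = +1, D/E = −1); the output is `logistic(−10·foldindex)`, so
foldindex < 0 maps to disorder > 0.5. This captures the low-hydropathy /
high-charge signature of disorder but none of the pairwise-energy context
an external predictor models; results on real proteins are expected to
improve when an external profile is supplied.

## Training-set construction

Positives are the validated docking sites; negatives are **all other
candidate S/T on the same client proteins** — never random proteome
background — so the forest learns to discriminate sites within a client,
which is the deployment question. Class imbalance is handled by balanced
class weights (default) or seeded 5:1 negative downsampling. Forest
defaults: 500 trees, √p features per split, min leaf 1; every training run
requires a seed and is bit-reproducible.

## Evaluation protocols

* **Leave-one-protein-out**: retrain without one client protein (forests
  *and* the built-in PSSM — the PSSM is refit per fold from training
  positives only, otherwise held-out windows leak into the sequence
  features and the null calibration breaks), rank its candidates, record
  the validated site's rank in all four columns.
* **Repeated holdout**: hold out 20% of client proteins (protein-level
  split so a protein's positive and negative sites never straddle the
  split), 200 repetitions by default.
* **Hit criterion**: rank within the top k% of the protein's candidates,
  threshold `ceil(k·n)` (a rank-1 site on a 5-candidate protein is a
  top-10% hit). Dual-site proteins contribute one record per site
  (denominator counts sites); protein-level rates (protein hits if any of
  its sites hit) are reported alongside.
* **Non-canonical analysis**: validated sites whose consensus score falls
  below a cutoff (0.5 default, 0.8 variant) are removed one at a time (the
  site, not the protein), the tool is retrained, and the site's de-novo
  rank is compared against an absolute top-15 cutoff, stratified by the
  missing-PTM flag. When consensus comes from the built-in PSSM, each
  positive is scored by a PSSM fit on the *other* positives
  (leave-one-site-out): a site's own window otherwise inflates its own
  consensus by roughly +2 log-odds of self-inclusion bias, which would
  empty the subset even for motif-free sites. The raw log-odds is mapped
  to [0, 1] by a logistic so the external 0.5/0.8 cutoff scale applies
  (flagged). A `train_on_subset_only` variant retrains on the
  non-canonical subset alone.
* **Enrichment**: Welch's unequal-variance t test per feature, docking vs
  other sites, with the relative mean difference
  `|(mean_other − mean_docking)/mean_docking|·100`; significance flagged
  at p < 0.001. Zero variance in both groups is degenerate: the limit
  value is reported and flagged.

## Synthetic data generator

The generator emulates the three signals the method exploits, each behind
an independent switch:

* **Sequence**: proteins of length 500–700 with an exact number of
  candidate S/T per protein (default 60, matching the tens-of-candidates
  scale of real clients and making the absolute top-15 criterion
  meaningfully stricter than chance at 15/60 = 25%); other positions drawn
  uniformly from the 18 non-S/T letters. Docking sites (1 per protein with
  probability 0.8, 2 with 0.2) emit the mode I/II determinants
  probabilistically (Arg at −3 with 0.7, Pro at +2 with 0.45, Phe/Tyr at
  −2 with 0.25), reflecting the looseness of the real consensus (the +2
  Pro is found in under half of validated sites).
* **Disorder**: residues in a ring 6–20 positions from a docking site are
  replaced with disorder-promoting letters (`E K P Q G D`, probability
  0.9). The ring deliberately excludes the ±5 consensus window ("just
  adjacent" to the site): if the window composition itself were enriched,
  a PSSM trained on the positives would absorb the disorder signal and the
  sequence and disorder channels could not be recovered independently.
  Ser is excluded from the pool so enrichment never changes the candidate
  universe.
* **Observation counts**: docking sites are observed with probability 0.9,
  with counts negative-binomial (mean 20, dispersion 1, clipped to ≥1);
  decoy S/T are observed with probability 0.3, counts NB(mean 3). The
  means mirror the strong but overlapping upward shift of docking-site
  observation frequency; dispersion 1 makes counts heavy-tailed, so the
  channels overlap and the problem is learnable but not separable.

With a switch off, that channel is generated identically for docking and
decoy sites (exchangeable); with all three off the dataset carries no label
signal at all, which the null-calibration test verifies end to end. Every
protein's content derives from a sub-seed of (master seed, protein index),
so records are independent and datasets byte-reproducible.

What the generator does **not** emulate: kinase-motif grammar beyond the
mode I/II determinants, real disorder (only its compositional signature),
protein-abundance and solubility biases of MS detection, isoform/coordinate
drift, or correlated observation counts between neighbouring sites.
Passing tests therefore demonstrate that the machinery recovers the signals
it assumes, at the stated strengths — not field performance on curated
interactome data.

## Numerical and protocol choices

* Percentile threshold uses a ceiling with a 1e−9 guard against binary
  representation of k·n.
* Rank ties: higher PTM score, then lower position — fully deterministic.
* Sub-seeds are derived by SHA-256 of (seed, context labels), keeping all
  streams below 2³¹ and independent across folds, repetitions and proteins.
* Protocol studies in the test suite and acceptance script use 50-tree
  forests with seeded 5:1 downsampling: the studies retrain a few thousand
  forests (LOO × seeds), and ranking stability, not probability precision,
  is what the protocols measure. The library default remains 500 trees.
* Degenerate inputs: empty predictions give header-only files; a protein
  with a docking site but no negatives warns and is retained; single-class
  training data and empty positive sets are hard errors.

## Known limitations

* The built-in disorder proxy and PSSM are stand-ins for external
  predictors; on real proteins, supply IUPred2A profiles and
  consensus-score tables for best behaviour.
* No probability calibration across proteins: scores order sites within a
  protein; cross-protein score comparisons are not meaningful.
* Reported headline numbers are computed on synthetic data; curated
  training tables of validated docking sites are required to reproduce
  field-scale accuracy figures.
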