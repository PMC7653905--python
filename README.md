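# trimorf

Per-residue prediction of **Molecular Recognition Features (MoRFs)** —
short (5–25 residue) regions of intrinsically disordered proteins that
fold upon binding a structured partner — by **trisecting** each
sequence into its two terminal zones and its middle zone and scoring
each zone with its own classifier.

Residues near a terminus lack full neighbouring context, which makes a
single whole-sequence model harder to learn. trimorf therefore trains
two RBF-kernel support vector machines: a *terminal* model on MoRF
segments that touch the first or last 20 residues, and a *middle*
model on the rest. Both consume **auto-covariance features** of
predicted structural attributes. For a segment of length *l* over *u*
selected channels with structural matrix *M*, the features are the
lagged second moments

    AC(k, j) = (1 / l) · Σ_{i=1}^{l−k} M(i, j) · M(i+k, j),
    k = 1 … DF,  j = 1 … u,

flattened into a vector of length DF·u (DF = 10 by default; the
default single channel is the upper α half-sphere exposure count,
`HSEa_up`). At query time each residue gets a window of up to 41
residues (flank 20, truncated at the termini), the window is
featurized identically to training, and the residue is scored by the
model of its zone. Decision values are min–max normalised to [0, 1].

Because a genuine MoRF spans several residues, raw tracks are
post-processed: each residue's score becomes
`(max(window) + median(window)) / 2` over a score window (flank 12 for
the model's own track). Tracks from several predictors can be fused by
plain averaging, optionally re-smoothed with flank 8. Evaluation pools
all residues of all sequences into one ROC curve (Mann–Whitney AUC,
ties at half credit) with an FPR-at-TPR summary grid.

A synthetic benchmark generator emulates the MoRF regime — one MoRF of
length 5–25 per sequence, a tunable mean shift of the `HSEa_up`
channel inside the MoRF over autocorrelated noise — so the whole
pipeline trains and evaluates with no external data or predictors.

## Worked example

```sh
trimorf simulate --out data --n-sequences 60 --seed 1
trimorf train    --fasta data/sequences.fasta --annotations data/annotations.tsv \
                 --traces data/traces --out bundle.joblib --seed 1
trimorf predict  --bundle bundle.joblib --fasta data/sequences.fasta \
                 --traces data/traces --out scores.tsv
trimorf evaluate --scores scores.tsv --annotations data/annotations.tsv \
                 --fasta data/sequences.fasta --out report.json
```

Training logs the per-model sample manifest — positives and negatives
balanced per zone:

```
INFO trimorf: bundle saved to bundle.joblib; manifest: {"terminal": {"n_pos": 20, "n_neg": 20}, "middle": {"n_pos": 53, "n_neg": 47}}
```

(three middle negatives had no feasible label-free placement and were
dropped with a warning). `evaluate` prints the headline numbers and
writes the full report:

```
{"auc": 0.9767124926045988, "n_pos": 987, "n_neg": 20026}
```

Here `auc` is the pooled per-residue ROC AUC over all 60 sequences
(0.98: the simulated structural signal is recovered almost perfectly
on the training set), and `n_pos` / `n_neg` count MoRF and non-MoRF
residues. `report.json` additionally holds FPR at TPR ∈ {0.2, …, 0.9};
e.g. at 80 % sensitivity the false positive rate here is 0.043.

Score tracks are TSVs with one row per residue:

```
seq_id  position  residue  score     stage
syn0000 1         M        0.514094  processed
```

`trimorf combine --scores a.tsv --scores b.tsv --out fused.tsv`
averages aligned tracks from several predictors (external tracks are
ingested through the same TSV format).

## File formats

* **FASTA** — sequences; 20-letter alphabet plus `X`.
* **Annotations** — TSV `seq_id / start / end`, 1-based inclusive
  MoRF intervals, non-overlapping.
* **Structural tables** — per-sequence TSV, header `index  aa` plus
  channel columns from: `SS_H SS_E SS_C ASA PHI PSI THETA TAU HSEa_up
  HSEa_dn HSEb_up HSEb_dn CN`. A best-effort `spider2` dialect maps
  SPIDER2-style headers (`P(H)`, `P(E)`, `P(C)`, `ASA`, `Phi`, `Psi`,
  `Theta(i-1=>i+1)`, `Tau(i-2=>i+2)`, `HSEu`, `HSEd`, `CN`, …) onto
  these channels; SPIDER2 splits its output across several files whose
  layout varies between releases, so check the mapping in
  `trimorf.io_formats.SPIDER2_COLUMN_MAP` against your files. trimorf
  only reads such outputs — it never runs a structure predictor.
* **Score tracks** — TSV `seq_id / position / residue / score / stage`.

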