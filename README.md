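# gtacore

Evolutionary analytics and donor-substrate prediction for **GT-A fold
glycosyltransferases** (GTs).

GT-A enzymes share a Rossmann-like catalytic domain that can be reduced to a
*common core* of 231 aligned positions, decorated by three hypervariable
loop regions (HV1–HV3) that carry family-specific acceptor-binding motifs.
`gtacore` implements the analysis pipeline built on such core alignments:

* **Alignment analytics** — A2M-style aligned FASTA I/O (uppercase/`-` =
  core columns, lowercase = inserts), trimming, per-column gap statistics
  with the strict >15% gap filter, consensus and prototype selection,
  hypervariable-insert detection (HV2 = insert longer than 28 residues
  between the β6/β7 anchors), family-wise redundancy filtering (<70%
  identity, stricter bounds for the very large families), the four-rule
  minimal-domain ("ancient sequence") filter, and a Karlin–Altschul
  E-value similarity network.
* **Conservation** — per-column Jensen–Shannon divergence conservation

  `score_c = (1 − gap_c) · JSD(p_c, q)` ,
  `JSD(p, q) = λ KL(p‖m) + (1−λ) KL(q‖m)` , `m = λp + (1−λ)q`

  with logs base 2, λ = 0.5 and a BLOSUM62 background `q`; plus a
  foreground/background **pattern-contrast** score (hypergeometric tail of
  the most enriched residue set, optional permutation calibration) that
  ranks family-characteristic positions.
* **Phylogeny** — p-distance / Poisson-corrected distances, family-profile
  distances (mean column-wise JSD), Saitou–Nei **neighbor joining** (exact
  on additive matrices), column-resampling bootstrap, and the support bands
  well (>90), moderate (>75), low (50–75), unresolved (<50).
* **Donor-specificity classifier** — each kept core column contributes five
  physicochemical features (charge, polarity, hydrophobicity, accessible
  surface area, side-chain volume); CFS feature selection maximizes Hall's
  merit `M_S = k r̄_cf / sqrt(k + k(k−1) r̄_ff)` over symmetrical-uncertainty
  associations within 5-fold CV; a gradient-boosted tree ensemble (GDBT,
  published hyperparameters: learning_rate 0.1, 1600 estimators,
  min_samples_split 25, min_samples_leaf 7, max_depth 4, max_features 18,
  subsample 0.75, random_state 10) predicts one of six donor classes
  (Glc, GlcNAc, Gal, GalNAc, Man, Others) with a confidence category:
  *high* if p₁ > 4·p₂, else *moderate* if p₁ − p₂ > 2·(1/6), else *low*.
* **Synthetic data** — a seeded generator planting globally conserved
  columns, family-specific columns, donor-determining columns, gaps and HV
  inserts, so every stage is testable closed-loop against ground truth.

## Worked example

```python
import gtacore as g

# simulate a donor-labelled core alignment: 6 classes x 120 sequences,
# 4 determining columns per class, 5% substitution noise
cfg = g.SimulationConfig(seed=1)
aln, labels, truth = g.generate_donor_dataset(cfg)

# strict >15% gap filter, five-property encoding, CFS selection
_, kept = g.filter_gapped_columns(aln, threshold=0.15)
X = g.encode_properties(aln, kept_columns=kept, labels=labels)
sel = g.cfs_select(X, n_folds=5, seed=1)
print(len(kept), "columns kept,", len(sel.selected), "features selected")

# fit the donor-specificity model and cross-validate
model = g.DonorSpecificityModel(X.subset(sel.selected))
cv = model.cross_validate(k=10, seed=1)
print(f"10-fold CV accuracy: {100 * cv.accuracy:.1f}%")
print(f"Bayes rate of the generator: {100 * g.bayes_rate(truth, seed=1):.1f}%")
```

prints

```
229 columns kept, 96 features selected
10-fold CV accuracy: 99.9%
Bayes rate of the generator: 99.9%
```

`229 columns kept` — two planted high-gap columns exceed the 15% filter;
`96 features selected` — CFS keeps a non-redundant informative subset of
the 1145 encoded features; the cross-validated accuracy of the fitted
classifier matches the generator's Bayes-optimal rate, i.e. the model
extracts essentially all the class signal the data contain.

The same stages are available from the shell:

```bash
gtacore simulate --kind donor --seed 1 --out-dir run/sim
gtacore encode run/sim/alignment.a2m.fasta --labels run/sim/labels.tsv --out-dir run/enc
gtacore select run/enc/features.tsv --labels run/sim/labels.tsv --out-dir run/sel
gtacore cv run/enc/features.tsv --labels run/sim/labels.tsv \
        --selected run/sel/selected_features.tsv --out-dir run/cv
```

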