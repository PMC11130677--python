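# Methods

## Problem and model

The package scores whether a chemical structure looks like a real
molecule or a generative-model artifact. The working assumption is that
real and generated molecules overlap almost completely in bulk
properties (QED, MW, logP, SAscore) but differ in the *joint*
distribution of fingerprint substructures: generated structures contain
bit combinations that real chemistry rarely produces. All three stages
therefore operate on binary 2048-bit ECFP4 (Morgan radius-2)
fingerprints.

**Anomaly stage.** A symmetric autoencoder (encoder widths mirrored in
the decoder, ReLU hidden layers, sigmoid output) is trained on real
fingerprints with per-bit binary cross-entropy. The per-molecule score
is the cosine `S_C` between input and reconstruction. Because both
vectors are non-negative, `S_C ∈ [0, 1]`; it is exposed to the ensemble
as `l_ecfp4`. `S_C` is the recovery *similarity*, not the loss: rarer,
harder substructures reconstruct worse, which is why `l_ecfp4`
correlates negatively with synthetic-accessibility scores.

**Classification stage.** Gradient-boosted trees, a feed-forward
network, a random forest and logistic regression compete on validation
AUROC over the raw fingerprint bits. The seven XGBoost hyperparameters
are tuned coordinate-wise in four rounds — {n_estimators,
learning_rate}, {max_depth, min_child_weight}, {subsample,
colsample_bytree}, {gamma} — each round grid-searching one group while
holding the others at the incumbent. Because each round's grid contains
the incumbent configuration, the final validation AUROC can never fall
below the anchored default (asserted in tests). Ties in family selection
break in the declared order gbt, ffnn, rf, logreg.

**Ensemble stage.** A logistic regression on standardized features
(zero mean, unit variance from the training partition; MW is three
orders of magnitude larger than the probability features, so
standardization is not optional). The feature set is chosen by
enumerating all 16 subsets of {sascore, qed, mw, logp} unioned with the
base {l_ecfp4, p_real_clf}; exact ties prefer the smaller set, then the
declared feature order. Constant features are dropped before
enumeration. The output `P_Real` is thresholded at 0.5 (configurable)
for the real/generated call.

## Dataset construction

Invalid SMILES (sanitization failures) and duplicates (canonical-SMILES
equality) are removed with full count bookkeeping
(`n_in = n_invalid + n_duplicate + n_out`). Each generated molecule is
paired with the real molecule of maximal ECFP4 Tanimoto similarity;
ties break toward the lexicographically smallest canonical SMILES so
the pairing is input-order independent. The classification dataset
`D_cls` keeps generated molecules with `0.3 ≤ S_T < 0.6` (lower-closed,
upper-open) plus their deduplicated real counterparts — structures of
extreme similarity would make the task degenerate in either direction.
The ensemble dataset `D_ens` is everything absent from `D_cls`
train/validation, checked by canonical SMILES and asserted as a set
intersection. Splits are 9:1:1 with exact integer sizes
(largest-remainder), label-stratified when every class has at least two
members, and seeded.

The autoencoder trains on the real pool *excluding* the real molecules
of the `D_ens` test partition, so the held-out metrics are computed on
structures no stage has seen. Class imbalance inside `D_cls` (several
generated molecules can share one real counterpart) is tolerated, not
rebalanced.

## Synthetic study data

`synthdata` makes the framework trainable without any corpus download:

* **Fixture.** ~330 drug-like SMILES shipped as text: ~140 well-known
  public-domain drug structures plus deterministic single-substituent
  analogs (marked `analog_*` in the file). At run time the pool is
  expanded to the requested size by conservative substituent decoration
  (methyl, halogen, methoxy, trifluoromethyl, …), emulating the analog
  series that populate real screening libraries.
* **Mutation generator.** "Generated" molecules are real molecules
  corrupted by 2–8 random graph edits (atom substitution among C/N/O/S,
  bond-order change, ring break, fragment swap), re-sanitized after
  every edit, keeping the largest fragment, dropped after 20 failed
  retries. More edits push the fingerprint further from the parent
  (asserted as a monotonicity test), and the uniform {2..8} edit mixture
  places roughly 40% of the pool in the moderate-similarity window at
  the default 2000/2000 scale. If the window yield falls below 200 the
  mixture is widened to include single edits and the pool topped up.
* **Fingerprint simulator.** Two populations with identical per-bit
  marginals but different joint structure: the "real" class couples
  designated bit groups to a shared Bernoulli latent (coupling
  probability q; q = 1 gives a co-occurrence ratio of 1/p), the
  "generated" class samples the same marginals independently (ratio 1).
  This isolates the joint-structure signal that the co-occurrence
  statistics are designed to detect.

What the generator does **not** emulate: the chemistry of any specific
generative model (character RNN grammar errors, VAE decoder artifacts),
database-scale diversity (hundreds of thousands of scaffolds), or
assay-driven composition bias of curated corpora. Passing the synthetic
benchmark shows the pipeline's machinery is sound — curation, training,
stacking, evaluation — not that the shipped fixture generalizes to any
particular external library.

## Defaults and numerical choices

| parameter | default | rationale |
| --- | --- | --- |
| fingerprint | 2048 bits, radius 2 | standard ECFP4 folding; binary bits |
| window | [0.3, 0.6) | moderate maximal similarity band |
| split ratio | 9:1:1 | train/validation/test |
| AE grid | widths {(1024,256),(512,128),(1024,128)} × lr {1e-3,1e-4} | covers nodes/depth/learning-rate at desk scale |
| AE training | batch 128, ≤30 epochs, patience 5, 4:1 train/held-out | early stop on held-out BCE |
| ffnn | hidden (512,128), dropout {0,0.2,0.5}, lr {1e-3,1e-4} | early stop on validation AUROC, patience 5 |
| ensemble LR | L2, C=1, lbfgs | plain regularized logistic fit |
| decision threshold | 0.5 | configurable |
| importance report | threshold 0.01, top-12 cap | matches the bit-signature analysis workflow |
| χ² correction | Yates when any expected cell < 5 | standard practice; both variants available |

Other numerical decisions: cosine recovery of an all-zero vector is an
error (undefined), while the Tanimoto of two all-zero fingerprints is
defined as 0 with a warning (it cannot occur for valid molecules under
the default featurizer). AUROC uses midranks for ties. Undefined metrics
(single-class AUROC/MCC, zero-variance correlations, zero-marginal
bits) are NaN sentinels, never silent zeros. Autoencoder grid cells that
diverge to non-finite loss are skipped; the run fails only if every cell
fails. Weight initialization is He-scaled and seeded; Adam is used
throughout the NumPy net. All randomness in a study flows from one root
seed.

The neural-network core is a deliberately small NumPy implementation
(dense layers, Adam, inverted dropout, per-output BCE): the package's
models are modest enough that BLAS-backed matrix products train them in
seconds to minutes on one CPU, and a single self-contained core keeps
the autoencoder and the feed-forward classifier bit-reproducible across
platforms.

## Problem sizes

The default study trains on 2000 real + 2000 mutated molecules; the
worked example in the README uses 600 + 600. Unit tests run on corpora
of 100–300 molecules and simulated fingerprint matrices; the acceptance
benchmark uses the default scale. These sizes were chosen as the
smallest at which the held-out metrics stabilize (AUROC varies by well
under 0.01 between seeds at the default scale).

## Known limitations

* The synthetic "generated" class is produced by graph mutation, not by
  an actual generative model; transfer of the trained bundle to real
  generative-model output requires retraining on such data.
* Co-occurrence p-values are reported raw, without multiple-testing
  correction across bit pairs.
* Probabilities from the classifier stage are not calibrated; only the
  ensemble output is meant to be interpreted as a probability.
* No 3D conformers, stereochemistry enumeration, or tautomer handling
  beyond RDKit's sanitization defaults.
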