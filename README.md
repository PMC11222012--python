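# distractnet

Brain-network analysis of multichannel EEG for recognizing distracted
driving states.

Driving with a secondary task — doing mental arithmetic, or watching a
phone — reorganizes the functional coupling between cortical regions.
`distractnet` implements the full analysis that exposes this: it turns
multichannel EEG (63 channels at 512 Hz in the default configuration) into
band-specific functional brain networks, extracts threshold-robust graph
topology features, and classifies epochs into *normal*, *cognitive
distraction* ("mind off road") and *visual distraction* ("eye off road")
states.  It is aimed at researchers in EEG functional connectivity and
driver-state monitoring who want a reproducible, testable reference
implementation of this pipeline — including a synthetic coupled-signal
generator so every stage can be validated end to end without access to
proprietary recordings.

## The method

1. **Preprocessing** — resampling to 512 Hz, zero-phase FIR bandpass
   0.5–40 Hz, fixed-length epoching (10 s), and decomposition into the
   four canonical rhythms δ (0.5–4 Hz), θ (4–8 Hz), α (8–13 Hz),
   β (13–30 Hz) by wavelet-packet reconstruction (db4, level 7; a
   zero-phase FIR alternative is selectable).

2. **Connectivity** — three pairwise synchronization estimators per band,
   each yielding a symmetric 63 × 63 matrix C_xy ∈ [0, 1]:

   - *Synchronization likelihood* (SL): embedding-based generalized
     synchronization,

         SL_xy = ⟨ |R_x(i) ∩ R_y(i)| / k_i ⟩_i ,

     where R_x(i) is the set of k_i = round(p_ref · W_i) nearest
     admissible neighbors of the embedded state at time i (Theiler window
     w₁, outer window w₂).  Independent signals give SL ≈ p_ref (0.05),
     identical dynamics give SL = 1.
   - *Phase locking value* (PLV): |⟨exp j(φ_x(t) − φ_y(t))⟩_t| from
     analytic-signal instantaneous phases — amplitude-blind.
   - *Coherence* (COH): band-averaged magnitude-squared coherence
     (1/F) Σ_f |S_xy|²/(S_xx S_yy) from Welch cross-spectra.

3. **Topology** — each matrix is binarized over a sparsity sweep
   (13%–47% in 1% steps, 35 grids), with two admission rules flagged per
   grid point: mean degree > 2 log(n) and small-world σ > 1.1 against
   Maslov–Sneppen degree-preserving nulls.  Four global features are
   computed per graph — characteristic path length L_g, clustering
   coefficient C_g, global efficiency E_g, local efficiency E_l — and
   aggregated as the normalized area under the feature-vs-sparsity curve.

4. **Recognition** — a 60-dimensional feature vector per epoch
   ({SL, PLV, COH} × 4 bands × {V, C_g, L_g, E_g, E_l}, where V is mean
   connection strength) feeds KNN, random forest, XGBoost and RBF-SVM
   classifiers under stratified 10-fold cross-validation with a reserved
   10% test split; feature importances are aggregated per estimator and
   band.

5. **Statistics** — one-way ANOVA of every feature across the three
   states with Bonferroni correction, and top-2% connectivity-difference
   maps between states.

## Worked example

```python
from distractnet import CohortSpec, train_evaluate
from distractnet.pipeline import extract_features
from distractnet.synthetic import generate_cohort

spec = CohortSpec(n_subjects=6, epochs_per_state=10, n_channels=16, seed=11)
cohort = generate_cohort(spec)          # 180 labeled 10-s epochs
table, _ = extract_features(cohort)     # 60 features per epoch
report = train_evaluate(table, task="ternary", classifier="gboost", seed=11)
print(report.summary())
```

```
gboost (ternary task, classes: cognitive, normal, visual)
  CV accuracy (10-fold): 1.000 (+/- 0.000)
  Held-out test: Acc=1.000 P=1.000 Re=1.000 F1=1.000
  ROC AUC (one-vs-rest): cognitive=1.000, normal=1.000, visual=1.000
```

The synthetic cohort elevates θ- and β-band coupling under distraction
(with a nonlinear Hénon component marking cognitive epochs), so a clean
pipeline separates the three states essentially perfectly at this effect
size; the numbers above are the cross-validated and held-out accuracies
of the gradient-boosting model on those 180 epochs.

The same stages are available from the shell:

```bash
distractnet simulate --subjects 2 --epochs-per-state 3 --channels 16 --out cohort/
distractnet features cohort/manifest.tsv --out features.tsv
distractnet classify features.tsv --task ternary --classifier gboost
distractnet stats features.tsv
distractnet run-all config.yaml     # full pipeline from a YAML config
```

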