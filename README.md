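# oscnet

Band-specific oscillatory **network similarity** and **subject
fingerprinting** for multichannel electrophysiological recordings.

Large-scale oscillatory activity organizes into brain-wide patterns —
how power and functional connectivity distribute across the scalp — that
differ by frequency band, oscillation metric, and behavioral state, yet
are strikingly stable within an individual across hours to months.
`oscnet` provides the complete analysis chain for characterizing this
organization in sensor space, for researchers working with EEG-like
multichannel time series:

- **Network vectors.** For each data segment and band, a power network
  *V* (one dB value per electrode, length 60 on the reference cap) and
  connectivity networks *U* (one value per non-neighboring electrode
  pair, length 1,578 after excluding the 192 neighbor pairs of 1,770).
  Metrics: phase locking value
  `PLV_jk = |1/n · Σ_t exp(i(φ_j(t) − φ_k(t)))|`, Spearman amplitude
  envelope correlation, and the volume-conduction controls wPLI and
  orthogonalized envelope correlation. Connectivity vectors are +1
  shifted, Box-Cox transformed (per-vector λ on a grid over [−5, 5])
  and z-scored; power stays in dB.
- **Network similarity.** Pearson *R* between two network vectors —
  scale- and offset-invariant — aggregated RSA-style over labeled pair
  categories, with Monte-Carlo/exhaustive resampling nulls, z-based and
  permutation p-values, Benjamini-Hochberg FDR, group-level t tests, and
  MDS maps for visualization.
- **Classification.** kNN (k = 5, correlation distance, inverse-distance
  votes) for rest/task state decoding (leave-one-subject-out) and
  long-term subject identification (train on sessions A+B, test on the
  months-later session C; chance 1/21 ≈ 4.8% at full cohort size), with
  posterior fusion across the 12 network types (4 bands × 3 metrics),
  per-subject segment pooling, rest/task max-merging, binomial and
  label-shuffle permutation tests, network-size subsampling curves, and
  a per-electrode searchlight.
- **Synthetic data.** Deterministic generators for (a) multichannel
  signals with subject/state/session-structured mixing over band-limited
  sources plus 1/f noise, and (b) network-vector populations from a
  variance-components model with closed-form expected similarities — so
  the entire pipeline is testable without access to raw recordings.

## Worked example

```python
from oscnet import (VectorModelParams, generate_vectors, expected_similarity,
                    similarity_matrix, selector, aggregate, run_comparison_suite)
from oscnet.classify import identify_subjects

params = VectorModelParams(
    length=1578, v_group=1.0, v_subject=1.0, v_state=0.25, v_noise=1.0,
    n_subjects=6, bands=("alpha",), metrics=("plv",), seed=7,
)
vecs = generate_vectors(params)   # 6 subjects x 20 blocks across 3 sessions

sm = similarity_matrix(vecs)
within, n_w = aggregate(sm, selector("within-rest", same=("subject",), each={"state": "rest"}))
print(f"within-subject rest similarity: R = {within:.3f} over {n_w} pairs "
      f"(model predicts {expected_similarity(params, 'same-subject-same-state'):.3f})")

stats = run_comparison_suite(vecs, "within_subject_rest", q=0.05, seed=1)
print(stats[["unit", "observed", "baseline", "z", "p_z", "fdr_flag"]].to_string(index=False))

rep = identify_subjects(
    [v for v in vecs if v.session in ("A", "B")],
    [v for v in vecs if v.session == "C"],
)
print(f"cross-session identification: {100*rep['merged_identity_accuracy']:.0f}% "
      f"(chance {100*rep['chance']:.1f}%)")
```

prints

```
within-subject rest similarity: R = 0.696 over 720 pairs (model predicts 0.692)
 unit  observed  baseline         z          p_z  fdr_flag
sub01  0.702710  0.429891 12.209236 1.387420e-34      True
sub02  0.688706  0.429891 11.582513 2.527104e-31      True
sub03  0.695898  0.429891 11.904402 5.613255e-33      True
sub04  0.695150  0.429891 11.870897 8.382967e-33      True
sub05  0.688927  0.429891 11.592429 2.250921e-31      True
sub06  0.696429  0.429891 11.928150 4.221439e-33      True
cross-session identification: 100% (chance 16.7%)
```

Each subject's rest networks are far more alike (R ≈ 0.70) than random
selections from the population (baseline R ≈ 0.43, the null mean), every
subject survives FDR, the empirical similarity matches the
variance-components prediction, and the subject fingerprints carried by
the vectors identify every held-out session-C recording.

The same analyses run from the shell over simulated multichannel signals:

```bash
oscnet all --out-dir runs/demo --seed 3 --n-subjects 3 --n-channels 8 \
       --fs 128 --duration 20
```

executes simulate → features → networks → similarity → stats → classify
→ searchlight → report, writing tidy CSV/JSON artifacts plus a manifest
(config hash, seed, version) per stage. See `docs/methods.md` for the
model, parameter, and design documentation.

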