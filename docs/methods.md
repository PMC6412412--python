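# Methods

## Model and assumptions

`sipfft` treats self-interaction prediction as binary classification of
single proteins from their evolutionary profile. The working assumption is
that the information separating self-interacting from non-self-interacting
proteins is present in the *column structure* of the PSI-BLAST PSSM — how
conservation scores co-vary across the 20 amino-acid channels — rather than
in position-by-position detail. The Gram matrix A = MᵀM discards positional
order and sequence length while keeping exactly that co-variation (A is the
un-centred second moment of the profile columns), and the 2-D Fourier
modulus of A gives a descriptor that is invariant to the phase of any
periodic structure. The classifier makes no generative assumption: it is a
distance-based ensemble, so anything that moves the descriptors of the two
classes apart in Euclidean geometry is usable signal.

## Pipeline parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| PSSM block | log-odds | First 20 numeric columns of the ASCII file; this block is the per-position match score, and the percentage block is a rescaling of the same information. |
| Column order | `ACDEFGHIKLMNPQRSTVWY` | Taken from the file header and permuted to this canonical order on ingest so Gram matrices are comparable across files. |
| FFT normalisation | 1/N per axis | The DC coefficient then equals the matrix mean. The 400-vector is the complex modulus, flattened row-major; the modulus is the standard "spectrum" reading and yields exactly 400 real features. |
| PSSM scaling | none | Raw log-odds values enter the Gram product; a column z-scoring flag exists for experimentation but is off by default. |
| PCA q | 300, capped at min(n_train − 1, 400) | Fitted on training folds only (leakage-safe); `pca_global` reproduces a single whole-dataset fit. |
| B1 | 10 | Number of selected projections (ensemble size). |
| B2 | 30 | Candidates per non-overlapping block; B1 × B2 candidates are drawn independently from one seeded generator. |
| q (projection) | 5 | Projected dimension. Never stated by the source method; the random-projection-ensemble literature uses small q, and it is exposed prominently in `RpConfig`. |
| k grid | 1, 4, 7, …, 40 | KNN neighbourhood sizes scored by leave-one-out error; values ≥ n_train are dropped so small runs remain valid. |
| Projection law | Gaussian (Bernoulli ±1 optional) | Columns rescaled to unit l2 norm after drawing. `identity` is a test hook that reduces the ensemble to plain KNN at B1 = B2 = 1. |
| Voting threshold α | training prevalence of class 1 | Positive call iff the member vote fraction strictly exceeds α. The vote fraction is also the ROC score — it is the model's only continuous output. |
| SVM arm | RBF, c = 0.03, g = 1200 | The documented comparison setting, delegated to scikit-learn's libsvm. The unusually small c and large g make the arm degenerate (all-positive or all-negative calls) on unscaled spectral features; a `--scale` flag is not applied by default so the arm reflects the documented configuration. |
| Folds | stratified 5-fold, seeded | Arithmetic mean and sample (n − 1) SD across folds. Fold assignments can be shared across model arms for paired comparison. |

## Tie-breaking and degenerate cases

All stochastic and near-degenerate choices are deterministic and documented:

- equidistant KNN neighbours: lowest training index (stable sort);
- even-k vote ties: class 1 iff the training class-1 prior ≥ 0.5, else 0;
- candidate projections with equal minimal LOO error: earliest drawn;
- tied k values: smallest k;
- MCC with a zero denominator: 0 (conventional);
- sensitivity/specificity with an empty class: NaN, excluded from fold
  averages with a warning;
- ROC threshold convention: positive iff score > t, matching the ensemble's
  strict voting inequality; curves are anchored at (0,0) and (1,1) and AUC
  is the trapezoidal area (equal to Mann–Whitney concordance with ties = ½).

All randomness flows through a single `numpy.random.Generator`; a run is
bit-reproducible from (data, config, seed).

## Synthetic data: what it emulates and what it does not

The generator emulates length-filtered profile datasets (lengths uniform in
a configurable range, default 50–300 — the short end of the 50–5000
biological filter, chosen so test suites run quickly). Negatives are i.i.d.
Gaussian N×20 matrices (noise SD 1); positives add a sinusoidal positional
signal (default amplitude 5, period 8) to a 6-column subset drawn **once per
dataset**. The subset is class-level, not per-protein: a per-protein subset
would make positives mutually dissimilar and unlearnable by any
distance-based classifier, which would test nothing. The signal is periodic
in position by construction, so the FFT descriptor has a direct target while
covariance and DCT descriptors retain partial power — mirroring the
qualitative ordering of descriptor families, not their quantitative scores.
The imbalanced preset (144 positives : 1594 negatives) reproduces the human
SIP census ratio scaled down tenfold.

The generator does **not** mimic real PSSM marginal distributions, BLAST
score calibration, integer quantisation, or phylogenetic correlation between
proteins. Passing tests therefore demonstrate that the pipeline's mechanics
are correct and that it recovers planted spectral class structure; they say
nothing about accuracy on real proteomes, which depends on profile databases
this package deliberately does not ship.

## Problem sizes

Test and acceptance runs use balanced datasets of 200 proteins (100 + 100)
for end-to-end checks, 30–120 samples for unit-level properties, and the
scaled imbalanced set (1738 proteins) for undersampling and prevalence
checks; cross-validated runs average over 3–10 seeds. These sizes were
chosen so that the planted-signal recovery regime (signal-to-noise 5) is
clearly separated from the null while the whole suite stays interactive.

## Known limitations

- PSI-BLAST itself is not run; the package parses its output and offers the
  Dayhoff fallback (each row = the mutation-matrix row of the observed
  residue). The fallback carries no evolutionary information beyond the
  substitution prior.
- The SVD comparison extractor flattens U·S; this is one reasonable reading
  of an under-specified descriptor and is included only as a baseline.
- Real SIP benchmark datasets (assembled from DIP, BioGRID, IntAct,
  InnateDB, MatrixDB and UniProt with literature-level filtering) are out of
  scope; the documented filtering rules (length 50–5000, evidence
  requirements) inform the synthetic defaults only.
- With B1 = 10 members the vote fraction takes 11 distinct values, so ROC
  curves from the ensemble are coarse; AUC is still well-defined via the
  trapezoidal rule.
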