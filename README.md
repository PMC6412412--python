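# sipfft

Sequence-based prediction of **self-interacting proteins (SIPs)** — proteins
whose copies, expressed from a single gene, bind each other
(homo-oligomerisation). Experimentally cataloguing SIPs is slow, the known
positives are a small minority of any proteome (e.g. 1441 SIPs against 15,938
non-SIPs in a curated human set), and pair-level signals used for general
protein–protein interaction prediction (co-expression, co-localisation) carry
no information for a protein interacting with itself. `sipfft` implements a
purely sequence-profile-based predictor for this imbalanced one-protein
classification problem, together with the full evaluation protocol needed to
benchmark it.

## Method

1. **Profile.** Each protein is represented by its PSI-BLAST
   position-specific scoring matrix *M* ∈ ℝ^(N×20) (N = sequence length,
   columns = amino acids). A Dayhoff-mutation-matrix fallback builds a profile
   directly from the bare sequence when no PSI-BLAST output is available.
2. **Length-free descriptor.** The Gram matrix *A = MᵀM* (20×20, symmetric
   PSD) removes the length dependence. The 2-D discrete Fourier transform of
   *A*, normalised by 1/N per axis and taken in modulus, yields a
   400-dimensional spectral descriptor; DCT, SVD and column-covariance
   descriptors are available as comparison extractors.
3. **PCA.** The 400 features are reduced to 300 principal components (capped
   at min(n_train − 1, 400) for small datasets), fitted on training folds
   only by default.
4. **Random-projection KNN ensemble.** B1 = 10 projections are selected, each
   the best of a block of B2 = 30 random unit-column-norm candidates
   (Gaussian or Bernoulli ±1 law, projected dimension q = 5), ranked by the
   leave-one-out error of a k-nearest-neighbour base classifier over
   k ∈ {1, 4, 7, …, 40}. A sample is called a SIP when the fraction of
   members voting positive strictly exceeds α, the training prevalence of the
   positive class — the data-driven threshold that keeps the ensemble usable
   on imbalanced data.
5. **Evaluation.** Stratified 5-fold cross-validation with optional majority-
   class undersampling; accuracy, sensitivity, specificity, Matthews
   correlation coefficient and balanced accuracy (Sen + Spe)/2 per fold and
   as mean ± sample SD; ROC curves and trapezoidal AUC from the ensemble vote
   fraction (or SVM decision score). An RBF-kernel SVM arm (c = 0.03,
   g = 1200, via scikit-learn/libsvm) serves as the comparison baseline.

A fully seeded synthetic-PSSM generator provides class-structured datasets
(negatives: Gaussian noise profiles; positives: an added periodic positional
signal on a shared column subset) so that the entire pipeline is testable
offline, including end-to-end class recovery.

## Worked example

```python
from sipfft.synthetic import SyntheticSpec, generate_dataset
from sipfft.features import extract_features
from sipfft.rp_ensemble import RpConfig
from sipfft.evaluation import kfold_cv

profiles, labels = generate_dataset(
    SyntheticSpec(n_pos=100, n_neg=100, signal_amplitude=0.8, seed=7)
)
fm = extract_features(profiles, labels=labels, extractor="FFT")
report = kfold_cv(fm, RpConfig(seed=7), n_folds=5, seed=7)
print(report.to_markdown())
```

prints

```
| Fold | Acc. (%) | Sen. (%) | Spe. (%) | MCC (%) | B_Acc. (%) | AUC |
|---|---|---|---|---|---|---|
| 1 | 97.50 | 95.00 | 100.00 | 95.12 | 97.50 | 1.0000 |
| 2 | 90.00 | 80.00 | 100.00 | 81.65 | 90.00 | 0.9987 |
| 3 | 87.50 | 75.00 | 100.00 | 77.46 | 87.50 | 0.9600 |
| 4 | 97.50 | 95.00 | 100.00 | 95.12 | 97.50 | 0.9750 |
| 5 | 100.00 | 100.00 | 100.00 | 100.00 | 100.00 | 1.0000 |
| Average | 94.50 ± 5.42 | 89.00 ± 10.84 | 100.00 ± 0.00 | 89.87 ± 9.74 | 94.50 ± 5.42 | 0.9868 ± 0.0184 |
```

Each row is one held-out fold of a 200-protein synthetic dataset whose
positive class carries a weak periodic profile signal (amplitude 0.8 at noise
SD 1): the ensemble recovers the class at ~95% accuracy, perfect specificity
and AUC ≈ 0.99; at amplitude 0 the same pipeline sits at chance.

The same pipeline is available from the shell
(`sipfft simulate | extract | reduce | train | predict | cv | baseline-svm |
report`); a three-profile PSSM fixture for quick experiments ships in
`examples/fixtures/`:

```bash
sipfft extract --pssm-dir examples/fixtures \
    --labels examples/fixtures/labels.tsv --out features.tsv
sipfft cv --features features.tsv --model rp --model svm \
    --n-folds 5 --seed 7 --out cv.json      # paired fold assignments
```

For real proteins, generate profiles with PSI-BLAST (3 iterations, e-value
0.001) before extraction:

```bash
psiblast -query protein.fasta -db swissprot -num_iterations 3 \
    -evalue 0.001 -out_ascii_pssm protein.pssm
```

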