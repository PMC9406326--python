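# Methods

This note documents the models and procedures `cvfair` implements, the
choices made where the original study description is under-determined, and
what the synthetic-data results do and do not show.

## Domain conversion

Images are standardized per image — `(x − μ)/σ` over all pixels and
channels, population (divisor-N) standard deviation — before any network
sees them. The same per-image rule applies at train and test time, so no
statistics leak across cross-validation splits; a dataset-level variant
(training-split statistics) can be had by normalizing externally before
calling the pipeline. Resizing uses bilinear interpolation with
antialiasing on downsampling.

Real inputs enter the complex domain through the discrete Fourier
transform, written as multiplication by the Fourier/Vandermonde matrix
`F[j,k] = w_N^{jk}` with `w_N = exp(−2πi/N)`. The base is taken as the
standard unit-modulus DFT kernel: it is the only choice under which the
transform of a real signal has Hermitian symmetry, which the pipeline
relies on. The transform runs along the **width axis** of each row and
channel (a config option transforms both axes); only the first
`⌊W/2⌋ + 1` coefficients are kept — the non-redundant half of a real
signal's spectrum, reducing the component count to "almost half".
`reconstruct_real` rebuilds the full spectrum by conjugate symmetry and
inverts the transform; round-trip error is below 1e−8, so the reduction is
lossless. The O(N²) matrix product is used as-is; at widths ≤ 224 an FFT
would gain nothing that matters here.

Inside a network's forward pass the spectrum is additionally scaled by
`1/√W` (unitary normalization). This is pure input conditioning: without
it the low-frequency components are ~√W larger than the rest and the
complex network trains poorly. The library-level `to_complex_domain`
keeps the raw Vandermonde product.

## Complex layer algebra

A complex tensor is a pair of equal-shape real arrays. All layers are
expressed as real computations on the two components, so ordinary real
backpropagation trains the network and the two components of each weight
are learned jointly.

* **Convolution** uses the standard complex product
  `(a+bi)(c+di) = (ac−bd) + (ad+bc)i` accumulated over the kernel support
  (four real convolutions). The original formula as printed sums products
  of component sums and drops the `i²` sign; it does not define a complex
  product, so the standard one — which the brute-force native-complex
  oracle in the tests also assumes — is implemented. Orientation is the
  deep-learning cross-correlation convention; a `flip_kernel` flag gives
  true convolution (the two differ only by a kernel flip).
* **Activation** is zReLU: a value passes unchanged only when its real
  *and* imaginary parts are strictly positive, else 0. The boundary is
  excluded (strict inequalities) and the subgradient on the blocked set is
  0. A `split` mode (per-component ReLU) is available; see the embedding
  note below.
* **Average pooling** takes the arithmetic mean per window on each
  component, which by linearity equals the complex mean.
* **Dense layers** use the bilinear (non-conjugating) complex product.
  The conjugating Hermitian inner product is exposed as a flag but is not
  the default: conjugation is not what reference complex-network
  implementations compute, and it breaks the correspondence with the
  native-complex matrix-product oracle.
* **Readout**: class scores must be real. The modulus `√(Re² + Im²)` is
  the default; a real-part readout is available by configuration.
* **Biases** are complex on complex layers and present by default (the
  original description is silent on biases). All biases are initialized
  at 0.1: a small positive offset keeps the (z)ReLU gates open at
  initialization, which measurably improves early training of the complex
  network — with zero biases roughly 3/4 of zReLU units are dead at init.

**The zero-imaginary embedding.** With all imaginary parts zero, complex
convolution, dense products and pooling reduce *exactly* to their real
counterparts — the claim that a real network is the special case of a
complex one. At whole-network level the claim holds exactly only under the
`split` activation and real-part readout: zReLU blocks the entire real
line (Im = 0 never satisfies Im > 0) and the modulus folds the sign of
negative scores. The test suite therefore checks op-level reduction for
the default configuration and network-level equality (to machine
precision) under `split`/real-part.

## Architectures and parameter parity

Both structures share the schedule: 3 × (conv 3×3 same-padding → 2×2
average pool → activation), flatten, 3 dense layers, a 2-unit output.
Parity is assessed in **real scalars** (one complex weight = two scalars),
the only reading under which the published per-layer ledger's totals for
the two structures are "equivalent". The published per-layer counts cannot
be inverted to unique kernel/channel sizes, so the shipped architectures
reproduce the structural sequence and the parity criterion (τ = 0.10),
not the literal counts; the transcribed ledger itself is kept as data and
its aggregate complex-units/real-scalars ratio (≈ 0.476) is asserted in
the tests.

Because the Hermitian reduction halves the complex network's input width
(and hence its flatten size), simply scaling all real widths by √2 does
not balance the totals. Instead the real twin is derived by scaling all
hidden widths by a single factor found by bisection on the real-scalar
total; the shipped desk-scale pair (32×32 inputs, complex widths 8/16/32
conv and 64/32/16 dense) lands at ratio 0.996.

## Training and evaluation

* Stratified k-fold cross-validation, k = 10 by default. Stratification
  matters with 40 abnormal cases in 200: unstratified folds can lack
  positives entirely, making Recall/Specificity undefined.
* Both structures always see byte-identical splits and batch orders: the
  shuffling stream is seeded from (config seed, fold index) only.
* Optimizer: ADAM, learning rate 0.001, β = (0.9, 0.999), ε = 1e−8. For a
  complex parameter the first moments are per component and the second
  moment is shared, driven by the squared gradient modulus g_R² + g_I²,
  with the usual bias corrections. One step from zero state with
  g = 1 + 1i and lr = 0.001 moves each component by −0.001/√2 ≈ −0.000707.
* Loss: cross-entropy over the softmax of the 2 real class scores (the
  original description names no loss). Default 15 epochs, batch 16 — a
  desk-scale problem-size choice; both are configuration.
* Positive class = abnormal (label 1), the standard disease-detection
  convention. The published fold metrics are mutually inconsistent with
  any single prevalence under either labeling, so retraining to reproduce
  them is out of scope by design.
* Metrics: Precision TP/(TP+FP), Recall TP/(TP+FN), F1 harmonic mean,
  Accuracy (TP+TN)/total, Specificity TN/(TN+FP); zero-denominator ratios
  are reported as 0 with a warning flag. The decomposition identity
  `Accuracy = (P·Recall + N·Specificity)/(P+N)` is asserted on every
  evaluation.

## Statistical protocol

Per metric, Shapiro–Wilk (Royston algorithm) runs on both 10-value fold
samples; if both p ≥ α = 0.05 the means are compared with the classical
pooled-variance two-tailed Student's *t* (a Welch variant is exposed),
otherwise with the two-tailed Mann–Whitney *U* using the tie-corrected
normal approximation with continuity correction — at n = 10 with heavy
ties, exact enumeration is convention-dependent. A constant metric column
(a structure predicting one class in every fold, which does occur on
imbalanced synthetic data) cannot come from a non-degenerate normal
distribution and fails the gate outright; two all-tied samples retain H0.
"Confidence interval of 5%" in the source description is read as
significance level α = 0.05.

Each structure's ROC operating point is (1 − mean Specificity,
mean Recall); quality is the Euclidean distance to the ideal corner (0, 1)
and the better structure's relative superiority is
`100·(d_worse − d_better)/d_worse`.

## Known inconsistencies in the published tables

The packaged fold tables are transcriptions of the published per-fold
values. Recomputation (scipy, cross-checked against R) shows several of
the published *summary* values are inconsistent with the published fold
values themselves:

* The ISIC2017 complex-structure Max/Min/Mean Accuracy rows duplicate the
  Recall summaries and contradict the fold Accuracy values (~0.76–0.82);
  the PH2 complex-structure Accuracy *fold column* duplicates its Recall
  column while the summary and normality rows for it match neither.
* In the normality rows, the F1/Precision/Recall entries are rotated by
  one column relative to recomputation from the fold values; Accuracy and
  Specificity entries (and many in-place values) do reproduce to ~1e−4.
* The published mean-comparison p-values (with exponents read as negative)
  differ from recomputation on the fold values by large factors.
* Under recomputation the PH2 F1 and Recall real-structure samples fail
  the normality gate (p ≈ 0.016, 0.050), so the gate selects U for them
  where the published account names *t*. Every gated comparison still
  rejects H0, and the complex structure has the higher mean in all 15
  dataset/metric pairs — the qualitative conclusion is unchanged.

For these reasons the package never stores or trusts printed summary
rows: summaries are always recomputed from fold values, and the report
annotates gate divergences. The ROC distances and superiority recomputed
from fold-value means *do* reproduce the published headline numbers
(0.26127/0.36022/0.31681/0.29447 and 27.46–27.47 %) to the printed
precision.

## Synthetic data: what it shows and what it does not

The generators emulate the *statistical structure* of the study data —
class-imbalance ratios (1621/374, 160/40, 320/141), lesion-like regular
vs irregular central regions on a textured background, scalogram-like
periodic S1/S2 low-frequency energy with an optional murmur band — with a
single `separability` knob scaling every class-difference term, so that
separability 0 makes the class distributions identical. Scalar
discriminants (interior-tone heterogeneity for lesions, murmur-band mean
energy for scalograms) have class-mean gaps monotone in separability, and
8-bit images are bit-reproducible from the profile seed.

They do **not** model realistic dermoscopy appearance, hair/ruler
artifacts, wavelet scalograms of real auscultation audio, or
inter-patient variability. Passing the end-to-end tests therefore shows
the pipeline is correct and the comparison machinery behaves sensibly on
data with known structure — it does not certify clinical performance, and
the published fold values are not reproducible by desk-scale retraining
(external data, GPU-scale training, and the inconsistencies above).

## Problem sizes used by the tests

Desk-scale throughout: 32×32 (or smaller) images, the shipped
default pair, 15 epochs (25 for the high-separability smoke check), and
n = 200/class for distributional checks on the generators. A 224×224
configuration of the same architecture family is provided
(`paper_scale_pair`) but not exercised by the tests.
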