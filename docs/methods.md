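# Methods

This package implements single-trial P300 detection for speller
brain-computer interfaces: a bilinear spatial-temporal discriminant
("spatial-temporal linear feature learning", STLFL) that projects
multichannel EEG epochs to a small feature space, a hybrid discriminative
restricted Boltzmann machine (DRBM) that turns those features into P300
probabilities, and repetition-aggregated decoding of speller characters.
A seeded oddball-session simulator provides test data for every stage.

## The LFL criterion and its bilinear extension

An epoch is a matrix `X ∈ R^{C×T}` (C channels, T samples). The classic
Fisher discriminant maximizes `w'S_B w / w'S_W w` with between-class scatter
`S_B = (m2−m1)(m2−m1)'` and pooled within-class scatter `S_W`. The LFL
criterion modifies the numerator two ways:

    J(w) = w'(S_BN − β S_W)w / w'S_W w,
    S_BN = S_b1 + α S_b2,   S_bi = (m_i − m)(m_i − m)',

where `m` is the grand mean, class 1 is the P300 class (weight 1) and α
reweights the non-target class's between-class term; β subtracts a
within-class penalty inside the numerator. The maximizer solves the
generalized eigenproblem `(S_BN − β S_W) w = λ S_W w`. With α = 1, β = 0 the
top direction reduces exactly to the Fisher direction `S_W^{-1}(m2 − m1)`,
because `m_i − m` are antiparallel whenever `m` is the class-weighted mean —
this limit is asserted in the tests.

The spatial-temporal version learns a spatial projection `W ∈ R^{C×h}` and a
temporal projection `V ∈ R^{T×h}` by alternating that eigenproblem over the
two modes. With V fixed, the spatial pencil is built from the C×T
difference matrices sandwiching `VV'`:

    S_BN^(V) = Σ_i α_i (m_i − m) VV' (m_i − m)',
    S_W^(V)  = ⟨(X_n − m_class(n)) VV' (X_n − m_class(n))'⟩_n,

and symmetrically (transposed differences, `WW'`) for the temporal step.
This difference-matrix construction is the only dimensionally coherent
reading of a bilinear LFL and reduces to the plain criterion when one side
is the identity. Features are `f = vec(W'XV)` (column-major), dimension h².

Numerical choices:

- **Initialization**: V starts as the first h columns of the T×T identity.
- **Ridge**: the right-hand pencil gets `ε = ridge_scale · trace(S_W)/d`
  (default `ridge_scale = 1e-6`) so rank-deficient within-scatter
  (n_epochs < C·T) stays solvable.
- **Ordering and sign**: eigenpairs are sorted by descending algebraic
  eigenvalue (stable ties); each eigenvector's largest-magnitude entry is
  made positive, otherwise arbitrary sign flips would defeat the convergence
  test. Columns are normalized to unit 2-norm.
- **Convergence**: stop when both `‖W^(n)−W^(n−1)‖₂` and `‖V^(n)−V^(n−1)‖₂`
  drop below `tol = 1e-5`, or after `max_iter = 500` iterations. When h
  exceeds the rank of the class difference, the trailing columns live in
  near-degenerate noise eigendirections and can keep rotating; runs that hit
  the iteration cap are still usable (the dominant columns stabilize early,
  and `converged`/`convergence_trace` report the state). The seeded
  convergence property in the tests is asserted at h = 2, where the
  eigen-gaps are stable; parameter recovery at h = 4 checks only the leading
  column.
- **Defaults**: h = 4 (16-dimensional features), α = 1, β = 0; α, β are
  normally chosen by the grid/cross-validation search in `evaluation`
  (default grids α ∈ 1:0.2:5, β ∈ {0, 1e-4, 1e-3, 1e-2, 0.1, 0.3, 0.5, 0.7,
  1, 1.5, 2}).

### When does the fit "recover" a planted ERP?

The criterion maximizes class separation under the within-class metric, so
its optimum is the *whitened* direction `S_W^{-1}a`, not the planted loading
`a` itself. The two coincide only when the within-class covariance is
(near-)isotropic. Three realistic effects break that: temporally colored
noise, latency/amplitude jitter of the ERP (which puts large within-class
variance along the ERP pattern itself), and slow compensation tails that a
0.1 Hz high-pass adds around large deflections. The parameter-recovery
experiment therefore uses the identifiability regime — deterministic
template, temporally white noise, stimulus-onset asynchrony long enough that
epochs do not overlap, and decimated epochs so the within-scatter is
well-estimated — where the Fisher optimum provably aligns with the planted
pair. Under those conditions the fit recovers both directions with
|cos| ≥ 0.95 in 20/20 seeded runs. Outside that regime the deviation from
the planted directions is a feature of discriminant analysis, not an error.

## Hybrid DRBM classifier

The classifier is an RBM with a class unit: visible units x (the STLFL
features, z-scored and modeled as Gaussian with unit variance), H binary
hidden units and a one-hot class y over K = 2 classes. The class posterior
is closed-form,

    p(y|x) ∝ exp(d_y) Π_j (1 + exp(c_j + U_yj + W_j·x)),

so the discriminative loss `−Σ log p(y|x)` has an exact gradient (verified
against finite differences and brute-force enumeration over all 2^H hidden
configurations). The hybrid objective adds a generative term,
`L = L_disc + γ L_gen`, with `L_gen` approximated by contrastive divergence
(CD-k, default k = 1; the negative-phase visible state is sampled from the
Gaussian conditional). Training is seeded mini-batch gradient descent.

Defaults: H = 5 hidden units (matched to the 16-dimensional STLFL
features), γ = 0.01, learning rate 0.05, batch 32, weight init N(0, 0.01²),
500 training epochs for standalone use and 100 inside the end-to-end
pipeline (the small feature space converges quickly). These are package
choices; only the hidden-layer size is inherited from the method this
package implements.

## Decoding and metrics

Per-epoch P300 probabilities are summed per stimulus code over the first m
repetitions, `C(j) = Σ_k S_j(k)`; sum and mean are argmax-equivalent since
every code flashes once per repetition. The matrix speller intersects the
winning row and column in a row-major 6×6 layout ("A–Z", "1–9", "_");
RSVP picks the winning group of nine. Ties break to the lowest code index.

Information transfer rate uses the standard bits-per-selection formula

    bits = log2 N + P log2 P + (1−P) log2((1−P)/(N−1)),
    ITR  = 60 · bits / T_char,

with `T_char = 2.5 + 2.1·rep` seconds for the matrix speller (12 flashes of
175 ms per repetition plus a 2.5 s inter-character pause). For RSVP no
selection-time formula is hard-coded; `T_char` is an explicit argument.
Feature separability is the squared pointwise biserial correlation,
`r = √(N1 N2)/(N1+N2) · (mean1 − mean2)/std_all`, with the population SD
(making r exactly the Pearson correlation with the binary label).
Accuracy tables report the sample SD (ddof = 1; 0.0 for a single session).

Hyperparameter search evaluates the full fit→score pipeline on a grid over
(α, β), either k-fold cross-validation or a seeded holdout. Folds are
stratified at the character-trial level so flashes of one character never
straddle train and validation — the only split that does not leak the
repetition structure.

## The synthetic session generator

The simulator emulates the two standard speller recordings:

- **Matrix speller (RCP)**: 6×6 grid, rows+columns flash once per
  repetition in seeded random order (100 ms flash, 75 ms ISI, 2.5 s pause
  between characters; 12 flashes/repetition, up to 15 repetitions → 180
  flashes per character), 64 channels at 240 Hz by default.
- **RSVP**: 9 groups of 3 symbols, one flash each per repetition (230 ms
  stimuli, no ISI). The inter-character pause defaults to 0.15 s, which
  makes a 45-stimulus trial last ≈10.5 s.

Targets receive a Gaussian-in-time ERP (peak 300 ms, SD 60 ms) loaded on
the last third of the channels (a crude centro-parietal proxy), with
per-flash latency jitter (SD 20 ms) and multiplicative amplitude jitter
(SD 0.2). Overlapping responses add linearly. Background noise is
per-channel AR(1) (coefficient 0.95) mixed by a random orthogonal matrix;
the mixing uses its own seed stream so spatial structure is constant across
an SNR sweep. SNR is defined as planted-ERP power over noise power within
the epoch window, in dB; the default of −15 dB was chosen so that
single-repetition decoding accuracy with ~20 training characters falls in
the 30–50% range reported for real matrix-speller recordings, and is held
fixed across all experiments.

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationarity across a session, inter-subject variability, realistic
scalp topographies or volume conduction, and SSVEP flicker. Passing tests
therefore demonstrate algorithmic correctness and the expected qualitative
behaviour (chance calibration, SNR monotonicity, small-training-sample
advantage of the bilinear method over vectorized Fisher), not clinical
performance on real EEG.

## Preprocessing

Zero-phase (forward-backward) filtering preserves P300 latency: a
third-order 0.1–30 Hz Butterworth for the matrix-speller profile, a
linear-phase FIR (order 3·fs/low-edge) at 0.5–25 Hz for the RSVP profile.
Epochs are half-open windows `[onset, onset + window)` of
`floor(window·fs)` samples (667 ms and 1 s respectively). Decimation trims
the epoch to a multiple of the factor and applies a polyphase
anti-aliasing FIR, so the output length is exactly `floor(T/factor)`
(e.g. 160 samples at 240 Hz → 26 samples at 40 Hz). Epoching precedes
decimation. Class balancing replicates minority (target) epochs — whole
copies plus a seeded without-replacement remainder — and is applied to
training data only; test data keeps its true flash stream for decoding.

## Experiment sizes

The bundled experiments are sized to run on one CPU in minutes: parameter
recovery uses 10-channel, 10-character sessions over 20 seeds; the
small-training-sample comparison uses 16 channels, 20 training + 10 test
characters, 5 repetitions, 20 seeds; chance calibration decodes 1000
schedule-only characters. Channel counts below the real 64-channel montage
leave the planted spatial structure (one loading vector) unchanged.

## Known limitations

- The DRBM's generative term uses CD-1 with Gaussian visibles; it is a
  regularizer here, not a calibrated density model.
- Alternating eigensolves carry no global convergence guarantee; see the
  convergence notes above.
- The α-class assignment ("α multiplies the non-target between-class term")
  follows one reading of an ambiguous convention; `_pencil` keeps it in one
  place should the opposite assignment be wanted.
- Real-time operation, artifact handling and transfer across subjects are
  out of scope.
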