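# Methods

`chemofdt` analyses slow activity fluctuations of the *E. coli* chemosensory
network as read out by single-cell ratiometric FRET between the response
regulator CheY-YFP and its phosphatase CheZ-CFP.  The FRET ratio is a linear
reporter of the relative kinase activity A ∈ [0,1] of the receptor–kinase
arrays, R = λA + μ, sampled at 1 frame/s.  The package provides (i) a
mechanistic stochastic model of a clustered receptor array, (ii) calibrated
synthetic single-cell ensembles standing in for recorded data, (iii) the
spectral estimators (ensemble PSD, autocorrelation, Parseval variances,
conversion factor, activity sorting), and (iv) the fluctuation–dissipation
(effective-temperature) analysis with a thermal/methylation noise
decomposition.

## Mechanistic array model

The receptor array is coarse-grained into independent *signaling teams* of
N allosteric units (trimers of receptor dimers; defaults N = 14,
N_T = 10⁴ receptor dimers per cell, hence ⌊N_T/3N⌋ = 238 teams).  Each team
is a two-state (ON/OFF) variable.  The team free energy per trimer is
f = f0 − m·ε_m + L(t) + η(t) (k_BT units), amplified N-fold at team level;
the equilibrium ON probability is A_eq = 1/(1 + e^{N·f}).  Switching is a
telegraph process with rates k_off→on = A_eq/τ_eff and
k_on→off = (1−A_eq)/τ_eff, so the stationary law is the Boltzmann
equilibrium and the relaxation time is the effective cluster response time
τ_eff regardless of the operating point.  With the enzymes off this process
satisfies detailed balance exactly — the property the
fluctuation–dissipation validation requires — and its two-sided activity
PSD is the Lorentzian 2A_eq(1−A_eq)τ_eff/(1+ω²τ_eff²) per team.

CheR/CheB molecules (defaults n_R = n_B = 140 per cell) bind from shared
free pools: a free CheR binds an unbound *inactive* team at rate k_bind per
enzyme (default 0.01 s⁻¹, i.e. a ~1 s search time across the array),
methylates it at k_cat (default 0.3 s⁻¹, m capped at m_max = 8 per trimer)
while bound, and unbinds at the first step the team turns active; CheB acts
symmetrically on active teams.  Only one enzyme can occupy a team.  These
kinetic defaults are order-of-magnitude choices (receptors far outnumber
enzymes; binding fast compared to switching); they are deliberately not
calibrated to the measured adaptation rate, so all mechanistic
enzyme-related tests compare against the *emergent* adaptation rate of the
simulation rather than a literature value.  An optional OU free-energy
noise term (σ_F, τ_F; default off) lets users add slow thermal free-energy
fluctuations beyond the intrinsic switching noise.

Integration uses a fixed step dt = 0.05 s with exact OU updates and
per-event Bernoulli draws; any per-step event probability above 0.2 raises
an error rather than silently coarsening the dynamics.  Output is
subsampled to the 1 Hz acquisition grid.  Known limitation (by
construction): independent teams underestimate the absolute fluctuation
amplitude of real arrays, so amplitude-calibrated quantities are assigned
to the phenomenological generator below.

## Synthetic FRET ensembles

The phenomenological generator produces the ratio directly:
R_t = (μ + λ·a(t) + λ·√(4a(1−a))·x_t)(1 − β t) + w_t, with x_t a stationary
OU process (correlation time τ, variance V_A at a = 1/2), w_t white
measurement shot noise, a(t) the deterministic activity level set by the
stimulation protocol, and β an optional bleaching drift (default 0).  The
√(4a(1−a)) factor makes fluctuations vanish at zero and saturating
activity, as observed.  The ratio is deliberately an unbounded Gaussian: an
activity variance of 0.46 at mean ≈ 1/2 exceeds what any [0,1]-bounded
variable can carry, so amplitude-calibrated ensembles can only be generated
at the ratio level; the mechanistic model keeps activity bounded.

Fixture registry (conditions, not dials): `wt_buffer` (Ā = 0.5, V_A = 0.46,
τ = 9.5 s), `rb_minus_intermediate` (V_A = 0.25, τ = 34 s),
`rb_minus_qeqe_protocol` (fully active in buffer, half active at 30 µM
MeAsp, inactive at 100 µM; protocol buffer→30 µM→buffer→100 µM→buffer),
`chewx2` (responsive mean, no slow fluctuations), `receptorless` (shot
noise only), `beads` (constant channels, lower shot), a small-drift
bleaching variant, and `mech_*` fixtures that delegate to the array model.
λ = 0.10 and the shot level are the measured study constants; μ = 1.0 is a
convention (only differences and the R̄-normalized spectra matter; all
derived quantities are reported in ratio units via the ensemble ⟨R̄²⟩, see
below).  Shot noise is calibrated so that the PSD estimator applied to the
receptorless fixture yields the flat floor ε_n² = 0.9×10⁻³ (σ_shot =
√ε_n² ≈ 0.030 per frame at 1 Hz).  MeAsp concentrations map to ligand free
energy per trimer through the standard two-constant form
ln((1+c/K_I)/(1+c/K_A)) with K_I = 18 µM, K_A = 2900 µM (package
conventions, config-exposed).

The paired adaptation fixtures used by the noise decomposition share one
thermal parameter set: the enzymes-off member is the passive OU (τ = 34 s,
V = 0.25); the enzymes-on member passes the same thermal process through
the two-state adaptation filter H(ω) = (iω + α·ω_RB)/(iω + ω_RB)
(ω_RB = 0.06 rad/s, α = 0.1) and adds a methylation component constructed
as an OU process with correlation time 1/ω_RB high-passed at ω_RB — its
spectrum ∝ ω²/(ω²+ω_RB²)² peaks exactly at ω = ω_RB (ω/2π ≈ 0.0095 Hz) —
with variance set so the total activity variance matches the wild-type
0.46.  This encodes the physical picture that the intermittent binding of
the few CheR/CheB molecules drives activity noise banded around the
adaptation rate.

What the generator does *not* emulate: image formation and segmentation,
channel-level photophysics (Poisson emission, bleed-through), cell-cycle
drift, or cell-to-cell parameter variability beyond what a fixture
explicitly injects.  Passing tests therefore validate the estimator chain
and the model logic under the stated noise structure, not robustness to
every artifact of real recordings.

## Spectral estimation

Per cell, the PSD is estimated on non-overlapping 400-frame segments as
s(f_k) = |R̂_k|²/(T·R̄²), k = 1..T/2 (DFT R̂, segment mean R̄, DC excluded),
averaged over segments then cells, with SEM across cells.  No window
function or detrending is applied by default (drift is handled by
subtracting the noise reference PSD; a linear-detrend flag exists for
bleaching data).  The discrete Parseval identity
(1/T)Σ_{k≠0} s_k = var(R/R̄) holds exactly per segment and is tested to
1e-12.  The ACF is the inverse DFT of the ensemble PSD (Wiener–Khinchin).

Because the segments are mean-normalized with the DC bin removed, all
spectra are natively in units of (R/R̄)².  Variances, the FDT comparison
and the decomposition rescale each ensemble's spectrum by its measured
⟨R̄²⟩ so that quantities are reported in ratio units (⟨ΔR²⟩ is the variance
of R itself, and the shot floor cancels exactly between strains with
different mean ratios).  For ensembles with R̄ = 1 the rescaling is the
identity.

Correlation times are fitted as C0·e^{−t/τ0} for t > 0 (C0 free, so the
white shot-noise spike at lag 0 does not bias the amplitude).  The default
fit propagates the exponential family *through the estimator*: removing the
segment mean (equivalently the DC bin) subtracts ≈ 2τ/T of the variance
from all lags, which biases a naive exponential fit short by ~5% at
τ = 9.5 s and ~25% at τ = 34 s for T = 400.  The fitted model is therefore
the expected DC-excluded circular sample ACF of an exponentially correlated
process, computed exactly from the triangular-windowed autocovariance; the
bare exponential remains available (`model="exp"`) and is exact on ideal
exponential input.  Fits on non-decaying input (white noise) are flagged as
failed rather than returning a silent τ.

Parseval variances floor negative shot-corrected bins at zero and report
the floored mass.  λ is estimated as the cell-averaged difference between
buffer-window and saturating-window mean ratios, excluding 20 s around
valve events; cells responding below 10% of the population response are
discarded as unresponsive.  Activity sorting uses
A = 1 − (R̄_pre,30 − R̄_30)/(R̄_pre,100 − R̄_100) with equally populated
subpopulations for n ∈ {10, 9, 6, 5, 4}; all (n, bin) points enter one
regression of the low-frequency PSD on A(1−A).

## Step responses and the adaptation link

The normalized step response is g(t) = ΔR(t)/(−λ·X_A∞·ε0) with
X_A∞ = N⟨A⟩(1−⟨A⟩); stimuli with a late-time activity change beyond 30% of
⟨A⟩ are refused (linear-response regime).  Since g does not decay, its
transform is defined through the impulse response: ĝ(ω) = FT[g′](ω)/(iω),
evaluated by trapezoidal quadrature; at 1 Hz sampling this reproduces the
closed form Re ĝ = −τ/(1+ω²τ²) of an exponential response to <1% below
0.05 Hz (discretization grows toward Nyquist).  An optional boxcar
smoothing of g before differentiation is available; its spectral
attenuation is common to any two spectra computed at the same width and
cancels in transfer ratios.

The enzymes-on and enzymes-off responses are linked by the two-state
adaptation filter H(ω) = (iω + α·ω_RB)/(iω + ω_RB) (α = residual unadapted
fraction; α = 0 is perfect adaptation).  `fit_adaptation_link` fits
(ω_RB, α) by time-domain least squares of the filtered g₋ against g₊,
after smoothing both with a common 9 s boxcar: without it, on noisy
independent measurements the optimizer is rewarded for driving ω_RB large
purely because the filter's low-pass action suppresses measurement noise.
The boxcar commutes with H, so clean inputs are still inverted exactly (up
to percent-level window-edge effects); when g₊ is constructed from the same
measured g₋ (shared noise), the unsmoothed fit is unbiased and is used.
ω_RB is carried in rad/s; its magnitude (0.06-scale) is what is
conventionally printed, with the corresponding ordinary frequency
ω_RB/2π ≈ 0.0095 Hz.

## Fluctuation–dissipation analysis

The effective temperature is defined by T/T_eff(ω) = G_R(ω)/(s_R(ω) − ε_n²)
with ε_n² taken from the receptorless-ensemble spectrum (per-bin
subtraction), evaluated on the contiguous band from the lowest frequency
where the corrected spectrum exceeds 3×SEM.  The dissipation is
G_R(ω) = −pref·Re ĝ(ω); a passive decaying response gives positive G.  Two
prefactor groupings ship:

* `paper_eq2`: (2λ²/(3N²))·⟨A⟩(1−⟨A⟩)·N_T — the printed Ising-like
  constant; it depends on (N, N_T) only through N_T/N², which is why
  fluctuations are insensitive to receptor expression when N²/N_T is
  conserved.
* `oracle_calibrated`: 6λ²⟨A⟩(1−⟨A⟩)·N/N_T — derived in closed form so
  that the analytic equilibrium telegraph array (Lorentzian PSD,
  exponential response, N_T/3N teams, unit mean ratio) returns
  T/T_eff ≡ 1 exactly.

The two differ by the constant N_T²/(9N³) (logged on every run).  The
equilibrium-unity validation uses the calibrated mode; with the default
parameters the printed grouping is not self-consistent for the
independent-team model — the same model-amplitude gap noted above — and the
dual mode keeps that visible instead of hiding it in a fitted constant.
The divergence frequency (T_eff → ∞, T/T_eff crossing zero) is located by
linear interpolation of the first in-band sign change whose new sign
persists for at least two bins; isolated single-bin flips at the noisy band
edge are not counted.

The adapted-cell spectrum decomposes as s⁺ = s_m + |ĝ₊/ĝ₋|²·s⁻ with s_m
defined as the residual (the identity s_m + s_T = s⁺ is exact by
construction).  The bin-wise transfer |ĝ₊/ĝ₋|² is unbiased only at high
response signal-to-noise: noise in the denominator inflates the ratio where
|ĝ₋| has decayed and over-subtracts the thermal part, tilting the apparent
methylation peak low.  The peak-frequency analysis therefore evaluates the
transfer from the fitted adaptation link, |H(ω; ω̂_RB, α̂)|², passed through
the `transfer` argument; bins with degenerate |ĝ₋| are masked, and the peak
search applies a 3-bin Hampel despike (single-bin blow-up protection)
before the argmax.

## Problem sizes and numerical choices

Analyses and acceptance runs use desk-scale ensembles chosen from measured
estimator noise: 200 cells × 1800 s for correlation times and variances
(τ0 recovery within ~5%), 200 cells for λ (±0.5%), 1000 passive
mechanistic cells for the adaptation-rate link (fit s.d. ≈ 4%), 400-cell
paired ensembles plus 1000-cell step ensembles for the decomposition peak
(readout stable to within one frequency bin of the T = 400 grid), and
50-cell fluctuation + 200-cell step mechanistic runs for the
effective-temperature pipeline.  Free energies are clipped at ±700 k_BT
before exponentiation; RNG streams derive from `numpy` `SeedSequence`
spawning, making every fixture bit-reproducible from (name, n_cells, seed).

## Known limitations

* Independent teams underestimate absolute mechanistic fluctuation
  amplitudes; amplitude targets live in the calibrated generator.
* The enzyme kinetics defaults give an emergent adaptation rate faster than
  the measured 0.06 rad/s; mechanistic enzyme tests are self-consistent
  (relative to the emergent rate) rather than absolute.
* The derivative-transform spectra degrade above ~0.05 Hz at 1 Hz sampling;
  all FDT statements are restricted to the above-noise band.
* The ACF fit's estimator-consistent model assumes a single-exponential
  process; multi-timescale mixtures will return an effective τ0, as any
  single-exponential fit would.
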