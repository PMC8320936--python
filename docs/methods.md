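# Methods

## Forward model (simulator)

The simulator emulates a spectrometer-based SD-OCT system: a Gaussian
source envelope S(λ) with centre wavelength λ₀ = 850 nm and FWHM
Δλ = 55 nm, sampled by a line camera on a grid *uniform in wavelength*
over λ₀ ± 1.6·Δλ (1024 pixels by default). Uniform-in-λ sampling is
deliberately nonuniform in wavenumber, so the reconstruction's
k-linearization step does real work; real spectrometers behave the same
way.

For reflectors r at one-way air-equivalent optical depth z_r (µm) with
intensity reflectivity R_r, the noiseless camera line is

    I(λ) = S(λ) · [ 1 + Σ_r 2√R_r · cos( 2 k n z_r(t) ) ],   k = 2π/λ,

with n the medium refractive index. Axial motion adds a displacement
d(t) projected onto the beam by cos θ: z_r(t) = z_r + cos θ · d(t)·10⁻³.
Motion models are a sinusoid d(t) = a·sin(2πft + φ₀) (a pure-tone
stimulus; f = 0 is the control) and a constant-velocity drift used to
characterise fringe washout.

**Exposure and washout.** Each line integrates over an exposure window
τ = exposure_fraction × line period (default 0.9 × 100 µs). The simulator
averages the instantaneous fringe pattern over `exposure_oversampling`
midpoint sub-instants spanning the window (default 16; 32 in washout
studies). This sub-sample averaging *is* the washout model — it is exact
for arbitrary motion as the oversampling grows, and the closed-form
attenuation |sinc(Δφ_exp/2)| for linear drift (Δφ_exp = round-trip phase
excursion per exposure) is used as an independent oracle in the tests
rather than as the implementation. The midpoint rule's residual error at
oversampling 32 and Δφ_exp = π is ~4·10⁻⁴, far below the 2 % tolerance
the washout tests use.

**Noise.** Additive Gaussian noise with standard deviation
`noise_sd` × envelope peak (default 10⁻³), seeded through
`numpy.random.default_rng`. Shot-noise scaling, speckle, dispersion
mismatch and galvo distortion are deliberately not modelled: the
generator exists to exercise the *phase* pipeline, and these effects
would add realism to the magnitude statistics without changing the
phase contracts under test. Consequently, passing tests demonstrate
correctness of the estimator and pipeline on this idealised interferogram
class, not performance on speckled in vivo data.

**Timing convention.** A-line j starts at t = j × line period and the
frame records these start times. Because the exposure average centres
the effective sampling instant, analytic phase predictions evaluate the
motion at t + τ/2.

**Default phantom.** Three reflectors emulate the middle-ear geometry:
thick tympanic-membrane fold (150 µm, R = 0.05), malleus (250 µm,
R = 0.2), thin membrane (350 µm, R = 0.02); n = 1, θ = 0. Depths sit
well inside the ~1.04 mm unambiguous range of the 1024-pixel grid and
are spaced so their mutual-interference (autocorrelation) terms at 100
and 200 µm fall outside every ROI.

## Reconstruction

Per frame: (1) background subtraction; (2) k-linearization by cubic
spline (linear optional) from the λ grid onto a k-uniform grid with the
same endpoints and pixel count; (3) apodization (Hann default, none or
Gaussian optional); (4) orthonormal FFT along the pixel axis, zero-padded
×2, positive-depth half kept; (5) 20·log₁₀ magnitude with a 10⁻¹² × peak
offset, clipped to a display range (default: peak down to peak − 60 dB)
for the structural image. Depth bins are air-equivalent:
z_m = π·m / (N_fft·δk), about 1.02 µm per bin at the defaults.

**Background choice.** The subtract-background operation defaults to the
per-pixel mean over A-lines, which is correct when lateral scanning
decorrelates the structure across the frame. The phantom here is not
scanned — a static sample gives identical A-lines, and the frame mean
*is* the signal — so the pipeline instead subtracts the source envelope
(the reference-arm-only spectrum a real system records as calibration).
Both behaviours are exposed on the same function.

**Phase reference.** After the FFT the spectral phase is re-referenced to
the centre of the k grid, so a reflector peak carries phase 2·k_c·(n z)
with k_c the band-centre wavenumber. Adjacent-line phase differences are
then Δφ = 2 k_c n cos θ · Δz — i.e. the effective Doppler wavelength is
the harmonic band centre (≈ 841 nm for this grid), about 1.1 % from λ₀;
velocity conversion uses λ₀ by convention, and this 1 % systematic is
visible in (and accepted by) the recovery tests.

## Doppler estimation

The Kasai estimator computes arg Σ conj(z_{m,n})·z_{m,n+1} over an
M (depth) × N−1 (A-line-pair) window, implemented with cumulative-sum box
sums and verified to 10⁻¹² against literal Python loops. Conventions:

- Window centred on the output pixel; at borders it shrinks to the
  in-bounds part (no data fabrication). A `strict` edge policy rejects
  windows larger than the image.
- Output range (−π, π], with the −π branch mapped to +π so the
  antiphase case is deterministic.
- Sign: motion that increases the optical path (away from the sample
  arm) gives positive Δφ, matching Δφ = (4π n_t cos θ/λ₀)·Δz.
- No phase unwrapping; excursions beyond ±π alias, by design.
- Defaults M = N = 4 for imaging. For *vibrometry time series* the demo
  configuration uses N = 2 (depth-only averaging): at a 10 kHz line rate
  a lateral window of 3 pairs spans 0.3 of a 4 kHz cycle and smears the
  waveform whose amplitude is being measured.

f_D = Δφ·f_a/2π with f_a the A-line rate: the published formula names
the *time interval* between lines, but dimensional consistency requires
the rate, and the package uses the rate throughout. Velocity
v = λ₀ f_D/(2 n_t cos θ) is applied element-wise; the Nyquist limit is
f_a/2 (5 kHz at 100 µs) and apparent frequencies fold as
|f − round(f/f_a)·f_a|.

Doppler pixels are gated by a structural-intensity mask (default: within
40 dB of the image peak), applied pairwise (both A-lines of a pair must
pass).

## ROI vibrometry

The ROI statistic is the mean of |Δφ| over valid pixels, dividing by the
count of valid pixels only; an ROI with no valid pixels is an error, not
a silent zero. The absolute value is used because a sinusoid's signed
phase averages toward zero across a frame while the plotted quantity is a
positive "phase variation"; a signed mode is kept as an option. Control
subtraction removes each ROI's 0 Hz baseline (the control column becomes
exactly zero). Sweeps run 10 replicate synthetic samples by default —
mirroring a 10-ear study design — and report min/max across replicates
as error bars; every (replicate, frequency) cell draws its own seed from
a SeedSequence of the master seed, so sweeps are bit-reproducible.

**Demo stimulus amplitudes.** No displacement calibration exists for a
92 dB tone at the eardrum, so amplitudes are free inputs. The packaged
demo injects nm-scale amplitudes with a maximum at 4 kHz
(40/60/100/70/50 nm at 1/2/4/6/8 kHz), a resonance-like profile chosen
once so the end-to-end sweep has a known ground-truth argmax; the package
makes no claim about actual tympanic-membrane mechanics, whose resonance
is an experimental finding the simulator takes as input, not a model
output. The 6 kHz condition, like 8 kHz, lies above Nyquist and folds
(6 → 4 kHz apparent, 8 → 2 kHz).

## Numerical choices and problem sizes

- Cubic spline for fringe resampling: standard accuracy/smoothness
  trade-off; its error floor on the default grid is below −50 dB,
  under the −31 dB Hann sidelobe the apodization tests measure.
- FFT zero-padding ×2 halves depth-bin quantization in peak-location
  tests; padding beyond that buys nothing the tests need.
- log-scale offset 10⁻¹² of peak: keeps the log finite without visible
  bias.
- Dominant-frequency readout: Hann-windowed, 16×-padded FFT of the
  phase trace with parabolic peak interpolation (sub-Hz resolution on
  ~0.1 s traces).
- Suite problem sizes — 1024-pixel spectra, 256-A-line frames (1024 for
  the aliasing study), 10-replicate sweeps, 200-trial variance studies —
  were chosen as the smallest sizes at which the measured quantities are
  stable to well under their test tolerances.

## Known limitations

- No speckle, shot noise, dispersion, conjugate-artifact removal, or
  bulk-motion correction; no transverse/vector Doppler; single-frame
  (intra-B-scan) Doppler only.
- The simulator's phantom is not laterally scanned, so frame-mean
  background subtraction degenerates on it (see Background choice).
- Velocity conversion uses λ₀ while the phase reference is the band
  centre: a ~1 % systematic at this bandwidth, growing with fractional
  bandwidth.
- Real-time concerns (GPU kernels, ring buffers, multithreading) are out
  of scope; the batch pipeline is contract-equivalent on whole frames.
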