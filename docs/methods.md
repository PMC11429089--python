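# Methods

This note records the models behind `mammoq`, the defaults and why they
were chosen, what the synthetic acquisitions do and do not emulate, and the
numerical choices that matter for reproducing its outputs.

## Acquisition model

The simulator produces linear "for processing" images of a PMMA QC phantom
on an amorphous-selenium flat panel. The expected signal at pixel (x, y) is

    mean(x, y) = offset + gain · mAs · heel(x, y) · exp(−Σ_m µ_m t_m(x, y)),

blurred by a Gaussian presampling PSF, followed by one noise draw per
pixel: Gaussian quantum noise with variance `quantum_gain · (mean − offset)`
(the Gaussian limit of a gain-scaled Poisson process) plus additive
electronic noise, clipped at zero. Insert boundaries are rendered with
4-fold sub-pixel coverage so the Cu edges carry genuine sub-pixel phase for
slanted-edge analysis. Blur is applied to the mean map *before* noise;
the noise is therefore white by construction, which keeps the presampled
MTF and the NPS independently measurable. The blur-induced noise
correlation of a real detector is deliberately not modelled.

**Spectral model.** Transmission is monoenergetic-equivalent Beer–Lambert
with *effective* per-material attenuation (defaults: PMMA 0.060 mm⁻¹,
Cu 0.654 mm⁻¹, Al 0.60 mm⁻¹). These are emphatically not narrow-beam
coefficients at a mammographic energy (Cu would be ~9 mm⁻¹); they are
effective values chosen once so that the *realised* behaviour matches a
clinical W/Rh system: the AEC inflates mAs by ~80 % when its sensor is
under the 1 mm Cu plate, and the Al square images at relative contrast
C = 1 − e^(−µ_Al·0.2) ≈ 0.11. Everything the analysis chain measures
depends only on realised contrast and noise, not on the spectrum, so this
replacement is exact for the package's purposes.

**Heel effect.** Field non-uniformity is a multiplicative profile along
the chest-wall → nipple axis times a small lateral tilt, normalised to a
maximum of 1. The axial shape is a sequence of flat plateaus joined by C¹
smoothstep transitions — chest-wall plateau 1.112, centre plateau 1.0,
nipple plateau 0.54 (row fractions 0–0.15, 0.42–0.60, 0.85–1.0), lateral
tilt 5.8 % → 8.7 % of the field across the image width. The plateau levels
were calibrated once so the five-ROI flat-field SNR pattern shows the
corner behaviour of a real upright unit (chest-wall corners a few percent
above centre, nipple corners ≈ 25–30 % below). The plateau stylisation is
deliberate: at desk scale a smooth profile steep enough to produce those
corner ratios would put a deterministic ramp *inside* the 64-px analysis
ROIs, and the ramp rather than the noise would then dominate the ROI
standard deviation. Real heel profiles are smooth; what is preserved here
is the ROI-level statistics, not the between-ROI shape.

**AEC servo.** Seven sensor footprints sit along the chest-wall → nipple
axis; with the default layout positions 1–2 are fully and position 3 is
~70 % covered by the Cu plate, positions 4–7 are clear of it. The servo
returns the mAs that drives the mean expected signal over the footprint to
a target (500 counts above offset), rounded to a 0.5 mAs quantum and capped
at 500 mAs, with kVp from a thickness lookup (28 kVp for the 40–50 mm
band). The sensor reading is *flat-field calibrated per position*: the heel
profile is divided out, as on clinical units, so a uniform phantom yields
the same mAs at every sensor position. Without this calibration the servo
would chase the heel profile and the mAs would vary strongly with position
on a uniform slab, which is not what real units do.

**Scales.** The default "test" scale is a 640 × 512 px frame (44.8 ×
35.84 mm at the physical 70 µm pitch) whose insert layout is shrunk while
preserving the *pixel* footprint of every analysis ROI (64-px contrast
ROIs, 128-px NPS region, 64-px uniformity ROIs); the "full" scale is the
24 × 29 cm detector with 256-px ROIs and the reference phantom geometry.
ROI statistics transfer between scales because ROI sizes are held fixed in
pixels. All experiments and tests run at desk scale; the replicate counts
(5 flat-field repeats, 10 replicates per study arm, 7 AEC positions) match
the acquisition protocol the phantom study prescribes.

## Measurement chain

**SNR / SDNR / COV.** Sample (n−1) standard deviations throughout (the
reporting tables use n = 5 replicates). SNR subtracts the detector DC
offset from the mean by default — the console formula is undocumented, so
both conventions are implemented behind a flag; subtraction makes SNR → 0
at zero exposure. SDNR is computed on raw signal (the offset cancels in
the difference).

**Slanted-edge MTF.** Per-line 50 %-threshold crossings (linear sub-pixel
interpolation) are fit with a straight line to get the edge angle — valid
band 1–10°; pixels are projected onto the edge normal and binned at ¼ pixel
into the ESF; the differentiated LSF is Hann-windowed about its peak and
Fourier transformed; the finite-difference and bin-aperture transfer
functions (each `sinc(f·Δ)`) are divided out. A synthetic Gaussian-blurred
edge is recovered to ≈ 0.1 % of the closed form up to 0.8 × Nyquist; an
ideal area-sampled edge reproduces the pixel-aperture sinc.

**nNPS.** A square homogeneous region (512 px full scale, 128 px desk
scale) is tiled by 9 half-overlapping square ROIs (side = half the region);
each ROI is detrended with a fitted full second-order 2D polynomial
(6 terms), which removes the heel trend exactly without eating broadband
noise; periodograms scaled by pitch²/N² are averaged over ROIs and frames
and divided by the squared offset-subtracted large-area mean. Axial curves
average the frequency rows flanking each axis; the radial curve averages
annuli excluding those axis bands. The flanking/exclusion band is 7 bins at
the 256-px ROI size and scales with ROI size (2 bins at 64 px) so the
blanked fraction of the spectrum is scale-invariant; annuli that fall
entirely inside the excluded band are filled with the first measured value
when a full grid is needed (they carry little weight under the u-weighted
detectability integral). Parseval's identity (Σ NPS·Δu·Δv = detrended
pixel variance) holds to machine precision and is tested.

**NPWE d′.** The canonical non-pre-whitening-with-eye-filter ratio

    d′² = [2πC ∫ S²MTF²VTF² u du]² / [2π ∫ S²MTF²VTF⁴ nNPS u du],

integrated by trapezoid on the radial-nNPS grid up to Nyquist
(7.14 mm⁻¹ at 70 µm), with the MTF interpolated onto that grid and clipped
at 0. The disc spectrum is S(u) = R·J₁(2πuR)/u with S(0) = πR². The eye
filter is VTF(f) = f^1.3·exp(−c·f²) with c set for a 4 cyc/deg peak,
normalised to 1, mapping image-plane to angular frequency through a 1.5
display magnification at 400 mm viewing distance; form and peak are
config-exposed. Contrast is measured on offset-subtracted signal,
C = (S_bg − S_Al)/(S_bg − offset), tied to the SNR convention. The
white-noise closed form d′ = C·√(πR²/N₀) anchors the implementation
(numerically within ~0.3 % on a fine grid). No internal-noise term is
added. Whether C is folded into S(u) or kept as a prefactor is a
representation choice with no effect on d′.

Per-image d′ at desk scale carries ≈ 7 % replicate noise, almost entirely
from the 9-ROI nNPS estimate (the 128-px region is 16× smaller in area
than the full-scale one); MTF and contrast noise contribute < 0.5 %.
Scaling-law tests therefore average the nNPS over several frames per
exposure level.

**Dosimetry.** AGD = K·g·c·s with K the inverse-square incident air kerma
at the slab surface (tube output 18.5 µGy/mAs at 1 m by default, source–
detector 700 mm, 25 mm support gap). g (50 % glandularity) and c (standard
breast of the 50–64 screening age group) are bilinear in (HVL, thickness)
from embedded CSV tables reconstructed from the published EUREF/Dance
protocol values; the weak HVL dependence of c is neglected (constant
columns). s is tabulated per target/filter (W/Rh: 1.042). PMMA thickness
maps to equivalent breast thickness through the standard EUREF table
(45 mm PMMA ≡ 53 mm breast). No extrapolation outside the tables — inputs
out of range raise. Default HVL 0.53 mm Al at 28 kVp W/Rh. The tube output
was set once so the recommended manual technique (28 kVp, 120 mAs, 45 mm
PMMA) lands at ≈ 1.5 mGy, the clinical AGD scale for this thickness; AGD
is then exactly linear in mAs, so a 13 % mAs cut is exactly a 13 % dose
cut. Heel-effect variation of the incident kerma across the breast is not
modelled in the dose estimate.

**Statistics.** Median (IQR; 25th–75th, linear/type-7 quantiles), except
exactly-five-value samples which are reported mean ± SD. Shapiro–Wilk and
Levene are computed and reported but never gate the pipeline. The omnibus
test is tie-corrected Kruskal–Wallis; post-hoc comparisons are Dunn
z-tests on pooled ranks with tie correction, Bonferroni-multiplied over
all C(k,2) pairs and capped at 1, α = 0.05. Groups with fewer than 3
replicates are excluded from testing (with a warning) but still
summarised. Dunn's test is implemented in-package and validated against a
hand-computed fixture and an exhaustive-permutation check of the
Kruskal–Wallis statistic.

## Experiments

`run_aec_experiment` images the phantom at AEC positions 1–7 (10
replicates each, seeds derived deterministically from a base via
`SeedSequence`), computes SDNR, C, d′(0.1), d′(0.25), AGD and mAs per
image, and compares the pooled misused (1–3) vs reference (4–7) groups.
`run_manual_experiment` compares recommended manual 120 mAs, the first
console reduction level (13 % default — the vendor's actual step is not
public; the value is a config parameter reverse-engineered from the dose
arithmetic), and the automatic reference arm, reporting replicate-paired
percent changes. Both are bit-reproducible from (config, seed base).

## What the simulator does and does not show

Passing tests demonstrate that the measurement chain is correct against
closed forms and that the *relative* phenomena — AEC mAs inflation under a
radiopaque target, SDNR/d′ ∝ √mAs, AGD ∝ mAs, misused > reference
orderings with corrected p < 0.05 — emerge under realistic calibrations.
They do not certify absolute SDNR/d′ agreement with any physical unit
(scatter, detector lag, spectral effects, anatomical backgrounds and
long-term drift are absent), IEC-grade MTF/NPS conformance, or patient
dosimetry with implants. Because week-scale drift is not modelled,
replicate scatter is purely statistical: precise metrics (SDNR) can reach
significance for small effects that a physical three-week study would not
flag, while d′ — noisier through its per-image nNPS — behaves like the
physical study.

## Numerical details worth knowing

- Determinism: every random draw traces to an explicit integer seed
  recorded in the image metadata; identical (config, seed) gives
  bit-identical images across runs.
- Degenerate inputs raise typed exceptions (zero ROI sd, background at
  offset level, zero noise integral, saturated AEC) rather than returning
  infinities.
- ESF bins that would be empty raise with advice to enlarge the bin
  fraction; sparse bins at the band corners are trimmed.
- 16-bit TIFF/DICOM output rounds pixels; the analysis chain operates on
  floats and is insensitive to this quantisation at the configured signal
  levels.
- Internal units: mm, mGy, mAs, counts; conversions only at the I/O
  boundary (µm pitch in data sheets, µAs in DICOM tags).
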