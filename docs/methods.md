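# Methods

## Optical model

A ray bundle focused at the center of a dielectric sphere of diameter *d*
meets the surface at normal incidence on entry and exit, so its coherent
self-interference is that of a plane-parallel slab of the same material and
thickness: `medium | core(d) | medium`. Surface films (bound protein) add
symmetric internal layers. Reflectance is computed with the standard 2×2
characteristic-matrix method at normal incidence,

    M_j = [[cos δ_j,  i sin δ_j / n_j], [i n_j sin δ_j,  cos δ_j]],
    δ_j = 2π n_j d_j / λ,

with the amplitude coefficient r = (n₀B − C)/(n₀B + C), (B, C)ᵀ = ΠM_j (1, n_s)ᵀ.
All media are lossless real dielectrics, so R + T = 1 holds to machine
precision and is asserted in the tests. The test suite cross-checks the
transfer matrix against an independently coded closed-form Airy single-film
formula to < 10⁻¹⁰ over 10⁴ random parameter draws.

Assumptions: normal incidence only (the sphere→slab analogy is taken as
exact), no Mie/vector-diffraction corrections, no absorption, no
polarization effects, unpolarized intensity addition not required.

## Materials

Dispersion fits live in a versioned registry (`spere/data/materials.yaml`):

| material | model | anchor | range (nm) |
|---|---|---|---|
| polystyrene | Sellmeier (Sultanova 2009) | n(589) = 1.592 | 400–1052 |
| water | Sellmeier (Daimon–Masumura 2007, 20 °C) | n(589) = 1.333 | 380–1100 |
| fused silica | Sellmeier (Malitson 1965) | n(589) = 1.458 | 250–2300 |
| streptavidin layer | constant 1.50 | — | 300–1500 |
| PDMS | constant 1.41 (literature value; configurable) | — | 300–1500 |
| 5CB liquid crystal | constants n_o = 1.55, n_e = 1.74 | — | 300–1500 |

The polystyrene fit was measured from 436.8 nm upward; its registry range
extends to 400 nm by smooth extrapolation of the Sellmeier form so that the
full 400–700 nm simulation band is usable (the extrapolated region is
never used by the default 450–700 nm measurement band). Group index
n_g = n − λ·dn/dλ is evaluated by central differences (0.5-nm step),
negligible error for these smooth fits.

## Spectrum database and decoding

The decoder's reference is one simulated spectrum per diameter on a
uniform diameter grid (default step 0.1 nm). Databases persist as `.npz`
arrays plus a JSON sidecar with build metadata and a format version;
loading validates both.

Decoding maximizes the Pearson correlation between the measurement and the
database rows over the fit band (default 450–700 nm). Choices:

* Rows are cubic-spline resampled **from the database grid to the
  measurement grid** — the simulated rows are smooth, so interpolating them
  cannot distort the noisy measurement. Resampled, mean-centred rows are
  cached per measurement grid, making replicate series cheap.
* Correlation is affine-invariant, so no intensity calibration is needed.
* Exact ties resolve to the smaller diameter, deterministically, and are
  logged.
* Optional sub-grid refinement fits a parabola through the correlations of
  the three diameters bracketing the argmax (clamped to that interval).
  It is off by default: the grid already matches the 0.1-nm convention,
  and refinement matters only for precision studies.
* Fits whose best correlation falls below 0.8 are rejected
  (`rejected_low_fit`); well-formed data correlate ≳ 0.98, so the floor
  only trips on garbage input.
* `r_squared` is the squared Pearson correlation of spectrum vs fit.

A volumetric scan (default 9×9×10 voxels, 100-nm lateral / 200-nm axial
spacing) is reduced by selecting the voxel with the maximum total intensity
(sum of raw counts over wavelengths); if that voxel lies on any face of the
volume the sphere's center was not captured and the dataset is excluded
(`rejected_boundary`). The selected spectrum is divided pointwise by a
mirror reference before decoding.

## Phasor representation

On a uniform wavenumber grid (cubic resampling), the spectrum is fitted to
R(k) ≈ A + B·cos(2πfk + φ₀). The frequency seed is the peak of the
zero-padded discrete spectrum of the signal after removing a 2nd-order
polynomial trend in k (order configurable); a dense grid of trial
frequencies (≥10 per side-lobe of the residual landscape) followed by
bounded local refinement finds the global least-squares f deterministically
— re-fits with seed perturbations of ±5% reproduce the phase to < 10⁻⁸ rad.
The reported phase is (2πf·k_ref + φ₀) mod 2π at k_ref = 1/500 nm⁻¹.
Spectra covering fewer than 3 fringe periods are rejected.

The fitted f equals the round-trip *group* optical thickness 2·n_g·d: exact
to 0.01% for dispersion-free cores, within 0.3% of the band-center oracle
for polystyrene up to ~12 µm. **Limitation:** for strongly dispersive cores
over a wide band the fringe signal is chirped (for polystyrene across
400–700 nm, n_g spans 1.77→1.62); once the chirp spread exceeds one
ambiguity lobe (1/Δk) of the single-frequency model — above ~14 µm for
polystyrene — the fitted f can differ from any single-wavelength oracle by
up to one lobe (≈2%). Frequency remains strictly monotone in diameter
throughout, so decoding and barcoding are unaffected; only the physical
identification of f with 2·n_g(λ_c)·d loosens. A 10-nm diameter change at
3 µm shifts the 500-nm phase by ≈0.40 rad (≈π/8), in line with the
analytic estimate 4π·n(500)·Δd/500.

## Sensing

**Adlayer.** A film of thickness t = 5 nm per side whose index is the
linear volume-fraction mixture n_eff(p) = p·n_layer + (1−p)·n_medium(λ)
(Maxwell-Garnett offered as an alternative; for this index contrast the two
differ by < 0.05 nm in predicted shift). The observable is the displacement
of the fringe maximum nearest 589 nm between bare and coated stacks,
located by parabolic interpolation on a 0.01-nm simulation grid. A
continuous-lag cross-correlation estimate of the shift is provided as a
cross-check; the two agree within 0.02 nm. (A discrete-lag correlation
argmax is *not* used: on windows holding ~1.4 fringe periods it is biased
by tens of percent, measured on a synthetic rigid shift.) Full density
gives ≈1.16 nm of redshift for a 3-µm polystyrene sphere in water; density
inversion is by bisection to 10⁻³ nm, with an explicit saturation error
above the full-density ceiling.

**Liquid crystal.** The droplet is a constant-index sphere whose effective
index the caller sets anywhere in [n_o, n_e] = [1.55, 1.74]; the mapping
from applied field to effective index is deliberately parametric (no
director-field physics). The medium defaults to PDMS at 1.41. Fringe
frequency scales with n_eff exactly (non-dispersive droplet), and the
tracked fringe redshifts strictly with rising index. Because the full
n_o→n_e swing moves fringes by several free spectral ranges, peak tracking
follows the nearest peak step-to-step and needs per-step shifts below half
an FSR — use enough intermediate index steps (or a smaller droplet) when
sweeping.

## Photometry

Fluorophore brightness is Φ·σ·C·N_A·L_eff (concentration converted to
molecules/nm³). The effective excitation/collection path L_eff is a single
calibration constant fixed by anchoring the polystyrene-in-water peak
reflectance (3.5%) to 700× the signal of 100 µM fluorescein
(Φ = 0.92, σ = 0.0121 nm²), giving L_eff ≈ 75 nm; every other ratio then
follows from published Φ, σ, C values with no further freedom. Multiplexing
capacity is floor(range/(m·precision)) with the spacing multiplier m
exposing both conventions (m = 1: spacing equal to the stated precision;
m = 2: a full ± interval). SNR is mean signal over the sample standard
deviation of the background. Attenuation series are fitted to A·exp(−z/ℓ)
by nonlinear least squares seeded from the log-linear fit; constant series
report a saturation flag instead of a divergent length.

## Synthetic instrument

The generator emulates the acquisition chain: fine-grid simulation (step ≤
sampling/6), Gaussian line-spread convolution (FWHM 0.6 nm), sampling onto
the 450–700 nm instrument grid at 0.6 nm, multiplication by a smooth
strictly positive 4th-order-polynomial source envelope peaking near 550 nm,
and additive Gaussian noise. Two imperfection parameters:

* `noise_sd` (default 0.01): detector-noise SD as a fraction of the fringe
  amplitude of the noise-free signal.
* `grid_offset_jitter` (default 0.15 nm): a uniform per-acquisition
  wavelength-calibration offset, modelling quarter-sample residual drift of
  the spectrometer calibration between reference and measurement. This
  term dominates the replicate spread of decoded diameters (a rigid
  wavelength shift δ maps to a diameter error ≈ d·δ/λ).

With these defaults, 21 simulated repeat measurements of a 4-µm silica
sphere spread over ≈2 nm peak-to-peak — inside the 3-nm theoretical limit
set by the 0.6-nm spectral resolution. Scan stacks attenuate off-center
voxels (intensity and fringe contrast together) with a 3-D Gaussian
confocal profile (σ = 150 nm lateral, 350 nm axial) and add no spectral
distortion. Barcoding scenarios assign distinct diameters at a configurable
spacing and fail with an explicit capacity error when the range cannot hold
the requested number of codes.

What the generator does **not** emulate: speckle, detector nonlinearity and
gain structure, wavelength-dependent noise, photobleaching of co-labels,
off-center spectral distortion, and scattering backgrounds of real tissue.
Passing closed-loop tests therefore demonstrates the correctness of the
decoding chain under the stated noise model, not performance on real
tissue data.

## Problem sizes

Defaults were chosen so every routine analysis runs in seconds on one core:
databases span the neighbourhood of the probe population (e.g. 1 µm of
range at 0.1-nm step ≈ 10⁴ rows) rather than the full 0.1–20 µm catalogue,
which remains available through the same API; sensing simulations use
0.01–0.02-nm sampling; Monte-Carlo precision uses 21–100 replicates. All
stochastic routines take explicit seeds and are bit-reproducible.
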