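# Methods

## Model overview and assumptions

`saxsbeam` models the coherent small-angle scattering signal of a single
pencil beam through a large object containing a deep target, under the
following assumptions:

- **Monoenergetic beam.** A single wavelength λ, set by the beam energy via
  λ[nm] = 1.23984193/E[keV]. Default 60 keV (λ ≈ 0.0207 nm), a typical
  diagnostic head-imaging energy; the energy is a configuration choice, not
  a modeled quantity.
- **Single scattering.** Every detected photon scattered exactly once;
  multiple scattering, which grows with object size, is not modeled.
- **Uniform attenuation.** Object and target share one linear attenuation
  coefficient μ (default 0.30 cm⁻¹, representative of grey/white matter at
  diagnostic energies). Attenuation uses the straight-through path *l*: the
  law-of-sines construction in `geometry.scatter_event_path_length` shows
  the deflected path differs from the chord by < 1 % for 2θ ≤ 0.05 rad
  anywhere along the chord, so splitting the exponential per scatter
  location is unnecessary at SAXS angles.
- **Background-subtracted signal.** All modeled scatter originates in the
  target; the density of scatterers outside the target is zero and
  non-target tissue scatter is assumed removed by background subtraction
  (it also occupies a different q range than the cross-β feature).
- **No solid-angle or extra detector factors.** Solid-angle variation is
  negligible over the small angular range; detector pixel size and energy
  resolution are assumed fixed per optimization problem and folded into the
  single triangular blur.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| σ | cm² | 5×10⁻²³ | differential scattering cross-section per scatterer |
| ρ_t | cm⁻³ | 5.5×10⁵ | scatterer number density inside the target |
| μ | cm⁻¹ | 0.30 | linear attenuation coefficient of object and target |
| L₀ | cm | 20 | mean target-to-detector distance |
| E | keV | 60 | beam energy (sets λ) |
| q_center | nm⁻¹ | 13.4 | centre of the target's diffraction feature |
| kernel width factor | – | 0.35 | triangle base as a fraction of the q spread |
| pixel size | cm | 0.05 | mask raster resolution |

σ, ρ_t, μ and L₀ are the reference values the intensity scale is anchored
to. q_center = 13.4 nm⁻¹ is 2π / 0.47 nm, the cross-β sheet spacing of
amyloid fibrils; the forward model itself is agnostic to the feature's
origin and q_center is plain configuration. Geometry is in cm, wavelength
in nm, q in nm⁻¹; the cm↔nm conversion is internal and exact.

## Step profile construction

The ideal-detector profile of an extended target is built by slicing the
target along the beam. A slice at signed offset x from the target centre
(positive toward the detector) sits at distance L₀ − x from the detector;
its ring on the detector, read back under the assumption that all scatter
happens at L₀, corresponds to the *apparent* scattering vector
q′ = 4π sin(½ arctan((L₀−x) tan 2θ / L₀))/λ. Slice weights ρ_t(x) dx are
deposited onto a uniform q grid with linear (cloud-in-cell) interpolation
and the profile is rescaled so its area equals the closed-form total
I/I₀ = σ e^(−μl) ∫ρ_t dx. This makes the total intensity exact at any grid
resolution and leaves the grid to control only the shape fidelity.

Two constructions of the q spread coexist deliberately:

- the **closed form** Δq/q = 2 − 2/(sin θ √(((L₀+r_t)/(L₀ tan θ))² + 1)),
  used for kernel sizing and grid spans; and
- the **apparent-q ray trace**, which actually places the intensity.

They agree to second order: the difference is bounded by
3(r_t/L₀)² + 5(r_t/L₀) sin²θ (a bound derived from the series expansions of
both forms and verified by property tests over θ ≤ 0.1, r_t/L₀ ≤ 0.15).
The closed form is treated as authoritative where a single spread number is
needed because it is the quantity the smearing kernel is defined against.

## Detector blur

Detector signal degradation is one symmetric triangular kernel Λ with unit
discrete area and base width 0.35 × the geometric q spread of the step.
"Width" is read as the full support of the triangle: together with "unit
area" that is the only reading that fixes the kernel completely. The kernel
is required to span at least 9 samples so its discrete shape is faithful;
convolution extends the grid by the kernel half-width on each side, so area
is conserved to round-off (the unit-area kernel makes this exact up to
floating point). Because 0.35 < 1 the kernel is always narrower than the
step, so the plateau of the step survives smearing — peak intensity is
set by the step height, not by the blur.

## Profile summaries

- **I_p**: maximum intensity sample.
- **I_t**: trapezoidal area under the profile (nm⁻¹ × relative units). By
  construction this equals the closed-form I/I₀ of the beam.
- **Δq**: half-width at half-maximum, defined as half the distance between
  the *outermost* crossings of I_p/2 with linear interpolation. Outermost
  crossings make the measure deterministic on flat-topped profiles and
  recover w/2 exactly for an ideal rectangle of width w.

## Figure of merit and ranking

Ω = I_p I_t / (l Δq). Dose is taken proportional to the in-tissue path
length l, which is justified by the similar (and low) radiosensitivities of
bone and neuronal tissue; the genuinely radiosensitive structures (cornea,
optic lens, oral cavity) are instead handled structurally, as an "excluded"
mask label. The default policy only *reports* paths that intersect excluded
regions (ranking them regardless), matching a planning workflow where the
final say is human; `exclusion_policy="drop"` removes them from the
ranking. Ω/Ω_max is normalized per ranking invocation over the surviving
candidates. Exact Ω ties break by (orientation, index) ascending, making
rankings reproducible.

A structural property worth knowing when reading rankings: for a uniform
target, I_t ∝ r_t and Δq ∝ r_t nearly cancel in Ω, so Ω depends on the
target radius only through weak higher-order terms and is dominated by
e^(−2μl)/l. Consequences: (i) among paths with equal attenuation length the
maximal-Ω path is the one with the largest target chord, but rasterized
masks produce *plateaus* of paths with identical target pixel counts near a
disk centre (width ≈ √(2 r_t/p) pixels at pixel size p), which tie exactly
and resolve by the deterministic tie-break; (ii) when attenuation lengths
differ, short chords win — through a circular head the best path grazes the
near edge of the target rather than crossing its centre. The bundled
slab-phantom tests use a rectangular object precisely so that all parallel
paths share l and the target-geometry dependence of Ω is isolated.

## Analytic scene sweeps

`phantoms.paper_sweep_configs` provides the canonical sweeps: object radius
4–10 cm (centred 2 cm target, L₀ = 20 cm), target-to-detector distance
18–22 cm (10 cm object), chord subtended angles π…π/3, elliptical target
a = 1 / b = 3 cm at incidence angles 0…π/2 in a centred 10 cm object, the
reference medium scene (0.5 cm target), and target radii 0.5–3 cm. The
target-size sweep models the target *bare* (attenuation path = target
diameter): with a fixed embedding object the attenuation term is constant
in r_t and the peak would not fall with target size, whereas the bare
target reproduces the expected trade — larger targets give lower peaks and
wider spreads — because μ·2r_t grows faster than the (L₀+r_t) geometric
gain. Scenes in these sweeps that do embed the target use the chord through
the object as the attenuation path.

## Synthetic phantoms vs. real data

The mask generator rasterizes analytic outlines (ellipse or rectangle
object, elliptical lobes, rectangular/elliptical excluded zones) by
pixel-centre membership, giving unambiguous, exactly reproducible labels
with known ground truth — which is what the parameter-recovery and
ranking tests need. It does not emulate: anatomically realistic lobe
shapes, segmentation errors beyond optional seeded boundary
salt-and-pepper noise, heterogeneous attenuation (skull vs. brain), or
partial-volume pixels. Passing tests therefore demonstrate the correctness
of the geometry → profile → metric → ranking pipeline, not the fidelity of
any particular anatomical segmentation.

## Numerical choices

- q grid: uniform, 2048 samples spanning q_center ± 1.5 × the geometric
  spread of the scene (configurable). The build errors out, naming the
  required span, if the step support would leave the grid.
- Slice deposition: ≥ 4 samples per grid step (minimum 1024 slices), so
  deposition ripple is far below the kernel scale.
- Kernel: ≥ 9 samples across the base; discrete area forced to 1 (checked
  to 1e-9).
- Degenerate paths: zero target pixels → Ω = 0 and `candidate=False`
  rather than an error, so whole-mask scans always complete; Ω itself
  rejects l = 0 and Δq = 0.
- Mask path length includes target pixels (object and target share μ);
  `include_target_in_path=False` switches to counting object pixels only —
  the two conventions differ by one target diameter per crossing.
- All numeric text output uses 9 significant digits so repeated runs are
  byte-identical.

## Known limitations

- Single-scattering only; in head-sized objects multiple scattering will
  add background and could shift optimization results.
- One attenuation coefficient for the whole object; a skull-like
  high-attenuation shell would penalize paths non-uniformly.
- Axis-aligned (Cartesian) mask paths only; oblique angles through a
  raster need a pixel-assignment rule this package does not define.
- The triangular blur width is a modeling constant, not calibrated against
  a physical detector's pixel size or energy resolution.
- 2-D masks only; volumetric (voxel) scout data is out of scope.
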