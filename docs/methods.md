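# Methods

`lamrec` reconstructs parallel-beam computed laminography data: the sample
rotates about an axis tilted by an angle φ from the vertical (φ = 0 is
conventional tomography), which suits flat, slab-shaped samples such as
stained brain sections. This note records the model, the discretisations,
the numerical choices, and what the synthetic studies do and do not show.

## Geometry and conventions

Volumes `mu(x1, x2, x3)` are stored as arrays `(n3, n2, n1)` with voxel
coordinates `x_k = index − n_k//2`; projections are `d(θ, v, u)` with the
rotation axis crossing the detector at the fractional column `center`
(default `det_nu/2`) and the row origin at `det_nv//2`. Angles θ are in
degrees and may span up to 360°. In the sample frame the beam direction at
angle θ is `(cos φ sin θ, cos φ cos θ, −sin φ)`; the handedness is pinned by
requiring that φ = 0 reproduces the standard Radon convention (verified
against scikit-image in the tests).

By the projection-slice theorem, the 2D spectrum of the projection at θ
samples the object spectrum on the tilted plane

    ξ1 =  σu cos θ + σv sin φ sin θ
    ξ2 = −σu sin θ + σv sin φ cos θ
    ξ3 =  σv cos φ

with (σu, σv) the detector frequencies in cycles/voxel. The union of these
planes over a full turn misses the double cone of directions within polar
angle φ of the ξ3 axis — solid-angle fraction `1 − cos φ` — which is the
source of laminographic "tail" artifacts. A full 360° scan is required:
with 180° only half of each frequency plane family is visited, and the
tests confirm the corresponding error increase at φ > 0.

## Operators

Two interchangeable discretisations of the projection integral:

* **Line** (`forward_line`/`adjoint_line`): rays are stepped at one-voxel
  increments with trilinear interpolation, clipped to the volume box; the
  adjoint scatters with transposed weights, so the pair passes dot tests to
  ~1e−16. Complexity O(N³·Nθ).
* **Fourier** (`forward_fourier`/`adjoint_fourier`): the volume spectrum is
  evaluated on the tilted planes with an unequally spaced FFT and each
  angle is inverse-2D-FFT'd (with a phase encoding the rotation-centre
  offset). Complexity O(N³ log N). Because ξ3 depends only on σv, the 3D
  USFFT splits into a batched 1D USFFT along x3 (one target frequency per
  detector row-frequency) followed by a batched 2D USFFT over (x1, x2)
  per ξ3-plane; a monolithic oversampled 3D buffer is never formed.

The two discretisations agree to ≲1% relative RMS on smooth volumes whose
projections stay on the detector (Gaussian-correlated fields, correlation
length ~6 voxels, supported in an interior ellipsoid); sharp or unsupported
objects expose their differing treatment of high frequencies (trilinear
low-pass vs band-limited sampling) and of content leaving the detector
(clipping vs periodic wrap). The Fourier operator treats out-of-band
frequencies by exact aliasing (the DFT of gridded data is 1-periodic).

## USFFT

Gaussian-kernel gridding (Dutt–Rokhlin / Beylkin / Greengard–Lee): divide
by the window in space, zero-padded FFT on a grid oversampled by R,
truncated Gaussian gather onto the target frequencies; the adjoint runs the
conjugate-transposed chain so the pair is an exact transpose. The window
variance follows the Greengard–Lee optimum `a = π w /(n² R (R − 1/2))` for
truncation half-width `w`. Defaults: R = 2, `w = 6`, giving a measured
maximum relative error < 2e−6 (1D) and < 2e−6 (2D) against direct
summation; `w = 4` gives ~1e−4 and is used as the "reconstruction-grade"
plan in the large studies, where a 1e−4 spectral error is far below the
discretisation error of FBP itself. Frequencies within half a kernel width
of ±0.5 wrap periodically. The interior FFT is unnormalised; the adjoint
carries the matching `M^d · ifft`.

## FBP

Pre-processing is `−log((raw − dark)/(flat − dark))` with the transmission
clamped at 1e−6 (relative) before the log. Filtering is per (θ, v) row
along u with the band-limited ramp (impulse response h[0] = 1/4, h[odd k] =
−1/(πk)²), optionally apodised by the Shepp–Logan (`|σ|·sinc σ`) or Parzen
windows. Two deliberate conventions: the DC bin of the transfer function is
set exactly to zero, and rows are edge-padded (not zero-padded) to the FFT
length — together these make the discrete filter annihilate constant rows
exactly while leaving circle-supported sinograms bit-identical to the
classical zero-padded treatment.

The reconstruction weight per angle is `Δθ · cos φ / m`, with `m = 2` for a
full-circle scan (every frequency plane is visited twice) and `m = 1` for a
half-circle tomographic scan. The Jacobian of the (θ, σu, σv) → ξ map is
`|σu| cos φ`, which is why the classical ramp in σu needs only the extra
cos φ factor at φ > 0. The absolute scale is verified by reconstructing a
unit-attenuation ball at φ = 0 to amplitude 1.00 ± 0.05.

## Alignment sweeps

`try_rotation_axis` / `try_lamino_angle` reconstruct the central slice for
each candidate (voxel-driven bilinear backprojection of the filtered data,
which only needs one slice) and write every image, mirroring the practice
of choosing by eye. An automatic ranking is provided: the axis sweep is
scored by slice variance (a correct centre adds feature contributions
coherently; raw gradient energy proved unreliable because streak artifacts
also raise it), the tilt sweep by gradient energy in the outer quarter
frame (tilt error defocuses proportionally to lateral radius, so the
border carries the signal while the middle is insensitive — the same
region the manual procedure inspects). On simulated brain-slab data at
256² × 64 with 192 angles the sweeps recover a +3 px axis offset and a
+0.5° tilt error within one search step (defaults 0.5 px / 0.25°). At
small lateral sizes (≲128 px) the tilt signal (≈ ρ·cos φ·Δφ at radius ρ)
drops below the noise of the ranking, so sweeps should be run on
full-width slices.

## TV-regularised ADMM

`admm_tv` minimises `½‖Lμ − d‖² + λ·TV(μ)` (isotropic TV, forward
differences, zero-flux boundary; `div3` is the exact negative transpose of
`grad3`) by ADMM on `z = ∇μ` with penalty ρ. The quadratic μ-subproblem is
solved by warm-started CG; one operator pair seeds the exact
normal-equation residual at the start of the run and the residual is
thereafter maintained recursively from quantities the CG steps compute
anyway, so the budget is exactly `outer_iters × inner_iters` forward and
adjoint applications (256 each for the default 64 × 4 schedule). With
λ = 0 the splitting collapses and the scheme is exactly plain CG on the
normal equations within the same budget (verified against SciPy's CG to
1e−5). The objective is logged per outer iteration; five consecutive
increases beyond rounding tolerance raise `DivergenceError` with the log
attached (the primal objective of ADMM is not strictly monotone, so the
tolerance is loose).

Defaults: ρ = 1, λ exposed. For the IC phantom at φ = 50° a grid search
over (λ, ρ) gave λ ≈ 4, ρ ≈ 10 at 128-scale (data scaled as minus-log
attenuation; the optimal λ grows with problem size because the data term
scales faster than the TV term), cutting the FBP reconstruction error by
roughly a quarter within 24 outer iterations — well clear of the 20%
artifact-suppression mark. ρ mainly sets the convergence speed; λ/ρ sets
the shrinkage threshold.

## Synthetic data

* `ic_phantom` — four flat "metal" layers with rectangular wiring routed
  alternately along x1/x2, pads, and vias; values 0 / ~0.9 (bimodal), all
  structure inside the reconstructible region. Emulates the strong sharp
  features that launch missing-cone tails.
* `brain_phantom` — bright smooth matrix (Gaussian-correlated field,
  correlation ~n/32) inside a soft slab support, with hundreds of small
  dark axon-like inclusions. Emulates low-contrast stained tissue.
* `simulate_measurement` — Beer–Lambert transmission with dark/flat fields
  and optional seeded Poisson noise; `normalize_minus_log` inverts it
  exactly in the noiseless case.

Both phantoms are invented textures: passing the studies shows the solver
reproduces the *artifact physics* (missing-cone degradation growing with
φ, TV suppression of those artifacts, alignment recovery), not that it
matches any particular real specimen. Real data additionally contain
rings, phase contrast, deformation and beam hardening, none of which are
modelled; ring-removal and phase-retrieval exist only as no-op hook points.

## Study sizes

The bundled verification studies use: the full simulation-scale missing
cone study at 256 × 256 × 128 with 384 angles; the TV benefit at
128 × 128 × 64 with 192 angles (angle count scaled with the volume to keep
the angular sampling density) and 24 × 4 ADMM iterations with the
reconstruction-grade USFFT plan; operator cross-checks at 32³–64³. The
chunked execution contract (angles for the 2D FFT stage, ξ3-planes for the
2D USFFT stage, columns for the 1D USFFT stage) is exercised with chunk
sizes from 1 to "all"; results are independent of chunking because every
column/plane/angle is processed independently.

## Known limitations

* Parallel beam only; no cone-beam or helical trajectories.
* The Fourier operator assumes the object's projections fit the detector;
  truncated (interior) laminography is not modelled.
* The sweeps' automatic ranking is a heuristic; the images remain the
  primary output, as in beamline practice.
* FRC shell counts use the raw number of spectral samples per ring; no
  symmetry correction is applied to the effective n of the 1/2-bit curve.
* Mosaic registration is translation-only; sample bending or rotation
  between tiles is out of scope.
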