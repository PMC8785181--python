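# Methods

## Scope and model

The package covers the analysis layer of a molecular-rotor membrane-probe
study: fitting the flexible-torsion part of a classical force field to
scan data, extracting rotational/structural observables from trajectories,
summarising emission ensembles, and unmixing lipid phases from
fluorescence-lifetime images via the phasor transform.  Electronic
structure (the scan energies, emission energies) and molecular dynamics
(the trajectories, the decays) are treated as *inputs*; the bundled
generators produce statistically faithful stand-ins with known ground
truth, which is what the test suite exercises.

## Torsional model and fitting

Flexible dihedrals use the topology-file dialect
`U(φ) = Σ_j k_j (1 + cos(n_j φ − γ_j)) + c`, with distinct multiplicities
per series; angles are degrees in (−180, 180], energies kcal/mol.  With
multiplicities and phases fixed, the force constants enter linearly, so
scan fitting is ordinary least squares on the design
`[1, 1+cos(n_j φ − γ_j)]`; "free phases" are handled by the cos/sin
expansion of each harmonic, which keeps the problem linear.  Scans on
angle sets that confound two multiplicities (e.g. only multiples of 90°
for n = 1 and 3) raise an error naming the confounded pair rather than
returning an arbitrary solution.

The full objective over reference energies, gradient and Hessian is a
weighted sum of mean-squared block mismatches, each normalised by its
number of independent terms (N scan points; N_K gradient entries;
N_K(N_K+1)/2 unique Hessian entries), making the weights
size-independent.  Weights default to 1.0 each — no published values
exist for them — and are configurable.  Gradient/Hessian blocks are
accepted in whatever (normal-coordinate) basis the reference supplies and
treated as opaque indexed arrays.  `JoyceModel` requires the model blocks
to be affine in the parameters, solves the stacked weighted least-squares
system, and falls back to a ridge-regularised solve (λ = 1e-10 · ‖A‖²_F)
with a warning when the system is singular; frozen parameters are folded
into the offsets.  The returned objective can never exceed the objective
at the initial point.

Landscape analysis evaluates the series on a 0.25° periodic grid, refines
each stationary point by the parabola through its three neighbouring
samples (residual energy error below 1e-6 kcal/mol for the fixtures
here), and reports barriers clockwise between consecutive minima, with
heights from both sides.  A flat series (peak-to-peak < 1e-10) is flagged
rather than reported as minima.

The bistable fixture family `A cos 2φ + B cos 4φ + c` is solved in closed
form for prescribed planar/orthogonal barrier heights.  The minima
positions then follow from the barrier pair: (7, 3) kcal/mol puts the four
wells at ±51.0°/±129.0°, (2.5, 5.0) at ±40.1°/±139.9°.  A two-term even
family cannot set both barrier heights and well positions independently;
the barrier heights were chosen as the controlled quantity.

## Rotational dynamics

The rotational-diffusion generator rotates each unit vector per step about
a uniformly random perpendicular axis by an angle ~ N(0, √(4 D dt)),
which gives the exact small-step contract ⟨P₂(p(0)·p(t))⟩ → exp(−6Dt);
the per-step decay factor is (1 + 3e^(−2σ²))/4, so the discretisation
bias at the default step (dt = τ/200) is below 0.1 %.  The jump generator
is a discrete-time approximation of a continuous-time Markov chain with
total escape probability 1 − e^(−k·dt) per step and a uniform choice among
the other wells, plus Gaussian libration; for two wells the indicator
autocorrelation time is 1/(2k).

`p2_acf` computes ⟨(p̂(s)·p̂(s+t))²⟩ as the autocorrelation of the six
unique entries of the outer-product tensor p̂p̂ᵀ via FFT (verified against
a brute-force double loop to 1e-12), then C_p = (3⟨·⟩ − 1)/2, averaged
over all origins and trajectories and normalised at lag 0.  Relaxation
times come from a one-parameter fit of exp(−t/τ) restricted to lags where
C_p ≥ 0.05 (beyond that the signal is noise-dominated), or from the
trapezoidal integral truncated at the first crossing below 0.05 plus the
analytic exponential tail C(t_c)·τ.  The two agree within 15 % on
monoexponential fixtures.  Uncertainties are block-averaging standard
errors over 5 blocks, split across trajectories when possible (time
otherwise); whether published error bars of this kind are block or fit
errors is generally unstated, so block averaging was chosen as the more
conservative estimator.  An ACF that never decays below the method's
threshold raises `NonDecayingACFError` instead of returning a number.

## Membrane observables

Frames are rectangular-box snapshots with per-particle roles; the bilayer
normal is z and all distances are minimum-image.  S_CD averages
(3cos²θ−1)/2 over C–H bonds and frames, with an optional restriction to
lipids within a 5 Å any-atom distance of the probe.  The bilayer
generator tilts chain axes by N(0, σ) about uniform azimuths with C–H
bonds perpendicular to the chain, so the construction value is
S_CD = −½⟨P₂(cos β)⟩ (+1 when C–H bonds are built parallel to the
normal) — the recovery tests compare against a Monte-Carlo evaluation of
that expectation, not against the implementation.  RDFs use periodic
k-d-tree pair counting normalised by the ideal-gas shell expectation
(cross-checked against MDAnalysis' InterRDF); density profiles are mass
per slab volume.  Area per lipid divides the lateral box area by
phospholipids per leaflet — sterols carry no phosphate and drop out of the
denominator by construction.  Thickness is the distance between the two
per-leaflet phosphate histogram peaks (0.05 nm bins, centroid-refined
over the peak neighbourhood), so its resolution is about half an
ångström for the delta-like synthetic headgroup layers.

## Emission statistics

Summaries are computed directly on wavelengths in nm (no eV conversion
before averaging); the ensemble mean is the primary "emission maximum"
statistic, with the Gaussian-fit centre reported alongside.  Gaussian
fits are unweighted nonlinear least squares with moment-based starting
values; a strongly bimodal histogram shows up as a fit RMS several times
the unimodal baseline rather than as a silent wrong centre.  The
twist-association test compares mean wavelengths inside |φ| ∈ [70°, 120°]
(where charge-transfer character raises the emission energy) against all
other angles with a two-sided permutation test, 10⁴ resamples, α = 0.01;
under shuffled pairings it flags at the nominal rate.  The
Förster–Hoffmann stage is OLS on log10–log10 axes and accepts a
rotational relaxation time as the viscosity proxy.

## Phasor analysis

Phasors use the first harmonic of the repetition period by default
(ω = 2π/T, T always explicit — acquisition metadata in this area is
unreliable enough that no default period is assumed) and bin-centre
timestamps, which makes the uniform-counts phasor exactly (0, 0) and
gives second-order convergence to the continuous transform as bins
shrink.  No instrument response or background model is applied (the
generators emit delta-IRF decays; photons are folded, not truncated).
Mixture fractions are the normalised position of the orthogonal
projection onto the reference segment, clamped to [0, 1], with the
perpendicular residual reported separately.  Pixels under the
`min_counts` threshold (default 50) are excluded, never smoothed.

## Problem sizes and what the tests show

Recovery runs use 200 trajectories × 20 000 steps for the headline τ
recovery (≈10⁴ relaxation times of statistics), 80 × 5 000 for the
two-decade slope, 10⁵–10⁶ photons per decay, 12 × 12-pixel images at
100–200 photons per pixel, and bilayers of 72–200 lipids — sizes chosen
so every stage's statistical error sits well inside the tolerance it is
tested against.  Passing tests demonstrate that the *analysis* is
correct and unbiased at realistic signal levels; they do not validate
the physics the generators idealise away (anisotropic rotation, coupled
torsions, headgroup roughness, IRF convolution, detector afterpulsing),
which is exactly the part a QM/MD engine or a microscope would supply.

## Known limitations

- Only independent per-dihedral cosine series are fitted; no
  multi-torsion coupling terms.
- Rectangular boxes and a z bilayer normal are assumed throughout.
- The phasor stage implements two-component unmixing only; multi-harmonic
  unmixing of three or more states is out of scope.
- Heavy binary trajectory/microscopy formats (XTC, DCD, PTU, SDT) are not
  parsed; the text/NPZ interchange formats in `rotorprobe.io` are the
  supported surface.
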