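# Methods

This note records the models implemented in `puckerdyn`, the conventions
and numerical choices behind them, what the synthetic generator does and
does not emulate, and the known limitations.

## Pseudorotation geometry

The pucker of a five-membered ring is parameterised by the phase `P` and
amplitude `χm` of the cosine model `χj = χm cos(P + 144°(j−2))`, with
`χ2` (Cα–Cβ–Cγ–Cδ) as the zero-phase torsion.  The forward map is the
Westhof–Sundaralingam relation

    tan P = [(χ4+χ1) − (χ3+χ5)] / [2 χ2 (sin 36° + sin 72°)],   χm = χ2 / cos P,

with 180° added to `P` whenever `χ2 < 0`.  This index convention was
validated two ways: the analytic round trip `pseudorotation ∘
ideal_ring_torsions = id` holds to 1e-9 over `χm ∈ (1°, 60°)`, and the
sign structure reproduces the tabulated conformer geometry of proline
(exo near `P ≈ 11–14°` with `χ2 > 0`, endo near `P ≈ 178–180°` with
`χ2 < 0`).  When `χ2 = 0` exactly (the interconversion barrier, `P = ±90°`)
the amplitude is recovered from the numerator, which equals
`2 χm sin P (sin 36° + sin 72°)` for cosine torsions.

The endo/exo boundary is half-open: exo for `P ∈ [−90°, 90°) mod 360°`,
endo otherwise, with `+90°` assigned endo.  Only degenerate barrier-top
geometries land exactly on the boundary, so the convention choice is
inconsequential in practice but keeps classification a total function.

`ideal_ring_coords` is a *fixture builder*, not a structure model: bond
lengths are fixed at 1.53 Å, three bond angles are optimised by
Levenberg–Marquardt so the chain closes while tracking the five target
torsions, and hydrogens are placed tetrahedrally (HCH 107°, r_CH 1.09 Å).
The cosine torsions of an exactly closed equilateral ring are not exactly
realisable, so re-measured torsions agree with targets to within about a
degree; tests budget for this.

Jump angles Δθ are computed by Kabsch superposition (proper rotation
enforced via the SVD sign correction) of one conformer onto the other on
the rigid C–N–Cα–C backbone fragment, followed by the angle between the
two C–H unit vectors.  Where only published per-bond jump angles are
available rather than conformer coordinates, their mean is used as the
effective Δθ (e.g. 82.65° and 82.47° → 82.56° for the proline Cγ–H pair).

## Generalized Karplus ³J model

Couplings are predicted with the Haasnoot–de Leeuw–Altona equation

    ³J = P1 cos²φ + P2 cos φ + P3 + Σi Δχi [P4 + P5 cos²(ξi φ + P6 |Δχi|)]

using the published two-substituent parameter set (class "8C", fragments
‑CH₂X–CH₂Y–; rms 0.367 Hz over 45 couplings) for the β–γ and γ–δ pairs and
the three-substituent set ("8D", ‑CHXY–CH₂Z–; rms 0.485 Hz over 100
couplings) for the α–β pairs.  Substituent electronegativities are Huggins
differences relative to H (C 0.40, N 0.85, O 1.30).  Orientation signs ξ
follow a fixed ring-path convention stored alongside the proline pattern
table; they are configurable, and because the two-state fit both generates
and inverts couplings through the same table, population and phase
estimates are insensitive to the global sign convention.

HH dihedrals are obtained from the endocyclic torsions by tetrahedral
offsets of 0/±120°.  The defaults were checked against explicit hydrogens
on the 3D ring fixture: across the full pseudorotation cycle the offset
model tracks measured HH dihedrals to better than 2° (tests assert 8°).
This mapping, not the Karplus curve, is the dominant systematic in
absolute coupling predictions, which is why externally fitted rms values
are reproduced in character but not to the last 0.01 Hz.

The two-state fit models observed couplings as
`J = x_endo J(P_endo, χm) + (1−x_endo) J(P_exo, χm)` with a shared
amplitude, and minimises the rms deviation by bounded trust-region least
squares from 32 Latin-hypercube starts (seeded; bounds P_exo ∈ [−40°, 70°],
P_endo ∈ [120°, 260°], χm ∈ [25°, 55°], x_endo ∈ [0, 1]).  A fitted
population within 1e-3 of 0 or 1 is flagged degenerate: the minor
conformer's phase is then unidentifiable.  On noiseless synthetic sets the
fit recovers the generating parameters exactly; at 0.1 Hz Gaussian noise
the population is recovered within ±0.03 (and unbiased) over replicates.

NOE-effective distances use strict r⁻⁶ averaging,
`r_k = r_ref (η_ref/η_k)^{1/6}` with `η = ⟨r⁻⁶⟩` and the Hα–Hβ3 pair at
2.40 Å as reference — appropriate for small peptides where overall and
internal motions are both fast; no r⁻³ regime is implemented.

## Dipolar T₁ with two-site-jump internal motion

The longitudinal rate of a protonated carbon is

    R₁ = N K [S² g(τc) + (1−S²) g(τ′)],   1/τ′ = 1/τc + 1/τe,
    g(τ) = j(ωH−ωC) + 3 j(ωC) + 6 j(ωH+ωC),   j(ω,τ) = τ/(1+ω²τ²),
    K = (μ0/4π)² ħ² γH² γC² / (10 r_CH⁶),
    S² = 1 − 3 x_endo x_exo sin²Δθ.

Constants are CODATA (γH = 2.6752219e8, γC = 6.728284e7 rad s⁻¹ T⁻¹,
ħ = 1.054571817e-34 J s); angular frequencies come from the stated Larmor
frequencies (600.13 / 150.90 MHz), not from a nominal B₀, and the context
validates νH/νC against γH/γC to 0.2%.  The normalisation was pinned by
requiring the full set of published inversions to hold simultaneously with
one constant set: 995 ms ↔ 48.2 ps, 310 ms ↔ 246 ps, 614 ms ↔ 82.8 ps
(rigid, N=1), 898 ms ↔ 29.7 ps and 386 ms ↔ 32 ps (two-site, N=2); the
package reproduces all five within 0.3–1.8%.

Both inversions are bracketed Brent root finds to 1e-6 ps.  Only the
fast-motion branch (τ below the T₁ minimum) is supported — the systems of
interest are small peptides with ωHτ < 1 — and a T₁ below the attainable
minimum, or a sidechain T₁ outside the band attainable at the given
(τc, S²), raises with the attainable range reported.  Populations entering
variable-temperature analyses are treated as temperature independent.

The CSA rate `(2/15)(ωC Δσ)² j(ωC, τ)` (axially symmetric) is exposed as a
diagnostic.  At Δσ = −43 ppm and τ ≈ 48 ps it is ~1.1% of the dipolar
rate; since conventions for quoting this fraction differ, it is reported
but never silently subtracted from T₁ inputs.

Arrhenius analysis fits `ln τ` against `1/T` by ordinary least squares
(`τ(T) = τ0 exp(Ea/RT)`), with duplicate temperatures either rejected or
geometric-mean deduplicated by explicit policy.

## Trajectory analysis

The P₂ autocorrelation uses all overlapping origins; the five real
second-rank spherical components turn the estimator into five FFT
cross-correlations, exact to the direct `⟨P₂(û(s)·û(s+t))⟩` sum at every
lag.  Overall motion is removed beforehand by superposing each frame onto
a reference (midpoint frame by default) on the four rigid backbone anchor
atoms.  The Lipari–Szabo model is fitted by bounded Levenberg–Marquardt
with data-driven starts; a flat curve short-circuits to S² = mean(C) with
τe flagged unidentifiable.  Single-exponential model-free only; no
extended (two-timescale) variant.

Transitions are counted on the χ2 series with a hysteresis rule: states
are the χ2-sign cores `|χ2| ≥ 10°`, frames in the band inherit the last
definite state, and only definite-to-opposite changes count.  Within-state
libration smaller than the band therefore never chatters.  The default
1 ps stride matches the counting convention of the reference tables; both
core width and stride are configurable because the count is
estimator-dependent.

## Torsion terms and calibration

Cosine terms use `E = Σ (V_n/2)(1 + cos(nθ − γ_n))`, normalised so the
χ2 = 0 barrier of a pure V₃ (γ₃ = 0) term above its minima equals V₃ —
the identity that links a fitted barrier directly to the force constant.
Ryckaert–Bellemans terms use the standard `E = Σ C_k cos^k(ψ)`, ψ = θ−180°.

The QM merit is `Φ² = Σ w_i [E_QM − (k0 + E_MM_base + E_tors)]²` with
Boltzmann weights `w ∝ exp(−β E_QM)`, β = 1.0 mol/kcal; the offset k0 is
the weighted mean residual in closed form.  Internal merit units are
kcal/mol; torsion terms stay in kJ/mol with conversion at the boundary.
Annealing uses geometric cooling (200 temperatures × 50 proposals, seeded,
hence bit-reproducible), V_n ≥ 0 and γ_n ∈ {0°, 180°} by default
(continuous phases optional), followed by an exact amplitude polish: for
fixed phases the merit is linear in the V_n, so a bounded linear
least-squares refit removes residual proposal jitter.

A caution established during design: over a restricted scan window such as
−75°…+75°, Boltzmann-weighted V₁/V₂ shapes can largely mimic a V₃ term
(the unconstrained V₃ standard error at 0.05 kcal noise is of order
10 kJ/mol), so planted-parameter recovery studies use the generator's
full-period default grid, where the cosine shapes are near-orthogonal and
V₃ is recovered within 0.2 kJ/mol at that noise level.  Fits to real
restricted-window scans should be read as fits of the barrier shape, not
as uniquely decomposed coefficients.

Simplex fitting wraps Nelder–Mead with the restart-scaling initial
simplex — vertex j perturbs parameter j to `x_j + c·x_j`, so rerunning
with different `c` probes different basins — positivity by projection, and
a full evaluation trace; `c = 0` is rejected as degenerate.  The merit
backend is pluggable (closed-form two-state couplings or the synthetic
simulator); no MD engine is driven.

Reweighting computes `w_i ∝ exp(−β_rw ΔE(χ_i))` in log space with max
subtraction, returning the weighted observable and `ESS = (Σw)²/Σw²`.
ESS/n is the overlap diagnostic and also the default surrogate for more
elaborate collectivity screens, which are out of scope; acceptance hooks
can be layered on top.

The timescale calibration `V = a ln(τ/ps) + b` is an ordinary least-squares
fit of V against ln τ with r² reported, or is constructed directly from
published (a, b) coefficients; `predict(τ*)` evaluates the matched force
constant.  It is equivariant under time rescaling (τ → sτ shifts V* by
a ln s), so the ps unit convention must be stated, as it is here.

## Synthetic generator: what it emulates, and what it does not

`synthdyn` realises exactly the model the analysis assumes: a
continuous-time two-state Markov chain with stationary endo population
`x` and exchange correlation time `τ_ex` (rates `k_endo→exo = (1−x)/τ_ex`,
`k_exo→endo = x/τ_ex`, so the state-ACF relaxation time is exactly τ_ex
and the reported τe ≡ τ_ex), sampled by exponential waiting times and
discretised on the frame grid; torsions from the cosine pucker model plus
Gaussian libration (default σ = 8°, a typical ring-libration width, kept
below the 10° hysteresis core); C–H vectors jumping by exactly Δθ between
two body-fixed orientations; and optional isotropic small-step rotational
diffusion for tumbling (per-step Gaussian rotation vectors with
`σ² = 2D dt`, `D = 1/(6τc)`; the O((D dt)²) rate error stays below 1% for
dt ≤ τc/20).  Defaults are the GPGG study conditions (x = 0.543,
τ_ex = 29.7 ps, χm = 38.3°, Δθ = 82.56°, τc = 48.2 ps) with `vapg-like`
and `ahm-like` presets alongside.  One seeded generator per simulation
makes every output bit-reproducible.

Because generator and analysis share the same model, passing tests
demonstrate *internal consistency and estimator correctness* — stationary
populations, exchange times, plateaus, transition rates and forward T₁
values all agree with their closed forms — not fidelity to explicit-solvent
MD.  Real trajectories have continuous pucker paths over the barrier,
anisotropic and rotation–internal-coupled motion, multi-exponential
internal decay, and force-field-dependent state geometry; none of that is
emulated.  Quantities that require hundreds of nanoseconds to microseconds
of solvated MD (per-parameter-set rms_Jp tables, transition-count columns,
MD populations) are therefore covered only by these simulator analogues at
desk scale: trajectories of 10⁵–10⁶ frames at 0.5–1 ps spacing, i.e.
0.2–1 µs of synthetic time, sized so the full suite runs in well under
a minute.

## Known limitations

* Five-membered rings only; no general N-ring puckering coordinates.
* HH-offset and orientation-sign conventions are internally consistent but
  not guaranteed to match any particular legacy fitting code bit-for-bit.
* Relaxation: dipolar + axial CSA only; no cross-correlation, NOE factors,
  anisotropic tumbling, or slow-branch inversions.
* Torsion-coefficient decomposition over restricted scan windows is
  ill-conditioned (see above); report barrier shapes, not coefficients.
* The reweighting implements weights and ESS only; it cannot create
  conformations absent from the parent trajectory.
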