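# Methods

This note records the physical model implemented by `treprsim`, the
conventions and numerical choices that are not forced by the physics, and the
limitations a user should know before trusting a simulation.

## Model

A trEPR experiment is modeled as: (i) a spin system with fixed magnetic
interactions, (ii) an initial density matrix created instantaneously by the
laser pulse, and (iii) incoherent dynamics acting during detection under a
weak continuous microwave field.  For every orientation of the molecule and
every static field B0 the simulator builds the rotating-frame secular spin
Hamiltonian, constructs ρ(t₀), propagates the stochastic Liouville equation

  d vec ρ / dt = (−i L_H + R) vec ρ,  L_H = 𝟙⊗H − Hᵀ⊗𝟙,

and detects S(t) = Tr(Ŝy,total ρ(t)).  Orientations are summed with equal
weights (powder average).  In Hilbert mode R ≡ 0 and the propagation reduces
to ρ(t) = e^{−iHt} ρ₀ e^{+iHt}.

### Hamiltonian terms (angular frequency, rad·μs⁻¹)

* Zeeman, per electron: ω₀ = g_eff μB B0/ħ with g_eff = ‖g_lab ẑ‖, the
  first-order secular value of an anisotropic g tensor; the full tensor is
  rotated to the laboratory frame per orientation (tensor-frame ZYZ Euler tilt
  followed by the powder rotation Ry(ϑ)Rz(ϕ)).
* Microwave: H₁ = Σᵢ ω₁,ᵢ Ŝx,ᵢ, ω₁,ᵢ = g_iso,ᵢ μB B1/ħ.  **Convention:** B1
  is the rotating-frame (circularly polarized) amplitude — no factor ½.
* Exchange: −J(½ + 2 Ŝ₁·Ŝ₂).  **Convention:** for J > 0 the triplet (or
  quartet) manifold lies below the singlet (or doublet) manifold, with
  singlet–triplet splitting exactly 2J.
* Dipolar coupling (pair systems): D_zz^lab (Ŝ₁z Ŝ₂z − ¼(Ŝ₁₊Ŝ₂₋ + Ŝ₁₋Ŝ₂₊)),
  i.e. the secular A term plus the pseudo-secular flip-flop term, which keeps
  total Sz conserved.  In the singlet–triplet basis it is diagonal.
* Zero-field splitting (triplet spin): (3/2) D_zz^lab (Ŝz² − S(S+1)/3 𝟙),
  with the tensor built from the conventional principal values
  (−D/3+E, −D/3−E, +2D/3).  The 3/2 prefactor makes this term exactly the
  high-field-basis diagonal of the full rotated S·D·S tensor interaction
  (asserted by a test), and reproduces the canonical first-order transition
  offsets ±D at the principal orientation.

Every secular Hamiltonian commutes with total Ŝz, so the rotating-frame
transformation H → H − ω Ŝz,total renders the full Hamiltonian
time-independent exactly; no piecewise time propagation is needed.

### Working bases

doublet {|α⟩,|β⟩}; radical pair (|T₊⟩,|T₀⟩,|T₋⟩,|S⟩) — chosen because the
initial states of photo-born pairs are natural there and the Hamiltonian has
only the S↔T₀ off-diagonal elements; triplet high-field (|T₊⟩,|T₀⟩,|T₋⟩);
triplet–doublet pair product basis (|T₊α⟩,|T₊β⟩,…,|T₋β⟩).  Single-spin
matrices use |m⟩ descending; Kronecker factors are ordered first-listed ⊗
second-listed throughout.  Basis transforms U act as M′ = U M U† with the
rows of U being the new-basis vectors in the old basis; eigenvector phases
are fixed (largest-magnitude component real positive, lowest index on ties)
so that repeated runs are bit-identical.

### Initial states

All presets populate only diagonal elements (no initial coherences — the
laser pulse creates populations, not transverse magnetization):

* `eigen` — populations of the ascending-energy eigenstates of the static
  laboratory-frame Hamiltonian, rebuilt at every field point.
* `zf`/`triplet-zf` — populations of the three zero-field triplet states in
  ascending zero-field energy (energies −D_aa of the ZFS principal values).
  They are projected onto the eigenstates of the full (non-secular) isolated
  triplet Hamiltonian at the actual field and orientation, the eigenstates
  are assigned to the (T₊,T₀,T₋) slots by maximum overlap, and coherences are
  discarded — the resulting ρ₀ is diagonal in the working basis and
  field-dependent.  For pair systems the triplet block is built the same way;
  for the radical pair, whose precursor ZFS is not one of its parameters, the
  pair's dipolar tensor defines the zero-field axes used in the mapping (a
  documented approximation).
* `singlet` / `triplet-pnm` — |S⟩⟨S|, or high-field populations (p₊,p₀,p₋)
  on the triplet levels.
* triplet–doublet pair: ρ_T ⊗ ρ_d (Kronecker product).
* `custom` — any Hermitian PSD matrix, the only preset allowed coherences.

Initial matrices are checked Hermitian and positive semidefinite (eigenvalues
≥ −1e-10; no silent repair) and by default normalized to unit trace
(`raw` keeps user totals; all signals are linear in ρ₀).

### Incoherent dynamics

Rates are set directly, not derived from a bath model.  Three input styles
(combinable):

* **T₁/T₂** — coherences decay at 1/T₂; populations relax toward the
  *uniform* distribution at 1/T₁: dρᵢᵢ/dt = −(ρᵢᵢ − Tr ρ/n)/T₁.  The target
  is the infinite-temperature distribution; at the ~0.3 K level-splitting
  temperatures equivalents of X-band quanta this is the standard
  high-temperature approximation, and true thermal targets are out of scope.
* **Element rates** (i, j, k, l, r): dρ_kl/dt += r ρᵢⱼ.  Loss from the
  source is explicit (negative self-rates), so population is conserved only
  when each population column sums to zero; a validator classifies a rate
  specification as conserving / decaying / gaining (gaining warns —
  unphysical without an external source).  Coherence-pumping entries warn,
  since they can break positivity; pure damping does not.
* **Population-rate matrix** (destination row × source column) with an
  auto-filled conserving diagonal unless an explicit diagonal (decay) is
  given; restricted to populations it reproduces classical first-order
  kinetics exactly (tested against the matrix exponential of the n×n rate
  matrix).

Rates may be declared in the `working` basis or in the `eigen` basis of the
static Hamiltonian (ascending energy); eigen-basis rate superoperators are
transformed per field and orientation.  The eigen option is what the
reverse-quartet scenario uses to address quartet/doublet states that are
coherent superpositions of the product basis.

### Propagation and detection

Both propagators use one spectral decomposition per (field, orientation)
reused over all time points — the dominant cost decision, cross-checked
against an independent fixed-step RK4 integrator of the same equations
(step 1e-4 μs, agreement ≤ 1e-6 on every demonstration scenario).  The
Liouville generator is generally non-normal; if its eigenvector matrix has
condition number above 1e8 the propagator falls back to scaling-and-squaring
matrix exponentials.  Detection is the unweighted total Ŝy expectation value
(no g-weighting); the sign convention is fixed so that an overpopulated
lower doublet level gives a positive (absorptive) early-time signal.
Hilbert-mode spectra may be multiplied by e^{−kt} as a phenomenological
overall decay.

### Powder averaging

Two equal-weight grids on the upper hemisphere (trEPR spectra are invariant
under field inversion): a triangular SOPHE-style mesh ((k+1)(k+2)/2 points
per octant, rings extended to full circles for hemisphere coverage) and a
golden-angle Fibonacci spiral.  Equal weighting (rather than classical
area weights) is deliberate; grid refinement converges to a stable amplitude
because weights sum to 1.  The third Euler angle is redundant for
axial detection and fixed at zero.  An octant mode exists for orthorhombic
tensors, and a `single` mode supports oriented samples.

## Demonstration scenarios and what they show

The five built-in scenarios (see `treprsim.fixtures`) define the conditions
under which the package's acceptance checks run:

* `doublet_nutation` — isotropic g = 2.0 at 9.75 GHz; peak at 348.3 mT;
  nutation frequency doubling with B1; exact Rabi law ½|Δp sin ω₁t|.
* `rp_zqc` — weakly coupled radical pair (g 2.0030/2.0047, J = 1 MHz, axial
  dipolar tensor ±1/−2 MHz), singlet-born; its on-resonance trace carries ≥ 2
  Fourier components matching eigenvalue gaps of the generator (nutation +
  zero-quantum beat).
* `triplet_t1t2` — powder triplet, D = 45 MHz, E = 9 MHz, zero-field
  populations (0, ½, ½); shorter T₁ accelerates signal decay, shorter T₂
  broadens the 1 μs spectrum.
* `triplet_custom_rates` — same triplet with unequal |T±⟩↔|T₀⟩ rates
  (2.0 vs 0.2 μs⁻¹ in the eigenbasis) giving an asymmetric 0.5 μs spectrum.
* `tdp_reverse_quartet` — strongly coupled triplet–doublet pair (J = −12 MHz
  putting the quartet above the doublet, D = 20 MHz); the Q±1/2 levels drain
  into the doublet at 2.0 vs 0.2 μs⁻¹, inverting the central net line from
  emission to absorption while the multiplet wings keep their sign.  The
  probed fields are located from the eigenvalue gaps because second-order
  ZFS shifts (~D²/3J) displace the quartet lines from the naive g_Q position.

The coupling strengths are deliberately modest model values: the scenarios
demonstrate phenomenology rather than reproduce specific compounds, and they
keep every eigenfrequency well inside the accuracy range of the fixed-step
RK4 cross-check.  What passing these checks shows is that the propagation
machinery, basis handling and rate models are correct; it does not validate
any particular molecular parameter set, and real systems with D of order
1 GHz will show the same physics at proportionally scaled fields and times.

## Problem sizes

Default test and acceptance runs use field axes of 51–161 points, time axes
of 201–501 points, Fibonacci grids of 40 orientations for Liouville powder
runs, and SOPHE grids up to 40 knots (3281 hemisphere orientations) for the
Hilbert-space grid-convergence study.  All matrices are dense; system
dimensions never exceed 6 (36 in Liouville space), so sparse machinery is
deliberately omitted.

## Numerical choices

* Units: GHz (microwave), mT (fields), MHz (J, D, E, dipolar), μs (time),
  μs⁻¹ (rates); internal angular frequencies in rad·μs⁻¹.
  μB = 9.2740100783e-24 J/T, h = 6.62607015e-34 J·s.
* Column-stacking vectorization, asserted by the vec(Hρ − ρH) identity test.
* Hermiticity tolerances 1e-12 (flags), 1e-10 (propagator input);
  unitarity 1e-8; PSD −1e-10.
* The powder-convergence test probes the early-time (0.05 μs) spectrum: at
  late times an undamped Hilbert-space powder is an increasingly oscillatory
  function of orientation (coherent off-resonance phases ~ D·t), which no
  fixed grid resolves — with relaxation these oscillations are damped and the
  powder envelope converges.
* Gaussian field broadening uses a normalized kernel over ±4σ; it is
  area-preserving away from the sweep edges.

## Limitations

* No hyperfine couplings, no nuclear spins, spins limited to s ≤ 1 (systems
  of dimension 2–6).
* Secular Hamiltonians only; the non-secular S·D·S appears solely as a test
  oracle and inside the zero-field→high-field population mapping.
* T₁ relaxation targets the uniform population distribution, not a Boltzmann
  distribution.
* No transitions between different spin systems, no least-squares fitting,
  no frequency-swept spectra.
* The `zf` mapping for pair systems uses the isolated-triplet Hamiltonian;
  exchange-induced mixing during the projection is neglected.
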