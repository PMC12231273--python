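# Methods

## Physical model and assumptions

The molecule is rigid; electronic transitions and whole-body rotations are
fast on the nuclear-spin time scale, so the nucleus sees the thermal and
orientational average of the induced field. Electrons are treated quantum
mechanically as a single spin-S multiplet with the spin Hamiltonian
H = SᵀDS + ½B₀ᵀgS (Hartree atomic units; the ½ is the Bohr magneton);
rotations are classical. The average is performed electronic-first at fixed
orientation, then over orientations with Boltzmann weights
exp(−βF(u)) of the orientation-dependent Helmholtz free energy — an exact
ordering that does not rely on a separation of the two time scales.

Assumptions and deliberate exclusions:

* Hyperfine coupling is not included in the diagonalized Hamiltonian; the
  nuclear moment enters only through the coupling operators. Indirect
  nuclear spin–spin coupling is therefore outside the model.
* Diamagnetic (closed-shell orbital-current) contributions to σ and τ are
  neglected; the reported shift is the paramagnetic part, with the reference
  compound's paramagnetic contribution taken as zero and 1−σ_ref ≈ 1.
  Positive δ means deshielded/downfield.
* Pseudocontact coupling uses the point-dipole approximation with the
  electronic moment M_el = −½gS of the *spin-Hamiltonian* model. A
  ligand-field (orbitally resolved) treatment of the PC mechanism is out of
  scope; the output metadata records this model choice.
* Nuclear Zeeman energies, relaxation, lineshapes and solid-state
  (single-orientation) spectra are not modeled.

## Orientational averaging

Only the external-field direction in the molecule-fixed frame,
u(χ,θ) = (−sinθcosχ, sinθsinχ, cosθ), affects molecular observables; the
third (extrinsic-ZYZ) Euler angle φ is integrated analytically, which
cancels the lab x/y components of the averaged induced field exactly. Grids
therefore store unit field directions, avoiding pole coordinates. The
lab-z component is assembled per direction as u·⟨B_ind⟩_mol.

The grid catalog holds the five closed-form Lebedev rules with 6, 14, 26,
38 and 50 points (octahedral orbits; rational weights such as 1/21, 4/105,
9/280 for the 26-point rule and algebraic node positions such as
p² = (1+3^−½)/2 for the 38-point rule), exact through spherical-harmonic
degree 3–11 and verified against the moment identities in the test suite,
plus Gauss–Legendre(cosθ) × uniform(φ) product rules of arbitrary even
degree. The convergence reference is the degree-131 product grid
(8712 points, the 5810-point class of quadrature accuracy); the convergence
sweep uses a 32-grid sequence of increasing degree. The production default
is the 26-point Lebedev rule: in the weak-field room-temperature regime the
integrand's harmonic content above degree 7 is of order (βΔF)², and the
26-point result agrees with the reference grid to ~10⁻¹³ relative on the
synthetic systems (comfortably below the 10⁻⁸ acceptance bound).

## Free-energy derivatives

**Numerical oracle.** The first nuclear-moment derivative is analytic
(Hellmann–Feynman): F_Mi(B) = ⟨∂H/∂M_i⟩. Remaining field derivatives are
central differences of that vector with Richardson extrapolation (Neville
table, 5 step-halvings) and mixed partials via directional-derivative
polarization identities. The base step is 0.05·kT/(μB·g_max) — the scale on
which thermal Zeeman populations vary — which balances truncation against
round-off for third differences; a fixed tesla-scale cap would force steps
~50× smaller at room temperature and amplify round-off in the third
difference by ~10⁵, so none is applied. The error estimate is the
difference of the last two extrapolation diagonals; non-convergence is
flagged in the result, never silent. Measured accuracy on the seeded suite
is ~10⁻⁹–10⁻⁸ relative, against a 10⁻⁶ contract.

**Analytic sum-over-states.** The imaginary-time (Duhamel) expansion of
Tr e^(−βH) gives the n-th derivative of the partition function with respect
to parameters that enter H linearly as a sum over n-cycles of eigenbasis
matrix elements, each weighted by a confluent divided difference of
f(x) = e^(−βx) over the cycle's eigenvalues (with the starting eigenvalue
doubled). Divided differences are evaluated through the Opitz identity
dd[x₀…x_k] = [f(J)]₀ₖ with J the bidiagonal node matrix, computed as a
batched matrix exponential in the scaled variable y = βE. Free-energy
derivatives follow from the log-derivative (cumulant) formulas through
fourth order. For second derivatives this reduces exactly to the Van
Vleck / Van den Heuvel–Soncini expressions (verified against the Curie law
to machine precision).

Degeneracies need no special casing in this formulation: the confluent
limit of a divided difference is built into the matrix exponential, so
exact Kramers degeneracies and near-degeneracies are handled uniformly and
no energy-denominator division ever occurs. This replaces the more common
explicit degenerate-subspace treatment (and its grouping tolerance); the
oracle-equivalence suite covers exact doublet degeneracy, rhombic
splittings down to fractions of kT, and S = 0 edge cases.

The spin dyadic ⟨⟨S_iS_j⟩⟩ and tetradic ⟨⟨S_iS_jS_kS_l⟩⟩ are the same
second/fourth derivatives taken with bare spin components; contracting them
with the coupling-coefficient matrices reproduces σ, χ (= −μ₀F_BB) and τ⁴,
which is asserted rather than assumed (including the equivalence of pairing
the moment index with any one field index in the (4:2) contraction).

## Units and conventions

Internal arithmetic is entirely in Hartree atomic units (μB = ½,
μ₀ = 4πα²); public inputs are cm⁻¹ (D), MHz (A_iso), Å (positions), tesla
or ¹H-MHz (fields; a "400 MHz" magnet is labeled by the proton Larmor
frequency regardless of the observed nucleus), kelvin, and rad s⁻¹ T⁻¹
(γ). Constants are pinned to CODATA 2018. χ is reported in m³ per molecule
(χ_au·a₀³). Shift coefficients are formed as β·σ·F_BB products in atomic
units before a single conversion to ppm and ppm/T², avoiding unit mixing;
note the indirect term carries β/μ₀ when written with χ (the μ₀ inside χ
cancels against it). Field specs in configurations must be unit-tagged.

The basis ordering mS = S…−S is fixed so operator matrices are reproducible
bit-for-bit. Non-symmetric g matrices are accepted verbatim (the Zeeman
term B₀ᵀgS defines the physics; M_el,i = −½Σ_k g_ik S_k is its exact field
derivative). The trace of an input D is projected out; asymmetry is an
error. The PC sign convention follows from the operator chain and is
validated against the classic axial pseudocontact formula
Δχ_ax(3cos²Θ−1)/(12πr³), including the sign (equatorial nuclei with
Δχ_ax > 0 are shielded).

## Synthetic systems

The seeded generator emulates the regime of a pentacoordinate high-spin
Ni(II) complex in solution — the setting in which the field-dependence
phenomenology (grid convergence, B₀⁴ truncation error, ~1 ppm field effects
on strongly shifted protons) is established: S = 1, |D| uniform in
2–10 cm⁻¹ with random sign, rhombicity E/D uniform in [0, 1/3], random
principal frames, g principal values uniform in 2.1–2.3, five protons at
2–6 Å with A_iso uniform in ±1 MHz. The oracle-equivalence suite widens
this to S = 1/2…5/2, |D| up to 12 cm⁻¹ and g in 1.9–2.4.

What the generator does **not** emulate: realistic hyperfine magnitudes for
directly coordinated nuclei (tens of MHz), anisotropic hyperfine tensors,
orbitally near-degenerate ions (lanthanoids) where the spin-Hamiltonian
truncation itself is questionable, distributed spin density (PDA breakdown
at short distances), and chemical exchange. Passing tests therefore
validate the statistical mechanics, tensor algebra and quadrature on the
stated model — not the adequacy of a spin-Hamiltonian parametrization for
any particular real complex.

## Problem sizes and numerical tolerances

Acceptance-scale computations use five protons, the 26-point production
grid, the 8712-point reference grid (one sweep), five field strengths for
the B₀⁴ slope, and a 20-system oracle suite — a few seconds each on one
core, since every diagonalization is of a (2S+1) ≤ 11 matrix. Tolerances:
quadrature identities 10⁻¹²; SOS-vs-oracle 10⁻⁶ (contract) with ~10⁻⁹
observed; rotation covariance 10⁻⁸; closed-form checks 10⁻⁸–10⁻¹²;
grid-convergence bound 10⁻⁸. Boltzmann factors are always referenced to the
minimum energy (electronic) or minimum free energy (orientational), keeping
both routes finite at arbitrarily low temperature and high field.

## Known limitations

* The second-order route fails at low temperature / very high field where
  the B₀² truncation breaks down; the finite-field route remains valid and
  is the cross-check.
* Shift decomposition into FC and PC is model-defined (isotropic vs
  point-dipole anisotropic hyperfine), not observable-defined.
* Lebedev rules above 50 points are represented by product-Gauss rules of
  matching accuracy class rather than true octahedral Lebedev designs; for
  fixed accuracy the product rules use ~1.5× more points, which is
  irrelevant at these matrix sizes.
* γ values are built in for ¹H, ¹³C, ¹⁵N, ¹⁹F, ³¹P only; other nuclei need
  an explicit gamma.
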