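# Methods

## Model

`aspsim` simulates adiabatic state preparation for an active-space
electronic-structure problem. The physical register carries one qubit per
spin orbital; spatial orbital `k` contributes its α spin orbital on qubit
`2k` and its β spin orbital on qubit `2k+1`, and computational basis state
`b` occupies spin orbital `q` iff bit `q` of the integer `b` is set
(little-endian). Ladder operators are Jordan–Wigner mapped,
`a†_p = ½(X_p − iY_p) ⊗ Π_{r<p} Z_r`, which preserves the canonical
anticommutation relations exactly; the tests verify this against an
independent combinatorial construction of fermionic matrices on occupation
bitstrings.

The problem Hamiltonian is the active-space electronic Hamiltonian
`H = Σ h_pq a†_p a_q + ½ Σ h_pqrs a†_p a†_q a_r a_s` plus a constant core
energy (nuclear repulsion and the mean field of the frozen core). The
two-electron coefficient follows the charge-density pairing
`h_pqrs = (PS|QR) δ(σ_p,σ_s) δ(σ_q,σ_r)` with `(ab|cd)` a
chemists'-notation spatial integral, so `H` is written with the operator
order `a†_p a†_q a_r a_s` directly.

The initial Hamiltonian is the occupied-orbital part of `H`:
`F = Σ_i h_ii n_i + ½ Σ_{i≠j} (h_ijji a†_i a†_j a_j a_i + h_ijij a†_i a†_j a_i a_j)`
with `i, j` restricted to the spin orbitals occupied in the starting
determinant. `F` is diagonal in the determinant basis, the starting
determinant is its eigenstate, and every term of `F` is a term of `H` with
an identical coefficient. The interpolated Hamiltonian is therefore
assembled string-wise after the qubit mapping: Fock strings held at full
weight plus the remainder scaled by `s`, which is numerically identical to
the convex combination `(1−s)H_I + sH_P` (asserted to 1e-12 in the tests).
The `i = j` two-electron term, whose operator vanishes identically, is
skipped so this coefficient-level subset property is exact.

## Spin operator and broken-symmetry starts

The total-spin operator is built as `S² = S₋S₊ + S_z(S_z + 1)` with
`S₊ = Σ_pq ⟨φ^α_p|φ^β_q⟩ a†_{pα} a_{qβ}`. The α–β spatial-orbital overlap
matrix makes the construction valid for spin-unrestricted orbital sets; it
reduces to the textbook same-index form for restricted orbitals. On a
restricted register `S²` is the exact spin operator (its spectrum is
`S(S+1)` and `[H, S²] = 0`); on an unrestricted active space whose α and β
spans differ it is the exact operator projected into the register space,
and is mildly approximate when the spans differ (the packaged
broken-symmetry sets have α–β overlap singular values ≥ 0.9987).

Broken-symmetry determinants can be produced two ways:

* `rotate_to_bs` rotates chosen occupied/virtual spatial pairs of a
  restricted set by `+θ` (α) and `−θ` (β), transforming all integral blocks
  and the α–β overlap consistently. The default `θ = π/4` fully localizes
  each pair in the degenerate limit, where the determinant carries
  `⟨S²⟩ = 1` per broken pair. This is the self-contained fixture route.
* The packaged molecular systems additionally ship the converged
  broken-symmetry UHF active-space integrals (unrestricted FCIDUMP dialect
  plus an `.ovlp` companion file). BS runs on packaged systems use this
  basis: the BS-UHF determinant is a mean-field optimum there (its energy
  reproduces the recorded UHF total energy to 1e-10 in the tests), whereas
  the rotated-but-unrelaxed restricted orbitals leave the determinant well
  above the UHF solution and produce a qualitatively harder sweep.

With a BS start the scheduled penalty `+ s(t) c S²` (default `c = 0.5`)
raises each contaminant of spin `S` by `c·S(S+1)` as the sweep progresses;
the penalty uses the overlap-carrying `S²`. The same-index ("corresponding
pair") variant was evaluated and rejected: in a localized BS orbital basis
it is far from the physical spin operator and fails to purify the state.

## Schedules, discretization, propagation

Five schedules are implemented (`Lin` x, `Squ` 3x²−2x³, `Sin` sin(πx/2),
`SinCub` sin³(πx/2), `Cub` 6x⁵−15x⁴+10x³); all are monotone with s(0)=0,
s(1)=1, and `Squ`/`SinCub`/`Cub` have zero initial slope — the property
that matters for BS starts, whose spin multiplet is quasi-degenerate at
s=0. The default discretization is `M = ⌈2T⌉` steps of `dt = T/M`, with
`s` evaluated at the end of each step (`x = m/M`, m = 1…M), matching the
discrete product `e^{−iH_M dt} ⋯ e^{−iH_1 dt}`.

Each step applies the second-order (palindromic, half-angle) Trotter
product by default; first order and `L > 1` repetitions are available. The
term order is re-derived every step from the instantaneous (s-scaled)
coefficients: descending `|ω|` with an ascending-lexicographic tie-break on
the Pauli string for determinism, or plain lexicographic ordering. Sorting
by the s-scaled rather than bare coefficients is a deliberate choice: the
instantaneous coefficients are what enter the step's rotations. The
constant (identity-string) part of the Hamiltonian is applied as an exact
global phase, not a rotation.

Statevector rotations `exp(−iθP)ψ = cosθ·ψ − i sinθ·Pψ` exploit the
permutation-plus-sign structure of a Pauli string on the computational
basis; a compiled fast path precomputes the permutation and sign pattern
per string and is bit-identical to the reference stepper (asserted in the
tests). A full sweep conserves the norm to better than 1e-8.

## Exact references and metrics

All reference quantities are computed by dense diagonalization restricted
to the fixed-(electron count, S_z) sector (dimension 400 for the (6e,6o)
M_S=0 problems; dense up to 4096, sparse Lanczos above). The CASCI target
for overlaps is obtained by first projecting onto the total-spin eigenspace
with `S = |M_S|` and diagonalizing `H` inside it. This matters: at
dissociation the covalent singlet/triplet/quintet/septet multiplet is
quasi-degenerate and an unprojected eigensolver returns arbitrary
spin-mixed combinations; the spin-pure singlet is the physically meaningful
target and is exact because `H` is spin-free.

The gap landscape reports the S₁−S₀ gap of `H(s)` between the two lowest
sector states with `⟨S²⟩ < 0.1` (grid points with fewer than two such
states carry NaN rather than raising). The adiabatic-condition diagnostic
`max_s |⟨Ψ_g|∂_s H|Ψ_e⟩| / (ε_e − ε_g)²` forms `∂_s H = H_P − H_I`
analytically, flags grid points degenerate within 1e-10, and short-circuits
to zero when `H_I = H_P`. Spin-component weights are squared projections
onto `S²` eigenspaces computed sector-wise; the weighted identity
`Σ w(S) S(S+1) = ⟨S²⟩` is property-tested.

## Protocol heuristics

* Diradical characters `y_i = 1 − 2(1−n)/(1+(1−n)²)` take the LUNO+i
  natural-orbital occupations `n ∈ [0,1]` as inputs (from the UHF solution
  supplied with the integrals; computing natural orbitals is outside this
  package's scope).
* Evolution-time rules `T = 20/Δε`, `5/Δε²`, `10/Δε²` consume the RHF
  HOMO–LUMO gap `Δε` (Hartree) recorded in the input metadata rather than
  recomputing it.
* Start switching: broken symmetry iff `max y > 0.6` (strict; `y = 0.6`
  keeps the Hartree–Fock start), bundled with the recommended schedule
  (Sin for HF, Squ for BS), the `20/Δε` rule for HF and a fixed `T = 50`
  for BS, and `c = 0.5`. All defaults are overridable per run.

## Packaged integrals and their generation

The shipped fixtures are N₂/STO-3G with a (6e,6o) valence active space at
R(N–N) = 1.0, 2.0, 3.0 Å and linear BeH₂/STO-3G with the full-valence
(4e,6o) space at R(Be–H) = 0.7, 1.326, 2.0, 2.5, 3.0, 4.0 Å (six
geometries sampling the 0.7–4.0 Å dissociation curve). They were produced
by `scripts/generate_integrals.py`, a self-contained minimal Hartree–Fock
code: McMurchie–Davidson s/p Gaussian integrals, DIIS-converged RHF and
UHF, four-index transformation, frozen-core reduction (4 core orbitals for
N₂, 1 for BeH₂), and FCIDUMP export through the package's writer. Because
plain aufbau SCF at stretched N₂ drops into a symmetry-broken π-rich
configuration, the generator enforces axial-symmetry blocking of the Fock
matrix (σ/π_x/π_y with x↔y equivalencing) and per-block occupation counts
(σ⁵π¹π¹ for N₂, σ³ for BeH₂), the moral equivalent of a production code's
point-group occupancy control. Validation anchors: H₂/STO-3G at 1.4 a₀
gives E(RHF) = −1.1167143 Eh, N₂ at 1.0977 Å gives −107.49589 Eh, the
integrals are rotation/translation invariant to 1e-14, and the N₂
dissociation asymptote equals twice the N-atom UHF energy. Active orbitals
are ordered occupied-first so the FCIDUMP aufbau determinant is the SCF
determinant; metadata (orbital energies, Δε, BS pairings by largest
exchange integral, LUNO occupations, y values) rides in
`data/metadata.yaml`.

## The analytic two-orbital model

`ToyModelSpec` defines a two-spatial-orbital, two-electron model (orbital
energies ε_g, ε_u; Coulomb J_gg, J_uu, J_gu; exchange K_gu; all other
two-electron elements zero), whose M_S = 0 closed-shell block is an exact
2×2 CI with ground energy
`E₀ = core + (H_gg+H_uu)/2 − √(((H_gg−H_uu)/2)² + K_gu²)`,
`H_gg = 2ε_g + J_gg`, `H_uu = 2ε_u + J_uu`, and Hartree–Fock squared
overlap `½(1 − δ/√(δ²+K²))`, `δ = (H_gg−H_uu)/2`. The **dissociation**
preset (degenerate orbitals, J = K = U/2 with U = 0.7 Eh) reproduces the
electronic structure of a covalent bond at infinite separation — exact 50%
Hartree–Fock overlap, degenerate covalent singlet/triplet, fully localized
broken-symmetry orbitals at θ = π/4; the **equilibrium** preset is weakly
correlated. These closed forms are the oracles for the CI solver, the gap
landscape and the adiabatic-bound diagnostics.

What the toy model emulates: the avoided-crossing structure of the sweep,
the spin-multiplet quasi-degeneracy that motivates zero-initial-slope
schedules, and the penalty-driven spin purification. What it does not:
multiple interacting bonds (atomic high-spin recoupling suppresses the
Hartree–Fock weight at dissociation well below the independent-bond
estimate), frozen-core embedding, and dense Hamiltonians with thousands of
Pauli terms. Passing the toy-based tests therefore validates mechanisms,
not molecular hardness; the packaged N₂/BeH₂ fixtures cover the latter.

## Numerical choices

* Coefficient pruning at 1e-12 (fermionic and Pauli); Hermiticity checked
  and imaginary parts ≤ 1e-10 dropped after the mapping.
* Dense matrix oracles capped at 14 qubits; dense sector solves at
  dimension 4096.
* Magnitude-ordering ties broken by ascending lexicographic Pauli string
  (qubit 0 leftmost); identical runs produce byte-identical trajectory
  CSVs.
* Degenerate inputs: empty sectors return empty bases (not errors); grid
  points without two singlet states report NaN gaps; adiabatic-bound grid
  points with gaps below 1e-10 are flagged and excluded from the maximum.
* FCIDUMP reading applies the full 8-fold (restricted) or 4-fold
  (unrestricted blocks) permutation symmetry and rejects duplicate entries
  that disagree by more than 1e-8.

## Known limitations

* Evolution-time claims at intermediate N₂ stretching are landscape
  sensitive. With these independently validated inputs, the
  Hartree–Fock-start sinusoidal sweep at R(N–N) = 2.0 Å needs roughly twice
  the shortest published evolution times to pass 0.9 squared overlap,
  while the quadratic gap rule `T = 10/Δε²`, the broken-symmetry
  acceleration, and the BeH₂ switching protocol all reproduce as published;
  the acceptance report states the measured values without adjustment.
* `S²` on truncated unrestricted active spaces is the projected spin
  operator, exact only when the α and β spans coincide; residual
  contamination after a penalized sweep is correspondingly nonzero (order
  0.01 in the N₂ broken-symmetry run).
* The C₂v Be + H₂ insertion pathway ships as a geometry recipe (Table of
  H-atom coordinates, basis and active-space metadata) plus the generation
  script stub; its published basis is not bundled, and 18-qubit sweeps at
  T ≳ 200 are outside the desk-scale test envelope.
* Problem sizes: the test suite and the acceptance script run 12-qubit
  sweeps with up to ~140 Trotter steps and 2000-term Hamiltonians, chosen
  to complete in about a minute while exercising every code path.
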