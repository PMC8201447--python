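# Methods

## Scope and model assumptions

The package treats exchange-coupled clusters of high-spin magnetic sites as
pure *spin systems*: every magnetic orbital is singly occupied, and the only
electron interaction retained is isotropic spin exchange,
H = Σ_{i<j} J_ij **Ŝ**_i·**Ŝ**_j, with J > 0 antiferromagnetic.  Charge
transfer (metal-to-metal or ligand-to-metal), orbital relaxation, anisotropic
and antisymmetric exchange, and biquadratic/ring corrections are outside the
model; published ab initio energies that contain such effects enter only as
numerical inputs to the exchange-constant extraction.  The sign convention
is fixed by the observable consequences built into the tests: with both
constants positive the singlet manifold lies lowest and the maximal-spin
state highest, and the singlet spacings are proportional to J_4B − J_2B.

## Genealogical CSFs

A CSF over n_o singly occupied orbitals is a sequence of ±1/2 spin
increments with non-negative partial sums (a branching-diagram path).  Such
paths are simultaneous eigenfunctions of every cumulative spin-squared
operator; two distinct paths are orthogonal, so the path set is an
orthonormal spin-adapted basis.  Doubly occupied orbitals never appear in
path enumeration — they are handled only by the Weyl–Paldus counting
formula, which is evaluated in exact integer arithmetic (counts reach ~6e9
and must not round).

The determinant expansion of a path multiplies elementary Clebsch–Gordan
factors for adding one spin-1/2 at a time (Condon–Shortley phases), pruning
prefixes that cannot reach the requested projection.  Its correctness is
established against an independent bit-arithmetic construction of the total
S² operator in the 2^n product space.

## The Hund constraint

For localized orbitals sorted by magnetic center ("atom-separated
ordering"), the physically dominant CSFs keep each site at maximal local
spin.  We formalize the constraint as node reachability on the branching
diagram: a node (j orbitals into site t, cumulative spin S) is allowed iff
S is obtainable by coupling the previous sites at maximal spin with the
partial site at spin j/2, *and* the target total spin remains reachable by
coupling S with the rest of site t at maximal partial spin plus the
remaining sites at maximal spin.  Reachable spin sets are computed exactly
by iterated triangle-rule coupling of half-integer sets.

This reproduces the expected structure: the first site's block is forced
monotone ascending (there the cumulative spin *is* the site spin), the last
block is forced monotone descending for a singlet, and the interior blocks
are unconstrained.  For four s = 5/2 sites and S_total = 0 the census is
Σ_k C(5,k)² = C(10,5) = 252 with per-channel counts C(5,k)², and for four
s = 3/2 sites C(6,3) = 20 — the perfect-square per-dimer pattern.  A
stricter reading ("every within-block step raises the site-internal spin")
would force all blocks monotone and leave one path per channel, which
contradicts the multireference channel counts; the reachability form is
therefore the implemented definition.

The enumeration is written for arbitrary site lists and any reachable
S_total; the quoted figures are verified for the singlet tetramers.

## Why the Hund block decouples exactly

With *site-symmetric* couplings (one intra-site constant per site, one
inter-site constant per site pair) the orbital-level Hamiltonian commutes
with every site **Ŝ**_t².  In the singlet sector of a four-site system,
the first-site and third-boundary cumulative operators equal S_A² and S_D²
respectively (the latter because **Ŝ**_D = −**Ŝ**_ABC on singlets), and both
are diagonal in the genealogical basis.  The Hund-allowed paths are exactly
those with maximal eigenvalues of these two diagonal conserved quantities,
so the 20- (or 252-) dimensional Hund span is an invariant subspace and the
cross-block matrix elements vanish to machine precision — the package
asserts < 1e−12.  With the two-bond/four-bond coupling pattern the pair
operator (S_A+S_B)² is conserved as well, which splits the Hund block into
channel blocks; that is what makes single-CSF initial states channel-selective.
Perturbing the inter-site couplings breaks the symmetry and produces the
quasi-block regime (small but nonzero cross elements), which the block
profiler reports.

## Imaginary-time projector

The deterministic analogue of projective eigensolvers:
x ← normalize((1 − τ(H − E))x), with the shift E updated to the running
Rayleigh quotient and τ defaulting to 0.9·2/(λ_max − λ_min) from Gershgorin
bounds.  Convergence criterion: ‖Hx − Ex‖ < tol (default 1e−10); reaching
max_iter returns an unconverged result carrying the residual.  Started from
a CSF inside one symmetry-decoupled channel, the iteration can never leave
the channel, so it converges to the channel's lowest eigenvalue — verified
against dense per-block diagonalization.

## Model fixtures and problem sizes

The site-symmetric fixture emulates Hund stabilization with a uniform
ferromagnetic intra-site constant, default |J_intra| = 10×max|J_inter|, so
non-Hund states are well separated from the Hund manifold.  Structural and
spectral tests run on the four-site s = 3/2 system (12 orbitals, 132 singlet
CSFs, 20-dim Hund block with four channels) and on random all-pair couplings
up to 10 orbitals, where the full 2^n product space is still cheap to
diagonalize for the independent oracle.  The channel-resolved projector
property is demonstrated on this s = 3/2 model — its 9-dimensional channel
blocks make the claim non-trivial — rather than on the s = 5/2 system, whose
16 796-dimensional CSF Hamiltonian is deliberately out of desk scale; the
s = 5/2 state resolution is instead exercised on the 1296-state HDvV model,
where all six singlet channels are explicit.  These model systems share the
structural phenomenology of real cubanes (dimension, block sizes, ordering
effects, sign coherence) but not their ab initio matrix elements, so passing
tests validate the spin-model machinery, not quantitative ab initio
energetics.

## HDvV tetramer numerics

Site operators are built per site (m ordered +s…−s) and embedded by
Kronecker products; each pair term **Ŝ**_i·**Ŝ**_j = SzSz + (S₊S₋+S₋S₊)/2
is a sum of pure Kronecker chains, so assembling the 1296×1296 Hamiltonian
is cheap.  The bond topology is data: each tetrahedron edge is assigned to
class 2B or 4B in the config, so the two-long-bond and two-short-bond
compounds are the same code path with different labels.

Clebsch–Gordan coefficients use Racah's algebraic sum evaluated in exact
`Fraction` arithmetic, with a float square root only at the end; the
coupled-basis unitary of the s = 5/2 tetramer is orthogonal to ~1e−15 and
diagonalizes the Hamiltonian with off-diagonal residues below 1e−10 relative
to max|J| (the asserted tolerance).  Alternative pairings such as (AC)(BD)
are supported and yield only block-diagonal forms, as expected.  The sympy
CG implementation serves as an independent oracle in the tests only.

## Exchange-constant extraction

Internally the mapping works in the input unit and converts at the
interface; 1 cm⁻¹ = 0.1239841984 meV (CODATA hc — the conversion constant
is a package choice, with reproduction of printed tables to their ±0.1
precision as the accuracy bar).  The ground channel (0 or 2s) is an explicit
input rather than being inferred, because assigning it requires inspecting
wave functions, which is outside the package's scope.  `predict_ladder`
re-zeroes on the ground-channel singlet; if a ferromagnetic parameter choice
pushes another state below it, the zero falls on the actual minimum so
ladders remain non-negative ascending sequences.  Extraction inverts
prediction exactly (float round trip to 1e−10 relative over J ∈ [−100, 200]
cm⁻¹).

## Degenerate and edge inputs

Zero singlet width means J_2B = J_4B (sixfold-degenerate singlets); either
ground channel gives the same constants.  Negative extracted constants are
returned rather than rejected.  Structural sparsity uses a 1e−12 magnitude
threshold.  Unreachable total spins yield empty bases/path lists rather than
errors, except where a basis is required (Hamiltonian construction), which
raises.

## Known limitations

- Hund enumeration is combinatorial; it is instant for tetramers but not
  intended for many-site clusters with large local spins.
- The exchange-Hamiltonian builder expands CSFs over determinants of one Sz
  sector; beyond ~14 orbitals this is the memory bottleneck.
- Only two coupling classes (2B/4B) are modeled in the HDvV layer; lower
  symmetries (three or more distinct J) would need the general J_ij form of
  the orbital-level module.
- The three-state mapping is exact inversion, not least squares; it uses
  exactly two gaps and inherits their uncertainties linearly.
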