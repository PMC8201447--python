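# spincluster

A spin-adapted toolkit for resolving the low-energy spin states of
exchange-coupled polynuclear transition-metal clusters — the archetype being
the fully oxidized [Fe(III)₄S₄] cubane, whose four high-spin d⁵ centers
(S_local = 5/2) couple antiferromagnetically into a dense manifold of
low-lying singlets.

It is written for quantum chemists and molecular magnetism researchers who
want to

- count and enumerate spin-coupling configurations (configuration state
  functions, CSFs) with genealogical branching diagrams,
- understand how orbital localization and *atom-separated ordering* compress
  a spin-adapted CI problem into a small Hund-allowed block that can be
  targeted state by state,
- solve the Heisenberg–Dirac–van Vleck (HDvV) model of a distorted spin
  tetramer exactly, and extract its exchange constants from computed or
  measured state-energy gaps.

## The models

**Counting.** A CAS(N e, n o) spin sector has the Weyl–Paldus dimension
f(N, n, S) = (2S+1)/(n+1) · C(n+1, N/2−S) · C(n+1, N/2+S+1).  Restricting to
singly occupied orbitals (a pure spin-exchange system) gives the van
Vleck–Sherman count g(n_o, S) = C(n_o, n_o/2−S) − C(n_o, n_o/2−S−1): each
such CSF is a monotone path with non-negative partial sums on the branching
diagram.  For 20 unpaired electrons coupled to a singlet, g(20,0) = 16 796
out of f(20,20,0) ≈ 6×10⁹; keeping every site at maximal local spin (the
Hund constraint, natural for localized orbitals sorted by magnetic center)
prunes this to 252 paths, classified by the intermediate pair spin
S_AB = S_CD into channels of size {1, 25, 100, 100, 25, 1}.

**Exchange Hamiltonians.** H = Σ_{i<j} J_ij **Ŝ**_i·**Ŝ**_j over orbital
spin-1/2 operators (J > 0 antiferromagnetic), represented exactly in the
genealogical CSF basis.  With site-symmetric couplings the Hund-allowed
sub-block decouples *exactly* from the spin-flip complement (the Hamiltonian
commutes with every site **Ŝ**²), its off-diagonal elements are
sign-coherent, and a deterministic imaginary-time projector
x ← (1 − τ(H − E))x started from a single channel's CSF converges to that
channel's lowest state rather than the global ground state — state-specific
targeting at model scale.

**HDvV tetramer.**
H = J_2B(**Ŝ**_A·**Ŝ**_B + **Ŝ**_C·**Ŝ**_D) + J_4B(**Ŝ**_A·**Ŝ**_C +
**Ŝ**_A·**Ŝ**_D + **Ŝ**_B·**Ŝ**_C + **Ŝ**_B·**Ŝ**_D), built in the 1296-state
product basis |S_A^z S_B^z S_C^z S_D^z⟩ and diagonalized exactly by the
Clebsch–Gordan unitary to |(S_AB S_CD) S_tot S_tot^z⟩.  Griffith's closed
form

E = J_2B/2 [S_AB(S_AB+1) + S_CD(S_CD+1) − 4s(s+1)]
  + J_4B/2 [S_tot(S_tot+1) − S_AB(S_AB+1) − S_CD(S_CD+1)]

puts the six singlets at (J_4B − J_2B)·{0, 10, 18, 24, 28, 30} above the
|(5,5),0,0⟩ state and the S_tot = 10 state at 55·J_4B.  Two gaps — the
singlet-manifold width and the maximal-spin gap — therefore determine both
constants; `spincluster.mapping` performs this three-state extraction and
the reverse ladder prediction.

## Worked example

Extract the exchange constants of the two-short-bond cubane from its singlet
width (54.3 meV) and S = 10 gap (550.2 meV), using the packaged config:

```bash
$ spincluster extract-j --config src/spincluster/data/compound2.yaml
{
  "j2b": 87.32051161419324,
  "j4b": 72.72187708368196,
  "unit": "cm-1",
  ...
}
```

J_2B ≈ 87.3 cm⁻¹ > J_4B ≈ 72.7 cm⁻¹: the pair singlets form along the two
short bonds, so the ground singlet is the (S_AB = S_CD = 0) channel.  The
same machinery predicts the full ladder from experimentally fitted constants
(J_4B, J_2B) = (70, 82) cm⁻¹:

```bash
$ spincluster ladder --config src/spincluster/data/compound2.yaml \
      --j4b 70 --j2b 82 --unit cm-1
state            E_model   unit
|(0, 0), 0, 0>   0         meV
|(1, 1), 0, 0>   2.97562   meV
|(2, 2), 0, 0>   8.92686   meV
|(3, 3), 0, 0>   17.8537   meV
|(4, 4), 0, 0>   29.7562   meV
|(5, 5), 0, 0>   44.6343   meV
|(5, 5), 10, 0>  521.973   meV
```

— the six singlets span 44.6 meV while the ferromagnetic S = 10 state sits
522 meV up: a strongly antiferromagnetic, spin-frustrated tetramer.
Counting and state-specific projection are equally direct:

```bash
$ spincluster count --orbitals 20 --spin 0
16796
$ spincluster paths --local-spin 5/2 --spin 0
total_hund_paths        252
channel_S_pair=0        1
channel_S_pair=1        25
...
$ spincluster project --local-spin 3/2 --start-channel 3
{"energy": -38.4, "iterations": 1, "converged": true, ...}
```

The projector run starts from the single (Γ⁽³⁾⊗Γ⁽³⁾) Hund CSF of the
12-orbital four-site model and lands on that channel's lowest eigenvalue.

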