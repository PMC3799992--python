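# Methods

`lpmc` simulates a single protein chain on a cubic lattice in an effective
solvent and measures its structure and stochastic dynamics.  This note
records the model, the calibration choices behind the bundled parameter
tables, the numerical machinery, and what the package's tests do and do not
establish.

## Chain model

The chain is a three-dimensional bond-fluctuation polymer.  Each node
occupies the eight vertices of a unit cube anchored at an integer
coordinate; excluded volume forbids any two cubes from sharing a vertex, so
anchors of distinct nodes differ by at least 2 on some axis.  Consecutive
nodes are joined by fluctuating bonds whose squared length must lie in
{4, 5, 6, 9, 10} — bond lengths between 2 and √10 with √8 excluded.  With
single-site moves this admissible set makes bond crossing impossible, which
is what qualifies the model as a true self-avoiding polymer.  There are 108
admissible bond vectors.

A residue is represented by one node (grain 1) or by two or three
consecutive nodes (grains 2 and 3) that all carry the residue's interaction
parameters unchanged; fine graining adds degrees of freedom without
re-normalizing couplings.  Default boxes are 64³ (grain 1), 100³ (grain 2)
and 210³ (grain 3), periodic in all directions.  Coordinates are tracked
unwrapped; wrapped copies drive the occupancy bookkeeping.

The packaged default sequence is the 136-residue human histone H3.1
(`data/h3_1.fasta`); any single-record FASTA with standard one-letter codes
can be substituted.

## Energetics

Every node interacts with non-bonded nodes and with effective-solvent sites
within a cutoff r_c = √8 through a generalized Lennard-Jones kernel

    U(ε, r) = |ε| (σ/r)¹² + ε (σ/r)⁶,   σ = 1 lattice constant.

The r⁻¹² core is always repulsive; the sign of ε decides whether the tail
attracts (ε < 0) or repels (ε > 0).  There is no shifting or tail
correction: the contribution is zero beyond r_c.  The 92 integer offsets
with 0 < |o|² ≤ 8 form the interaction shell (no lattice vector has
|o|² = 7).

**Residue–residue couplings.**  ε_ij is the Miyazawa–Jernigan (1996)
knowledge-based contact-energy table, bundled as a TSV and checksummed at
load time.  The table is divided by its mean magnitude over the 210 distinct
pairs (≈ 3.18), so ε_ij is O(1) and temperature is measured in reduced units
of this characteristic interaction energy.  This normalization places the
coil–globule transition of the unsolvated chain between T = 0.015 and
T = 0.020, inside the studied temperature range T = 0.010–0.040; with the
raw table the chain would still be collapsed at T = 0.04 and the whole
temperature axis would be meaningless.

**Residue–solvent couplings.**  Empty lattice sites — sites covered by no
cube footprint — form the effective solvent.  A node of residue type i
couples to an empty site at squared distance r² with strength f_s·ε_i, where
f_s ≥ 0 is the empirical solvent-quality knob and ε_i is signed by
hydropathy class: positive (solvent-repulsive) for hydrophobic residues
(A, C, F, I, L, M, V), negative (solvent-attractive) for polar
(G, N, P, Q, S, T, W, Y) and charged (D, E, H, K, R) residues.  The bundled
table is the Kyte–Doolittle index divided by its maximum magnitude 4.5; the
model then rescales it by max|ε_jk|/20 ≈ 0.114 so that at the top of the
studied solvent range (f_s = 20) the strongest residue–solvent coupling
equals the strongest residue–residue contact energy.  The f_s axis therefore
sweeps the solvent coupling from zero to contact strength.  Without this
anchoring (couplings of order 1), solvated dynamics at f_s ≥ 5 are frozen at
all temperatures below 0.025 and no solvent response can develop at any run
length.

**Solvent separations.**  Solvent terms enter at r² ∈ {4, 5, 6, 8} — the
same separations at which residue pairs can interact, since excluded volume
sets the closest approach of two anchors to 2.  Sites inside a node's
excluded-volume halo (r² ≤ 3) are not counted as solvent: the kernel at
those separations is one to two orders of magnitude larger than at contact
distance, and counting them produces move barriers tens of times larger than
any structural energy in the model, freezing the chain without affecting its
energy landscape ordering.

Bonded neighbors along the chain are excluded from the pair sum — the
covalent link already constrains them.  Of the 48 cubic point-group
operations, the full energy is exactly invariant under translations, and the
pair part under all signed axis permutations; the solvent sum is measured
from the cube's anchor corner, which reflections do not preserve.  This mild
anisotropy is a standard artifact of the anchored-footprint convention and
has no preferred direction once configurations are ensemble-averaged.

## Dynamics

Metropolis kinetics with single-node, single-site trial moves.  One Monte
Carlo step (MCS) is N attempts, N the node count, with the node drawn
uniformly with replacement and the direction uniform over ±x, ±y, ±z.
Geometric constraints (bond window, excluded volume) are checked first; a
geometrically legal move is accepted with probability min(1, exp(−ΔE/T)).
Temperature is in reduced units (k_B = 1, energies as above).

ΔE is computed incrementally.  Three lattice grids are maintained: cube
coverage (occupancy), anchor → node index, and a solvent field
Φ(s) = Σ_m U(f_s ε_m, |a_m − s|²) that prices the solvent terms all nodes
would gain or lose when a site s is uncovered or covered.  A trial move
costs O(shell); an accepted move additionally updates Φ on the 2 × 92
offsets around the old and new anchors.  The running total energy is
re-derived from scratch at a configurable audit cadence; the observed drift
against the incremental value is ~10⁻¹⁰ over 10⁶ sweeps and the audit also
re-validates every bond and the disjointness of all cube footprints.  The
Python reference implementation in `energetics` computes the same sums
explicitly and the test suite asserts agreement at every dump of short runs.

Reproducibility: one integer base seed; per-sample (initialization, move
stream) seed pairs are derived through `numpy.random.SeedSequence([base,
sample])` and kept below 2³¹.  Identical configurations and observable
series follow from identical seeds.

Initialization grows a random self-avoiding configuration by sequential
placement with uniformly shuffled admissible bond vectors, restarting on
dead ends (bounded).  Growth is mildly biased toward denser configurations
relative to the uniform self-avoiding ensemble; at quasi-frozen state points
(low T in strong solvent) measured exponents reflect this arrested initial
ensemble, which is the physically intended behavior — the same arrest the
model exhibits at full scale.

## Observables

* **R_g** — root-mean-square node distance from the centroid, unwrapped.
* **R_c(t)** — ensemble RMS displacement of the unwrapped center of mass;
  the diffusion exponent is the log-log slope over the later part of the
  record, optionally measured from the equilibration boundary to exclude
  the initial-relaxation transient.  A multi-origin (time-averaged) MSD
  estimator is available for stationary dynamics and is the recommended way
  to measure the exponent: single-origin displacements of a handful of
  walkers scatter far too much to resolve it to ±0.05.  Its fit stops at
  half the maximum lag, beyond which too few independent origins remain.
* **Mobility** — per-node accepted/attempted moves over the equilibrium
  window (the later half of the run by default), reduced to residue level
  by averaging a residue's nodes.
* **Per-residue energy** — pair plus solvent energy of each node, evaluated
  on every equilibrium frame.  Summed over nodes this counts each pair term
  twice and each solvent term once; an identity test pins this bookkeeping.
* **S(q)** — spherically averaged structure factor
  S(q) = ⟨|Σ_j exp(iq·r_j)|²⟩/N, averaged over equilibrium frames and 64
  seeded random unit directions per |q|, on 32 log-spaced magnitudes in
  [2π/L, π].  S(q→0) → N; S ≤ N.
* **Effective dimension D_e** — |slope| of log S vs log q by least squares.
  The default window is box-anchored, q ∈ [4π/L, 1]: length scales from the
  natural lattice wavelength 2π (q = 1 corresponds to a linear distance of
  6.28 lattice constants) up to half the box edge, covering the spread of
  the chain's radius of gyration across conditions.  Below λ = 2π the
  bond-scale correlation hole breaks the power law; above L/2 periodic
  images interfere.  D_e ≈ 1.76 marks a self-avoiding coil, ≈ 2 an ideal
  chain, ≈ 3 a compact globule.  For blob-chain states a two-window mode
  fits the high-q (local, sub-blob) and low-q (chain morphology) regimes
  separately, split at q = 0.55 (λ ≈ 11), where the measured S(q) of the
  blob-chain state crosses over between its two power-law regimes.
* **R_g(f_s) scan** — equilibrium ⟨R_g⟩ over a grid of solvent strengths at
  fixed T; the characteristic strength f_sc is the grid arg-max with
  optional 3-point parabolic refinement, flagged when it falls on the grid
  boundary (no interior peak).

## Synthetic fixtures

`make_fixture` generates deterministic objects with analytic expectations:
homopolymers and random sequences (chain inputs), a rod (R_g closed form,
D_e = 1), Gaussian chains (Debye scattering, D_e = 2 at intermediate q) and
a uniform ball (D_e = 3 over the window covering its size, qR ∈ (1.25, 4),
between the Guinier knee and the first form-factor zero).  These validate
the estimator chain end to end.  They do not emulate lattice discreteness,
excluded volume, or sequence heterogeneity; passing fixture tests
establishes the estimators, not the simulation physics, which is checked
separately (exact Boltzmann equilibrium on the enumerable two-node system,
SAW statistics against a rejection-sampling oracle, audits of the geometric
invariants over 10⁶ sweeps).

## Problem sizes

Production ensembles in the acceptance script and heavy tests use 5–10
independent samples of 2×10⁵–10⁶ MCS on the 64³ box — the package's
standard desk-scale protocol.  Equilibrium averages use the later half of
each run.  At strongly quenched state points (T = 0.010, f_s = 0) the
collapse is complete in most but not all replicas at these lengths; the
ensemble spread of R_g is reported alongside every average.

## Known limitations

* The hydropathy couplings are a documented stand-in built from the
  Kyte–Doolittle index; only their signs, relative magnitudes within
  classes, and the f_s-axis anchoring are constrained.
* Quasi-frozen states (low T, strong solvent) are arrested, not
  equilibrated; exponents measured there characterize the arrested
  ensemble.
* Single chain only; no side-chain nodes; no physical time mapping (the
  MCS is the only clock) and no laboratory-unit calibration.
* Reflection symmetry of the solvent sum is broken at the single-
  configuration level (anchored footprints), exactly compensated by
  ensemble averaging over random initializations.
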