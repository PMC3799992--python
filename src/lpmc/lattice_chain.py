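"""Bond-fluctuation chain on the cubic lattice.

A protein is represented as a chain of nodes on a simple cubic lattice.  Each
node occupies the eight vertices of a unit cube anchored at its coordinate;
excluded volume means no two cubes share a vertex.  Consecutive nodes are
tethered by fluctuating bonds whose length ``l`` satisfies ``2 <= l <= sqrt(10)``
with ``sqrt(8)`` excluded, i.e. the squared bond length lies in {4, 5, 6, 9, 10}.
Together with single-site hops this bond set forbids chain crossing, which is
what makes the model a genuine self-avoiding polymer rather than a lattice
random walk.

Coordinates are kept *unwrapped* (they grow without bound as the chain
diffuses); wrapped coordinates modulo the box edge ``L`` are derived when an
occupancy grid is needed.  The box is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical one-letter amino-acid alphabet used for all type indexing.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Admissible squared bond lengths of the bond-fluctuation model.
ALLOWED_BOND_SQ = frozenset({4, 5, 6, 9, 10})

#: Interaction / bond cutoff squared used for the occupancy bookkeeping.
MAX_BOND_SQ = 10


def _enumerate_bond_vectors() -> np.ndarray:
    out = []
    for x in range(-3, 4):
        for y in range(-3, 4):
            for z in range(-3, 4):
                if x * x + y * y + z * z in ALLOWED_BOND_SQ:
                    out.append((x, y, z))
    return np.array(out, dtype=np.int64)


#: All 108 admissible bond vectors.
BOND_VECTORS = _enumerate_bond_vectors()

#: The eight vertex offsets of a node's unit-cube footprint.
CUBE_OFFSETS = np.array(
    [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)


def validate_bond(delta) -> bool:
    """True iff ``delta`` is an admissible bond vector (|delta|^2 in {4,5,6,9,10})."""
    d = np.asarray(delta, dtype=np.int64)
    return int(d @ d) in ALLOWED_BOND_SQ


@dataclass(frozen=True)
class LatticeSpec:
    """Periodic cubic box of edge ``L`` lattice constants."""

    L: int = 64
    periodic: bool = True

    def __post_init__(self):
        if self.L < 8:
            raise ValueError("lattice edge must be at least 8 (L > 2*r_c)")
        if not self.periodic:
            raise ValueError("only periodic boundaries are supported")


def validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty residue sequence")
    bad = sorted(set(seq) - set(AA_ALPHABET))
    if bad:
        raise ValueError(f"invalid residue letter(s): {', '.join(bad)}")
    return seq


@dataclass
class ChainState:
    """A bond-fluctuation chain configuration.

    ``positions`` are unwrapped anchor coordinates, one row per node; at grain
    g each residue is represented by g consecutive nodes that all carry the
    residue's type.
    """

    positions: np.ndarray          # (N, 3) int64, unwrapped
    sequence: str                  # residue string (length N / grain)
    grain: int
    lattice: LatticeSpec
    node_types: np.ndarray = field(init=False)    # (N,) int64 index into AA_ALPHABET
    node_residue: np.ndarray = field(init=False)  # (N,) int64 residue index

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        n_res = len(self.sequence)
        self.node_residue = np.repeat(np.arange(n_res, dtype=np.int64), self.grain)
        self.node_types = np.array(
            [AA_INDEX[self.sequence[r]] for r in self.node_residue], dtype=np.int64
        )
        if self.positions.shape != (self.n_nodes, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({self.n_nodes}, 3)"
            )

    @property
    def n_nodes(self) -> int:
        return self.grain * len(self.sequence)

    @property
    def L(self) -> int:
        return self.lattice.L

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.L)

    def node_codes(self) -> list[str]:
        return [self.sequence[r] for r in self.node_residue]

    def occupancy(self) -> np.ndarray:
        """uint8 grid of cube-covered lattice sites (1 = covered)."""
        L = self.L
        occ = np.zeros((L, L, L), dtype=np.uint8)
        for p in self.wrapped():
            for o in CUBE_OFFSETS:
                s = (p + o) % L
                occ[s[0], s[1], s[2]] += 1
        if occ.max() > 1:
            raise ValueError("excluded-volume violation: overlapping cube footprints")
        return occ

    def anchor_grid(self) -> np.ndarray:
        """int64 grid mapping wrapped anchor site -> node index + 1 (0 = none)."""
        L = self.L
        grid = np.zeros((L, L, L), dtype=np.int64)
        for i, p in enumerate(self.wrapped()):
            grid[p[0], p[1], p[2]] = i + 1
        return grid

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.sequence, self.grain, self.lattice)


def audit_state(state: ChainState) -> None:
    """Raise ``ValueError`` if any chain invariant is violated."""
    deltas = np.diff(state.positions, axis=0)
    bond_sq = np.einsum("ij,ij->i", deltas, deltas)
    bad = [i for i, b in enumerate(bond_sq) if int(b) not in ALLOWED_BOND_SQ]
    if bad:
        raise ValueError(f"inadmissible bond(s) at index {bad[:5]} (sq={bond_sq[bad[:5]]})")
    state.occupancy()  # raises on overlap
    w = state.wrapped()
    if np.any((state.positions - w) % state.L != 0):
        raise ValueError("unwrapped/wrapped coordinates disagree modulo L")


class GrowthError(RuntimeError):
    """Self-avoiding growth failed (lattice too crowded or pathological seed)."""


def initialize_chain(
    sequence: str,
    grain: int,
    lattice: LatticeSpec,
    rng: np.random.Generator,
    max_restarts: int = 10_000,
) -> ChainState:
    """Grow a random self-avoiding configuration with admissible bonds.

    Nodes are added one at a time with a uniformly shuffled choice among the
    108 admissible bond vectors; a dead end restarts the whole growth.  The
    same generator state always yields the same configuration.
    """
    seq = validate_sequence(sequence)
    if grain not in (1, 2, 3):
        raise ValueError("grain must be 1, 2 or 3")
    n_nodes = grain * len(seq)
    L = lattice.L

    for _ in range(max_restarts):
        occ = np.zeros((L, L, L), dtype=np.uint8)
        pos = np.zeros((n_nodes, 3), dtype=np.int64)
        pos[0] = rng.integers(0, L, size=3)
        _place(occ, pos[0], L)
        ok = True
        for i in range(1, n_nodes):
            order = rng.permutation(len(BOND_VECTORS))
            for k in order:
                cand = pos[i - 1] + BOND_VECTORS[k]
                if _free(occ, cand, L):
                    pos[i] = cand
                    _place(occ, cand, L)
                    break
            else:
                ok = False
                break
        if ok:
            return ChainState(pos, seq, grain, lattice)
    raise GrowthError(
        f"self-avoiding growth failed after {max_restarts} restarts "
        f"({n_nodes} nodes on a {L}^3 lattice)"
    )


def _place(occ: np.ndarray, p: np.ndarray, L: int) -> None:
    for o in CUBE_OFFSETS:
        s = (p + o) % L
        occ[s[0], s[1], s[2]] = 1


def _free(occ: np.ndarray, p: np.ndarray, L: int) -> bool:
    for o in CUBE_OFFSETS:
        s = (p + o) % L
        if occ[s[0], s[1], s[2]]:
            return False
    return True


#: The six single-site trial displacements (+/- x, y, z).
MOVE_DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


def move_is_legal(
    state: ChainState, node: int, candidate: np.ndarray, occ: np.ndarray | None = None
) -> bool:
    """Geometric legality of moving ``node`` to ``candidate`` (bonds + excluded volume)."""
    candidate = np.asarray(candidate, dtype=np.int64)
    if node > 0 and not validate_bond(candidate - state.positions[node - 1]):
        return False
    if node < state.n_nodes - 1 and not validate_bond(
        candidate - state.positions[node + 1]
    ):
        return False
    if occ is None:
        occ = state.occupancy()
    L = state.L
    old_sites = {tuple((state.positions[node] + o) % L) for o in CUBE_OFFSETS}
    for o in CUBE_OFFSETS:
        s = tuple((candidate + o) % L)
        if s not in old_sites and occ[s]:
            return False
    return True


def propose_move(state: ChainState, node: int, rng: np.random.Generator):
    """Draw a uniform single-site trial move for ``node``.

    Returns ``(candidate, legal)``; the state is not modified.
    """
    if not 0 <= node < state.n_nodes:
        raise IndexError(f"node index {node} out of range")
    direction = MOVE_DIRECTIONS[rng.integers(0, 6)]
    candidate = state.positions[node] + direction
    return candidate, move_is_legal(state, node, candidate)
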