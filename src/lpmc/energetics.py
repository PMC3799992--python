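"""Interaction energies: residue-residue and residue-solvent couplings.

Every node interacts with other (non-bonded) nodes and with empty lattice
sites within a cutoff ``r_c = sqrt(8)`` through a generalized Lennard-Jones
kernel

    U(eps, r) = |eps| (sigma/r)^12 + eps (sigma/r)^6,      sigma = 1,

whose hard core is always repulsive while the sign of ``eps`` decides whether
the tail attracts (eps < 0) or repels (eps > 0).  Residue-residue strengths
``eps_ij`` come from the Miyazawa-Jernigan knowledge-based contact table;
residue-solvent strengths are ``f_s * eps_i`` with ``eps_i`` a hydropathy-based
per-residue coupling (positive for hydrophobic residues, negative for polar
and charged ones) and ``f_s`` the solvent-quality knob.

Empty lattice sites — sites covered by no node's cube footprint — constitute
the effective solvent.  The cutoff shell around an anchor contains exactly 92
lattice sites (all integer offsets with 0 < |o|^2 <= 8; note |o|^2 = 7 has no
integer representation).

Everything here is a plain NumPy reference implementation; the hot Monte
Carlo loop in :mod:`lpmc._kernel` reimplements the same sums and is audited
against these functions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .lattice_chain import AA_ALPHABET, AA_INDEX, CUBE_OFFSETS, ChainState

R2_CUT = 8

#: Smallest squared separation at which solvent terms enter: the same
#: closest-approach distance excluded volume imposes on residue pairs.
SOLVENT_R2_MIN = 4


def _enumerate_shell() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    offs, r2s, own = [], [], []
    for x in range(-2, 3):
        for y in range(-2, 3):
            for z in range(-2, 3):
                r2 = x * x + y * y + z * z
                if 0 < r2 <= R2_CUT:
                    offs.append((x, y, z))
                    r2s.append(r2)
                    own.append(x in (0, 1) and y in (0, 1) and z in (0, 1))
    return (
        np.array(offs, dtype=np.int64),
        np.array(r2s, dtype=np.int64),
        np.array(own, dtype=bool),
    )


@dataclass(frozen=True)
class PotentialSpec:
    """Interaction kernel geometry: sigma, cutoff, and the 92-site shell."""

    sigma: float = 1.0
    r2_cut: int = R2_CUT
    shell: np.ndarray = field(default_factory=lambda: _enumerate_shell()[0])
    shell_r2: np.ndarray = field(default_factory=lambda: _enumerate_shell()[1])
    shell_own: np.ndarray = field(default_factory=lambda: _enumerate_shell()[2])


def pair_potential(eps: float, r2, sigma: float = 1.0):
    """Generalized LJ energy at squared separation ``r2`` (0 beyond the cutoff).

    Accepts scalar or array ``r2``; ``r2 == 0`` is an excluded-volume breach
    and raises.
    """
    r2 = np.asarray(r2, dtype=np.float64)
    if np.any(r2 == 0):
        raise ValueError("r2 = 0: two entities on one site (excluded-volume breach)")
    s2 = sigma * sigma / r2
    u = np.where(r2 <= R2_CUT, abs(eps) * s2**6 + eps * s2**3, 0.0)
    return float(u) if u.ndim == 0 else u


# ---------------------------------------------------------------------------
# bundled interaction tables


def _data_path(name: str):
    return resources.files("lpmc.data").joinpath(name)


def _checksum(path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_contact_matrix(path=None) -> tuple[np.ndarray, str]:
    """Load a 20x20 symmetric contact-energy table (TSV, one-letter labels).

    Returns the matrix indexed by :data:`AA_ALPHABET` order and a short
    checksum for provenance logging.  Defaults to the bundled
    Miyazawa-Jernigan (1996) contact energies.
    """
    p = _data_path("mj1996_contact_energies.tsv") if path is None else path
    df = pd.read_csv(p, sep="\t", index_col=0)
    if sorted(df.index) != sorted(AA_ALPHABET) or sorted(df.columns) != sorted(
        AA_ALPHABET
    ):
        raise ValueError("contact table must be labeled by the 20 one-letter codes")
    df = df.loc[list(AA_ALPHABET), list(AA_ALPHABET)]
    m = df.to_numpy(dtype=np.float64)
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix is not symmetric")
    try:
        digest = _checksum(p)
    except AttributeError:  # plain string path
        with open(p, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()[:16]
    return m, digest


def load_solvent_couplings(path=None) -> tuple[np.ndarray, dict[str, str], str]:
    """Load per-residue solvent couplings eps_i and H/P/E class labels."""
    p = _data_path("hydropathy_solvent_couplings.tsv") if path is None else path
    df = pd.read_csv(p, sep="\t")
    if sorted(df["res"]) != sorted(AA_ALPHABET):
        raise ValueError("solvent table must cover the 20 one-letter codes")
    eps = np.zeros(20)
    classes: dict[str, str] = {}
    for _, row in df.iterrows():
        eps[AA_INDEX[row["res"]]] = float(row["eps_i"])
        classes[row["res"]] = str(row["class"])
    for a in AA_ALPHABET:
        e, c = eps[AA_INDEX[a]], classes[a]
        if c == "H" and e <= 0 or c in ("P", "E") and e >= 0:
            raise ValueError(f"sign of eps_i({a}) inconsistent with class {c}")
    try:
        digest = _checksum(p)
    except AttributeError:
        with open(p, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()[:16]
    return eps, classes, digest


@dataclass
class InteractionModel:
    """Complete energetics: contact matrix, solvent couplings, and f_s."""

    contact: np.ndarray                 # (20, 20) eps_ij
    eps_solvent: np.ndarray             # (20,) eps_i
    f_s: float = 0.0
    potential: PotentialSpec = field(default_factory=PotentialSpec)
    provenance: dict = field(default_factory=dict)

    def pair_table(self) -> np.ndarray:
        """(20, 20, 9) lookup: U(eps_ij, r2) for r2 = 0..8 (entry 0 unused)."""
        if getattr(self, "_ptab", None) is None:
            tab = np.zeros((20, 20, R2_CUT + 1))
            for r2 in range(1, R2_CUT + 1):
                if r2 == 7:
                    continue  # no lattice vector has |o|^2 = 7
                for i in range(20):
                    for j in range(20):
                        tab[i, j, r2] = pair_potential(self.contact[i, j], r2)
            self._ptab = tab
        return self._ptab

    def solvent_table(self) -> np.ndarray:
        """(20, 9) lookup: U(f_s * eps_i, r2) for r2 = 0..8.

        Solvent terms enter at the same separations at which residue pairs
        can interact, r2 in {4, 5, 6, 8}: sites inside a node's
        excluded-volume halo (r2 < 4) are not counted as solvent.
        """
        if getattr(self, "_stab", None) is None:
            tab = np.zeros((20, R2_CUT + 1))
            for r2 in range(SOLVENT_R2_MIN, R2_CUT + 1):
                if r2 == 7:
                    continue
                for i in range(20):
                    eff = self.f_s * self.eps_solvent[i]
                    tab[i, r2] = pair_potential(eff, r2) if eff != 0.0 else 0.0
            self._stab = tab
        return self._stab


def default_model(f_s: float = 0.0, normalize: bool = True) -> InteractionModel:
    """Bundled MJ + hydropathy energetics at solvent strength ``f_s``.

    With ``normalize`` (the default) the contact table is divided by its mean
    magnitude over the 210 distinct pairs, putting eps_ij on the same O(1)
    scale as the solvent couplings eps_i: temperature is measured in reduced
    units of this characteristic interaction energy.

    The hydropathy couplings are normalized so that at the top of the studied
    solvent range (f_s = 20) the strongest residue-solvent coupling equals
    the strongest residue-residue contact energy: eps_i = (KD_i / 4.5) *
    max|eps_jk| / 20.  This anchors the meaning of the empirical f_s axis —
    f_s sweeps the solvent coupling from zero up to contact strength.
    """
    contact, c_digest = load_contact_matrix()
    scale = 1.0
    if normalize:
        iu = np.triu_indices(20)
        scale = float(np.abs(contact[iu]).mean())
        contact = contact / scale
    eps, classes, s_digest = load_solvent_couplings()
    solvent_scale = float(np.abs(contact).max()) / 20.0
    eps = eps * solvent_scale
    return InteractionModel(
        contact,
        eps,
        f_s=f_s,
        provenance={
            "contact_checksum": c_digest,
            "solvent_checksum": s_digest,
            "contact_scale": scale,
            "solvent_scale": solvent_scale,
            "classes": classes,
        },
    )


# ---------------------------------------------------------------------------
# reference energy sums (slow, explicit; the MC kernel is audited against these)


def _shell_scan(state: ChainState, anchor: int, pos, occ, agrid, model):
    """Pair and solvent sums around unwrapped position ``pos`` for node ``anchor``."""
    spec = model.potential
    L = state.L
    utab = model.pair_table()
    stab = model.solvent_table()
    t_i = state.node_types[anchor]
    e_pair = 0.0
    e_solv = 0.0
    for o, r2, own in zip(spec.shell, spec.shell_r2, spec.shell_own):
        s = tuple((pos + o) % L)
        m = agrid[s] - 1
        if m >= 0 and m != anchor and abs(m - anchor) != 1:
            e_pair += utab[t_i, state.node_types[m], r2]
        if model.f_s != 0.0 and not own and occ[s] == 0:
            e_solv += stab[t_i, r2]
    return e_pair, e_solv


def residue_energy(state: ChainState, node: int, model: InteractionModel) -> float:
    """Energy of one node: non-bonded pairs plus solvent sites within r_c."""
    occ = state.occupancy()
    agrid = state.anchor_grid()
    e_pair, e_solv = _shell_scan(state, node, state.positions[node], occ, agrid, model)
    return e_pair + e_solv


def node_energies(state: ChainState, model: InteractionModel) -> np.ndarray:
    occ = state.occupancy()
    agrid = state.anchor_grid()
    out = np.zeros(state.n_nodes)
    for n in range(state.n_nodes):
        e_p, e_s = _shell_scan(state, n, state.positions[n], occ, agrid, model)
        out[n] = e_p + e_s
    return out


def total_energy(state: ChainState, model: InteractionModel) -> float:
    """Total energy: each non-bonded pair once plus all node-solvent terms."""
    occ = state.occupancy()
    agrid = state.anchor_grid()
    e_pair = 0.0
    e_solv = 0.0
    for n in range(state.n_nodes):
        e_p, e_s = _shell_scan(state, n, state.positions[n], occ, agrid, model)
        e_pair += e_p
        e_solv += e_s
    return 0.5 * e_pair + e_solv


def delta_energy(
    state: ChainState, node: int, candidate, model: InteractionModel
) -> float:
    """Incremental total-energy change if ``node`` moved to ``candidate``.

    Only terms involving the moving node change: its own pair and solvent
    sums, plus the solvent terms other nodes gain/lose where the node's cube
    footprint uncovers/covers lattice sites.  Equals the full-recompute
    difference to numerical precision.
    """
    candidate = np.asarray(candidate, dtype=np.int64)
    old = state.positions[node]
    if np.array_equal(candidate, old):
        return 0.0
    L = state.L
    occ = state.occupancy()
    agrid = state.anchor_grid()
    # remove the moving node from the grids
    for o in CUBE_OFFSETS:
        s = tuple((old + o) % L)
        occ[s] = 0
    agrid[tuple(old % L)] = 0

    e_old = sum(_shell_scan(state, node, old, occ, agrid, model))
    e_new = sum(_shell_scan(state, node, candidate, occ, agrid, model))

    d_block = 0.0
    if model.f_s != 0.0:
        stab = model.solvent_table()
        spec = model.potential
        old_sites = {tuple((old + o) % L) for o in CUBE_OFFSETS}
        new_sites = {tuple((candidate + o) % L) for o in CUBE_OFFSETS}

        def blocked(site_w) -> float:
            # solvent terms other nodes lose while `site_w` is covered
            tot = 0.0
            for o, r2 in zip(spec.shell, spec.shell_r2):
                a = tuple((np.asarray(site_w) - o) % L)
                m = agrid[a] - 1
                if m >= 0:
                    tot += stab[state.node_types[m], r2]
            return tot

        for s in old_sites - new_sites:
            d_block += blocked(s)       # freed: other nodes regain these terms
        for s in new_sites - old_sites:
            d_block -= blocked(s)       # newly covered: other nodes lose them
    return e_new - e_old + d_block
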