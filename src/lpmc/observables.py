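"""Measured quantities: size, dynamics, structure factor and scaling fits.

All geometric observables use unwrapped coordinates: periodic wrapping would
corrupt the radius of gyration, the center-of-mass displacement and the
structure factor alike.

The central scaling diagnostic is the spherically averaged structure factor

    S(q) = (1/N) < | sum_j exp(i q . r_j) |^2 >,

averaged over ensemble frames and random unit directions per wave-vector
magnitude.  Over a window of length scales covering the chain (lattice
constant pair distance up to ~2 R_g) a power law S(q) ~ q^(-1/nu) holds and
the magnitude of the log-log slope estimates the effective dimension
D_e ~ 1/nu: about 1.76 for a self-avoiding coil, 2 for an ideal chain, 3 for
a compact globule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernel
from .lattice_chain import ChainState
from .mc_engine import EnsembleResult, RunConfig, run_ensemble
from .multigrain import GrainMap, residue_level_reduce


# ---------------------------------------------------------------------------
# size and dynamics


def radius_of_gyration(positions) -> float:
    """RMS distance of nodes from their centroid (unwrapped coordinates)."""
    if isinstance(positions, ChainState):
        positions = positions.positions
    r = np.asarray(positions, dtype=np.float64)
    d = r - r.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->i", d, d).mean()))


def rms_com_displacement(
    frames_ensemble,
    times,
    fit_window: tuple[float, float] | None = None,
    origin: int = 0,
    time_average: bool = False,
):
    """Ensemble RMS displacement of the center of mass, R_c(t), plus exponent.

    ``frames_ensemble`` is a sequence of per-sample trajectories (n_rec, N, 3).
    Returns ``(R_c, exponent, se)`` where the exponent is the log-log slope of
    R_c vs t over ``fit_window`` (default: the later three quarters of the
    displacement record, skipping t = 0).  ``origin`` selects the reference
    record; measuring from the equilibration boundary instead of the initial
    configuration removes the transient while the chain relaxes from its
    random starting state.  ``time_average`` switches to the multi-origin MSD
    estimator (valid once the dynamics are stationary).
    """
    times = np.asarray(times, dtype=np.float64)
    if len(times) - origin < 2:
        raise ValueError("need at least two frames past the origin")
    times = times[origin:] - times[origin]
    coms = [
        np.asarray(frames, dtype=np.float64)[origin:].mean(axis=1)
        for frames in frames_ensemble
    ]
    if time_average:
        # stationary-regime estimator: average |COM(t0+tau) - COM(t0)|^2 over
        # all time origins t0 as well as over replicas; far lower variance
        # than the single-origin displacement of a handful of walkers
        n = len(times)
        n_tau = n // 2
        msd = np.zeros(n_tau)
        for com in coms:
            for k in range(1, n_tau):
                d = com[k:] - com[:-k]
                msd[k] += np.einsum("ij,ij->i", d, d).mean()
        msd /= len(coms)
        times = times[:n_tau]
        rc = np.sqrt(msd)
        if fit_window is None:
            # beyond half the lag range too few independent origins remain
            fit_window = (times[1], times[-1] / 2.0)
    else:
        msd = np.zeros(len(times))
        for com in coms:
            disp = com - com[0]
            msd += np.einsum("ij,ij->i", disp, disp)
        msd /= len(coms)
        rc = np.sqrt(msd)

    if fit_window is None:
        fit_window = (times[-1] / 4.0, times[-1])
    lo, hi = fit_window
    mask = (times >= lo) & (times <= hi) & (times > 0) & (rc > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 frames in the fit window")
    fit = stats.linregress(np.log(times[mask]), np.log(rc[mask]))
    return rc, float(fit.slope), float(fit.stderr)


# ---------------------------------------------------------------------------
# structure factor


@dataclass
class SqProfile:
    """Spherically averaged structure factor with optional fitted slopes."""

    q: np.ndarray
    S: np.ndarray
    n_nodes: int
    fits: list[dict] = None  # filled by fit_effective_dimension

    def __post_init__(self):
        if self.fits is None:
            self.fits = []


def default_q_grid(L: int, n_q: int = 32) -> np.ndarray:
    """Log-spaced wave-vector magnitudes in [2*pi/L, pi]."""
    return np.geomspace(2 * np.pi / L, np.pi, n_q)


def _unit_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def structure_factor(
    frames, q_grid, n_directions: int = 64, seed: int = 12345
) -> SqProfile:
    """S(|q|) averaged over frames and random unit directions per |q|.

    ``frames`` is (F, N, 3) (or a single (N, 3) configuration).  The seeded
    direction sample makes the estimator reproducible.
    """
    r = np.asarray(frames, dtype=np.float64)
    if r.ndim == 2:
        r = r[None]
    if r.size == 0:
        raise ValueError("empty ensemble")
    F, N, _ = r.shape
    q_grid = np.asarray(q_grid, dtype=np.float64)
    rng = np.random.default_rng(seed)
    S = np.zeros(len(q_grid))
    for iq, qm in enumerate(q_grid):
        dirs = _unit_directions(n_directions, rng)          # (D, 3)
        phase = np.einsum("fnj,dj->fdn", r, qm * dirs)      # (F, D, N)
        amp2 = np.abs(np.exp(1j * phase).sum(axis=2)) ** 2  # (F, D)
        S[iq] = amp2.mean() / N
    return SqProfile(q_grid, S, N)


def window_covering_rg(
    rg: float, lam_min: float = 2.0, rg_factor: float = 2.0
) -> tuple[float, float]:
    """q-window for length scales lam_min .. rg_factor * R_g (q = 2*pi/lambda)."""
    return (2 * np.pi / (rg_factor * rg), 2 * np.pi / lam_min)


def default_fit_window(L: int) -> tuple[float, float]:
    """Box-anchored scaling window q in [4*pi/L, 1].

    Length scales from the natural lattice wavelength 2*pi (q = 1 corresponds
    to a linear distance of 6.28 lattice constants) up to half the box edge,
    which covers the spread of the radius of gyration of the chain across
    solvent conditions.  Below lambda = 2*pi the discrete monomer structure
    (bond-scale correlation hole) breaks the power law; above L/2 periodic
    images interfere.
    """
    return (4 * np.pi / L, 1.0)


def blob_windows(
    L: int, q_split: float = 0.55
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(high_q, low_q) windows for blob-chain states, split at ``q_split``.

    The high-q window probes scales below the blob size (local globular
    assembly), the low-q window the large-scale chain morphology.  The split
    defaults to the blob scale lambda = 2*pi/q_split ~ 11 lattice constants,
    where the measured S(q) of the blob-chain state crosses over between its
    two power-law regimes.
    """
    lo, hi = default_fit_window(L)
    return (q_split, hi), (lo, q_split)


def fit_effective_dimension(
    profile: SqProfile, window: tuple[float, float]
) -> tuple[float, float]:
    """|slope| of log S vs log q over ``window``; records the fit on the profile.

    Returns ``(D_e, standard error)``.  Requires at least 4 grid points inside
    the window and strictly positive S.
    """
    lo, hi = window
    mask = (profile.q >= lo) & (profile.q <= hi)
    if mask.sum() < 4:
        raise ValueError(f"fewer than 4 grid points in fit window {window}")
    if np.any(profile.S[mask] <= 0):
        raise ValueError("non-positive S(q) in fit window")
    fit = stats.linregress(np.log(profile.q[mask]), np.log(profile.S[mask]))
    de = float(abs(fit.slope))
    se = float(fit.stderr)
    profile.fits.append(
        {"window": (float(lo), float(hi)), "n_points": int(mask.sum()),
         "D_e": de, "se": se}
    )
    return de, se


def ensemble_sq(
    result: EnsembleResult, n_q: int = 32, n_directions: int = 64, seed: int = 12345
) -> SqProfile:
    """Equilibrium S(q) of an ensemble run on the default q grid."""
    frames = result.equilibrium_frames()
    return structure_factor(
        frames, default_q_grid(result.config.lattice.L, n_q), n_directions, seed
    )


def effective_dimension_of_run(
    result: EnsembleResult, two_windows: bool = False, **sq_kw
):
    """Fit D_e over the window covering the spread of R_g.

    Returns ``(profile, [(D_e, se), ...])`` — one fit for the single-window
    mode, (high-q, low-q) fits when ``two_windows`` is set.
    """
    profile = ensemble_sq(result, **sq_kw)
    L = result.config.lattice.L
    if two_windows:
        windows = blob_windows(L)
    else:
        windows = (default_fit_window(L),)
    return profile, [fit_effective_dimension(profile, w) for w in windows]


# ---------------------------------------------------------------------------
# residue-level profiles


@dataclass
class ResidueProfile:
    residue_index: np.ndarray   # 1-based
    codes: list[str]
    mean_energy: np.ndarray
    energy_se: np.ndarray
    mobility: np.ndarray
    mobility_se: np.ndarray


def residue_profiles(result: EnsembleResult) -> ResidueProfile:
    """Equilibrium per-residue mean energy and mobility (ensemble averages).

    Node energies are evaluated on every equilibrium frame; mobility is the
    per-node fraction of accepted attempts over the equilibrium window.  At
    fine grain both are averaged over each residue's nodes.
    """
    cfg = result.config
    model = result.model
    mask = result.equilibrium_mask()
    if not mask.any():
        raise ValueError("empty equilibrium window")
    L = cfg.lattice.L
    utab = model.pair_table()
    stab = model.solvent_table()
    use_solvent = bool(model.f_s != 0.0)
    seq = result.sequence
    gm = GrainMap.for_sequence(len(seq), cfg.grain)
    t0 = (1.0 - cfg.equil_fraction) * cfg.steps

    per_sample_e, per_sample_m = [], []
    for s in result.samples:
        types = _node_types(seq, cfg.grain)
        e_nodes = np.zeros(gm.n_nodes)
        frames = s.frames[mask]
        for fr in frames:
            posw = np.mod(fr, L)
            occ, agrid, _ = _kernel._build_grids(
                posw, L, False, types, stab, _kernel.SHELL, _kernel.SHELL_R2
            )
            e_nodes += _kernel._node_energies(
                posw, types, occ, agrid, utab, stab, use_solvent,
                _kernel.SHELL, _kernel.SHELL_R2, _kernel.SHELL_OWN, L,
            )
        e_nodes /= len(frames)
        per_sample_e.append(residue_level_reduce(e_nodes, gm))
        per_sample_m.append(residue_level_reduce(s.ledger.mobility(t0), gm))

    e = np.array(per_sample_e)
    m = np.array(per_sample_m)
    n = e.shape[0]
    se = lambda a: a.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(a.shape[1])
    return ResidueProfile(
        np.arange(1, len(seq) + 1),
        list(seq),
        e.mean(axis=0),
        se(e),
        m.mean(axis=0),
        se(m),
    )


def _node_types(sequence: str, grain: int) -> np.ndarray:
    from .lattice_chain import AA_INDEX

    return np.array(
        [AA_INDEX[c] for c in sequence for _ in range(grain)], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# solvent-strength scan


@dataclass
class SolventScan:
    f_s: np.ndarray
    rg_mean: np.ndarray
    rg_se: np.ndarray
    T: float
    f_sc: float
    on_boundary: bool


def find_characteristic_fs(
    fs_grid, rg_values, refine: bool = True
) -> tuple[float, bool]:
    """Peak location of R_g(f_s): grid arg-max with optional parabolic refinement.

    Returns ``(f_sc, on_boundary)``; when the maximum sits on the scanned-grid
    boundary no interior peak exists and the flag is raised.
    """
    fs = np.asarray(fs_grid, dtype=np.float64)
    rg = np.asarray(rg_values, dtype=np.float64)
    if len(fs) < 3 or len(fs) != len(rg):
        raise ValueError("need a grid of at least 3 matching f_s / R_g values")
    k = int(np.argmax(rg))
    if k == 0 or k == len(fs) - 1:
        return float(fs[k]), True
    f_sc = float(fs[k])
    if refine:
        x = fs[k - 1 : k + 2]
        y = rg[k - 1 : k + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (
            x[2] ** 2 * (y[0] - y[1])
            + x[1] ** 2 * (y[2] - y[0])
            + x[0] ** 2 * (y[1] - y[2])
        ) / denom
        if a < 0:
            vertex = -b / (2 * a)
            if x[0] < vertex < x[2]:
                f_sc = float(vertex)
    return f_sc, False


def solvent_scan(
    sequence: str, T: float, fs_grid, config: RunConfig, refine: bool = True
) -> SolventScan:
    """Equilibrium <R_g>(f_s) over a grid of solvent strengths at fixed T."""
    fs_grid = np.asarray(fs_grid, dtype=np.float64)
    if len(fs_grid) < 3:
        raise ValueError("need at least 3 f_s values")
    means, ses = [], []
    for fs in fs_grid:
        res = run_ensemble(sequence, config.with_(T=T, f_s=float(fs)))
        m, s = res.rg_equilibrium()
        means.append(m)
        ses.append(s)
    means = np.array(means)
    ses = np.array(ses)
    f_sc, boundary = find_characteristic_fs(fs_grid, means, refine=refine)
    return SolventScan(fs_grid, means, ses, T, f_sc, boundary)
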