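"""Metropolis kinetics: acceptance law, determinism, equilibrium distribution."""

import math

import numpy as np
import pytest
from scipy import stats

from lpmc import energetics as en
from lpmc.lattice_chain import (
    BOND_VECTORS,
    CUBE_OFFSETS,
    ChainState,
    LatticeSpec,
    audit_state,
    move_is_legal,
)
from lpmc.mc_engine import (
    RunConfig,
    metropolis_accept,
    mc_sweep,
    run_ensemble,
    run_sample,
    sample_seeds,
)


def test_metropolis_downhill_always_accepted(rng):
    assert all(metropolis_accept(-1.0, t, rng) for t in (0.001, 1.0, 100.0)
               for _ in range(100))


def test_metropolis_rate_at_de_equal_t(rng):
    # empirical acceptance at dE = T is exp(-1)
    n = 100_000
    hits = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n))
    assert hits / n == pytest.approx(math.exp(-1), abs=0.005)


def test_metropolis_freezes_at_low_t(rng):
    assert not any(metropolis_accept(1.0, 1e-4, rng) for _ in range(10_000))


def test_sample_seed_derivation_stable():
    a = sample_seeds(42, 3)
    assert a == sample_seeds(42, 3)
    assert a != sample_seeds(42, 4)
    assert all(0 <= s < 2**31 for s in a)


def test_run_determinism(h31_sequence):
    cfg = RunConfig(T=0.02, f_s=2.0, steps=400, samples=2, seed=9,
                    dump_interval=100, audit_interval=200, lattice=LatticeSpec(64))
    r1 = run_ensemble(h31_sequence, cfg)
    r2 = run_ensemble(h31_sequence, cfg)
    for a, b in zip(r1.samples, r2.samples):
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.energies, b.energies)


def test_record_layout_and_equilibrium_window():
    cfg = RunConfig(T=0.05, steps=2, samples=1, seed=1, dump_interval=1,
                    audit_interval=0, lattice=LatticeSpec(16))
    res = run_ensemble("MA", cfg)
    assert list(res.times) == [0, 1, 2]
    # later half of the run is the averaging window
    assert list(res.equilibrium_mask()) == [False, True, True]


def test_kernel_energy_matches_reference_and_audits(h31_sequence):
    """Running incremental energy equals the explicit reference at every dump."""
    for f_s in (0.0, 5.0):
        model = en.default_model(f_s)
        cfg = RunConfig(T=0.02, f_s=f_s, steps=600, samples=1, seed=3,
                        dump_interval=150, audit_interval=200,
                        lattice=LatticeSpec(64))
        s = run_sample(h31_sequence, cfg, model)
        assert s.geometry_violations == 0
        assert s.max_energy_drift < 1e-9
        for k in range(len(s.times)):
            st = ChainState(s.frames[k], h31_sequence, 1, cfg.lattice)
            audit_state(st)
            assert s.energies[k] == pytest.approx(
                en.total_energy(st, model), abs=1e-8
            )


def test_long_run_geometry_audits_clean():
    """Bond-window and excluded-volume audits over a million sweeps."""
    cfg = RunConfig(T=0.05, f_s=2.0, steps=1_000_000, samples=1, seed=11,
                    dump_interval=100_000, audit_interval=10_000,
                    lattice=LatticeSpec(16))
    s = run_sample("MARTKQTARKSTGGKA", cfg, en.default_model(2.0))
    assert s.geometry_violations == 0
    assert s.max_energy_drift < 1e-9
    final = ChainState(s.frames[-1], "MARTKQTARKSTGGKA", 1, cfg.lattice)
    audit_state(final)


def _frozen_cluster_state():
    """3x3x3 block of anchors spaced 2: the central node cannot move at all."""
    layer = [(0, 0), (1, 0), (2, 0), (2, 1), (1, 1), (0, 1), (0, 2), (1, 2), (2, 2)]
    order = []
    for iz in range(3):
        path = layer if iz % 2 == 0 else list(reversed(layer))
        order.extend((x, y, iz) for x, y in path)
    pos = np.array([[4 + 2 * x, 4 + 2 * y, 4 + 2 * z] for x, y, z in order],
                   dtype=np.int64)
    state = ChainState(pos, "A" * 27, 1, LatticeSpec(16))
    audit_state(state)
    center = order.index((1, 1, 1))
    return state, center


def test_frozen_interior_node_is_blocked():
    """Every single-site move of a fully caged interior node is illegal."""
    state, center = _frozen_cluster_state()
    for d in np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                       [0, 0, 1], [0, 0, -1]]):
        assert not move_is_legal(state, center, state.positions[center] + d)


def _jammed_periodic_state():
    """64 cubes on the even sublattice of an 8^3 box: every site covered."""
    layer = []
    for y in range(4):
        xs = range(4) if y % 2 == 0 else range(3, -1, -1)
        layer.extend((x, y) for x in xs)
    order = []
    for z in range(4):
        path = layer if z % 2 == 0 else list(reversed(layer))
        order.extend((x, y, z) for x, y in path)
    pos = np.array([[2 * x, 2 * y, 2 * z] for x, y, z in order], dtype=np.int64)
    state = ChainState(pos, "A" * 64, 1, LatticeSpec(8))
    audit_state(state)
    return state


def test_fully_jammed_box_has_zero_accepts():
    """At full packing no trial move can satisfy excluded volume."""
    state = _jammed_periodic_state()
    assert state.occupancy().sum() == 8**3  # every lattice site covered
    cfg = RunConfig(T=1e6, steps=20, samples=1, seed=2, dump_interval=20,
                    lattice=LatticeSpec(8))
    _, attempts, accepts = mc_sweep(state, en.default_model(0.0), cfg, 77,
                                    n_sweeps=20)
    assert attempts.sum() == 20 * 64
    assert accepts.sum() == 0


def test_two_node_boltzmann_equilibrium():
    """Stationary distribution over all 108 relative configurations.

    For a 2-node chain every legal state is a translation x relative bond
    vector; translations are uniform, so the visited bond-vector histogram
    must match exact Boltzmann weights of the enumerated energies.
    """
    L = 16
    T = 0.5
    model = en.default_model(2.0)
    energies = {}
    for v in BOND_VECTORS:
        pos = np.array([[6, 6, 6], [6 + v[0], 6 + v[1], 6 + v[2]]], dtype=np.int64)
        st = ChainState(pos, "MR", 1, LatticeSpec(L))
        energies[tuple(v)] = en.total_energy(st, model)
    e = np.array([energies[tuple(v)] for v in BOND_VECTORS])
    w = np.exp(-(e - e.min()) / T)
    p = w / w.sum()

    state = ChainState(np.array([[6, 6, 6], [8, 6, 6]], dtype=np.int64), "MR", 1,
                       LatticeSpec(L))
    cfg = RunConfig(T=T, f_s=2.0, steps=100, samples=1, seed=5, dump_interval=100,
                    lattice=LatticeSpec(L))
    index = {tuple(v): k for k, v in enumerate(BOND_VECTORS)}
    counts = np.zeros(len(BOND_VECTORS))
    n_obs = 4000
    for i in range(n_obs):
        mc_sweep(state, model, cfg, move_seed=1000 + i, n_sweeps=25)
        counts[index[tuple(state.positions[1] - state.positions[0])]] += 1

    expected = p * n_obs
    # pool rare states so every chi^2 bin has expectation >= 5
    order = np.argsort(expected)
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for k in order:
        acc_o += counts[k]
        acc_e += expected[k]
        if acc_e >= 5:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    obs_b[-1] += acc_o
    exp_b[-1] += acc_e
    chi2 = (np.subtract(obs_b, exp_b) ** 2 / np.array(exp_b)).sum()
    pval = stats.chi2.sf(chi2, df=len(obs_b) - 1)
    assert pval > 0.01


def test_saw_ensemble_matches_static_sampler():
    """Zero couplings: MC equilibrium R_g equals a direct SAW-sampling oracle."""
    n = 14
    zero = en.InteractionModel(np.zeros((20, 20)), np.zeros(20), f_s=0.0)
    cfg = RunConfig(T=1.0, steps=30_000, samples=4, seed=21, dump_interval=500,
                    audit_interval=10_000, lattice=LatticeSpec(32))
    res = run_ensemble("A" * n, cfg, zero)
    rg_mc, se_mc = res.rg_equilibrium()

    # rejection sampling: uniform over admissible-bond walks, keep self-avoiding
    rng = np.random.default_rng(99)
    rgs = []
    while len(rgs) < 400:
        steps = BOND_VECTORS[rng.integers(0, len(BOND_VECTORS), size=n - 1)]
        pos = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        d = pos[:, None, :] - pos[None, :, :]
        clash = (np.abs(d) <= 1).all(axis=2)
        np.fill_diagonal(clash, False)
        if not clash.any():
            c = pos - pos.mean(axis=0)
            rgs.append(np.sqrt((c**2).sum(axis=1).mean()))
    rg_saw = float(np.mean(rgs))
    se_saw = float(np.std(rgs, ddof=1) / math.sqrt(len(rgs)))
    assert abs(rg_mc - rg_saw) < 3 * math.hypot(se_mc, se_saw) + 0.02


def test_mobility_increases_with_temperature(h31_sequence):
    """Seed-averaged acceptance of the chain grows monotonically with T."""
    rates = []
    for i, T in enumerate([0.010, 0.020, 0.040]):
        cfg = RunConfig(T=T, f_s=0.0, steps=4_000, samples=3, seed=31,
                        dump_interval=1_000, audit_interval=0,
                        lattice=LatticeSpec(64))
        res = run_ensemble(h31_sequence, cfg)
        accept = np.mean([
            s.ledger.accepts[-1].sum() / s.ledger.attempts[-1].sum()
            for s in res.samples
        ])
        rates.append(accept)
    assert rates[0] < rates[1] < rates[2]


def test_geometric_acceptance_at_high_temperature():
    """At T >> couplings the acceptance equals the purely geometric rate."""
    seq = "A" * 20
    zero = en.InteractionModel(np.zeros((20, 20)), np.zeros(20), f_s=0.0)
    rates = []
    for model, T in ((en.default_model(0.0), 1e7), (zero, 1.0)):
        cfg = RunConfig(T=T, f_s=0.0, steps=10_000, samples=2, seed=13,
                        dump_interval=5_000, audit_interval=0,
                        lattice=LatticeSpec(32))
        res = run_ensemble(seq, cfg, model)
        rates.append(np.mean([
            s.ledger.accepts[-1].sum() / s.ledger.attempts[-1].sum()
            for s in res.samples
        ]))
    assert rates[0] == pytest.approx(rates[1], abs=0.01)


def test_config_validation():
    with pytest.raises(ValueError):
        RunConfig(T=-1.0)
    with pytest.raises(ValueError):
        RunConfig(steps=1)
    with pytest.raises(ValueError):
        RunConfig(grain=5)
    with pytest.raises(ValueError):
        RunConfig(f_s=-2.0)
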