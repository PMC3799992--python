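"""Metropolis kinetics and ensemble orchestration.

Time is measured in Monte Carlo steps (MCS): one MCS is N attempted
single-node moves with the node drawn uniformly with replacement, N being
the number of chain nodes.  Geometric constraints (bond window, excluded
volume) are enforced before the Boltzmann test ``min(1, exp(-dE/T))``.

An ensemble run draws ``samples`` independent replicas, each with its own
initialization and move stream derived from one base seed, and records
observables at a fixed dump cadence.  Equilibrium averages use the later
half of the run by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel, energetics
from .lattice_chain import ChainState, LatticeSpec, initialize_chain, validate_sequence


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one ensemble run (reduced units throughout)."""

    T: float = 0.020
    f_s: float = 0.0
    steps: int = 100_000          # MCS per sample
    samples: int = 10
    seed: int = 0
    dump_interval: int = 1_000
    audit_interval: int = 5_000
    grain: int = 1
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    equil_fraction: float = 0.5   # later fraction of the run used for averages

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.f_s < 0:
            raise ValueError("f_s must be non-negative")
        if self.steps < 2 or self.samples < 1:
            raise ValueError("need steps >= 2 and samples >= 1")
        if self.dump_interval < 1:
            raise ValueError("dump_interval must be positive")
        if self.dump_interval > self.steps:
            object.__setattr__(self, "dump_interval", self.steps)
        if self.grain not in (1, 2, 3):
            raise ValueError("grain must be 1, 2 or 3")
        if not 0.0 < self.equil_fraction < 1.0:
            raise ValueError("equil_fraction must be in (0, 1)")

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def sample_seeds(base_seed: int, sample: int) -> tuple[int, int]:
    """Deterministic (init_seed, move_seed) pair for one replica.

    Derived from the base seed and the sample index through a SeedSequence so
    replicas are statistically independent; both values stay below 2^31.
    """
    ss = np.random.SeedSequence([int(base_seed), int(sample)])
    a, b = ss.generate_state(2, np.uint32)
    return int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Boltzmann acceptance min(1, exp(-dE/T))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if dE <= 0:
        return True
    return rng.random() < math.exp(-dE / T)


@dataclass
class AcceptanceLedger:
    """Per-node attempt/accept counters, cumulative at each dump time."""

    times: np.ndarray      # (n_rec,) MCS
    attempts: np.ndarray   # (n_rec, N)
    accepts: np.ndarray    # (n_rec, N)

    def window_counts(self, t_start: float) -> tuple[np.ndarray, np.ndarray]:
        """(attempts, accepts) per node accrued at times > t_start."""
        idx = np.searchsorted(self.times, t_start, side="right") - 1
        idx = max(idx, 0)
        return (
            self.attempts[-1] - self.attempts[idx],
            self.accepts[-1] - self.accepts[idx],
        )

    def mobility(self, t_start: float = 0.0) -> np.ndarray:
        att, acc = self.window_counts(t_start)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(att > 0, acc / np.maximum(att, 1), 0.0)
        return m


@dataclass
class SampleResult:
    """Trajectory and bookkeeping of one replica."""

    times: np.ndarray       # (n_rec,) MCS of each record (0, dump, 2*dump, ...)
    frames: np.ndarray      # (n_rec, N, 3) unwrapped anchors
    energies: np.ndarray    # (n_rec,) running total energy
    ledger: AcceptanceLedger
    max_energy_drift: float
    geometry_violations: int
    init_seed: int
    move_seed: int

    @property
    def final_state_positions(self) -> np.ndarray:
        return self.frames[-1]


@dataclass
class EnsembleResult:
    sequence: str
    config: RunConfig
    model: energetics.InteractionModel
    samples: list[SampleResult]

    @property
    def times(self) -> np.ndarray:
        return self.samples[0].times

    def equilibrium_mask(self) -> np.ndarray:
        t0 = (1.0 - self.config.equil_fraction) * self.config.steps
        return self.times >= t0

    def equilibrium_frames(self) -> np.ndarray:
        """(n_eq_frames_total, N, 3) pooled over samples."""
        mask = self.equilibrium_mask()
        return np.concatenate([s.frames[mask] for s in self.samples], axis=0)

    def rg_series(self) -> np.ndarray:
        """(samples, n_rec) radius of gyration at each record."""
        from .observables import radius_of_gyration

        out = np.zeros((len(self.samples), len(self.times)))
        for i, s in enumerate(self.samples):
            for j in range(len(self.times)):
                out[i, j] = radius_of_gyration(s.frames[j])
        return out

    def rg_equilibrium(self) -> tuple[float, float]:
        """Ensemble mean and standard error of equilibrium R_g."""
        mask = self.equilibrium_mask()
        per_sample = self.rg_series()[:, mask].mean(axis=1)
        n = len(per_sample)
        se = per_sample.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        return float(per_sample.mean()), float(se)


def run_sample(
    sequence: str,
    config: RunConfig,
    model: energetics.InteractionModel,
    sample: int = 0,
) -> SampleResult:
    """One replica: seeded growth, ``config.steps`` sweeps, dumped observables."""
    seq = validate_sequence(sequence)
    init_seed, move_seed = sample_seeds(config.seed, sample)
    state = initialize_chain(
        seq, config.grain, config.lattice, np.random.default_rng(init_seed)
    )
    pos = state.positions.copy()
    use_solvent = bool(model.f_s != 0.0 and np.any(model.eps_solvent != 0.0))
    frames, energies, attempts, accepts, drift, violations = _kernel.run_chain(
        pos,
        state.node_types,
        config.lattice.L,
        config.steps,
        config.T,
        model.pair_table(),
        model.solvent_table(),
        use_solvent,
        config.dump_interval,
        config.audit_interval,
        move_seed,
    )
    if violations:
        raise RuntimeError(
            f"geometry audit failed in sample {sample}: {violations} violation(s)"
        )
    n_rec = frames.shape[0]
    times = np.arange(n_rec, dtype=np.int64) * config.dump_interval
    ledger = AcceptanceLedger(times, attempts, accepts)
    return SampleResult(
        times, frames, energies, ledger, float(drift), int(violations),
        init_seed, move_seed,
    )


def mc_sweep(
    state: ChainState,
    model: energetics.InteractionModel,
    config: RunConfig,
    move_seed: int,
    n_sweeps: int = 1,
):
    """Advance ``state`` by ``n_sweeps`` MCS in place; returns per-node counters.

    Thin wrapper over the compiled kernel for stepwise use; ensemble runs
    should go through :func:`run_ensemble`.
    """
    use_solvent = bool(model.f_s != 0.0 and np.any(model.eps_solvent != 0.0))
    frames, energies, attempts, accepts, drift, violations = _kernel.run_chain(
        state.positions,
        state.node_types,
        state.L,
        n_sweeps,
        config.T,
        model.pair_table(),
        model.solvent_table(),
        use_solvent,
        n_sweeps,          # single dump at the end
        0,                 # no audit inside a short stepwise call
        move_seed,
    )
    if violations:
        raise RuntimeError("geometry audit failed during sweep")
    return energies, attempts[-1], accepts[-1]


def run_ensemble(
    sequence: str,
    config: RunConfig,
    model: energetics.InteractionModel | None = None,
) -> EnsembleResult:
    """Run ``config.samples`` independent replicas of one condition."""
    if model is None:
        model = energetics.default_model(config.f_s)
    elif model.f_s != config.f_s:
        raise ValueError("model.f_s disagrees with config.f_s")
    results = [
        run_sample(sequence, config, model, sample=k) for k in range(config.samples)
    ]
    return EnsembleResult(validate_sequence(sequence), config, model, results)
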