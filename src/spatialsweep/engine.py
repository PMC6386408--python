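"""Stochastic simulation of spatial soft sweeps on a periodic deme lattice.

The reduced, deme-level model: every deme carries a single allelic identity
(0 = wildtype, k >= 1 = the k-th beneficial mutation to arise).  Two event
types compete:

* mutation -- a uniformly chosen wildtype deme acquires a fresh allele label,
  with per-deme rate ``u_tilde`` (mutations per dispersal attempt);
* migration -- a uniformly chosen mutant deme launches a jump whose distance
  is drawn from the power-law kernel and whose direction is isotropic; the
  target deme (periodic wrapping) adopts the source allele only if it is
  still wildtype (allelic exclusion), otherwise the attempt fails.

Per event, the mutation branch is taken with probability
``u_tilde*n_wt / (u_tilde*n_wt + n_mut)`` -- equivalent to assigning weight
``u_tilde`` to each wildtype deme and 1 to each mutant deme.  Time is measured
in units of the expected interval between dispersal events per deme and
advances by an exponential increment of mean 1/R, R = n_mut + u_tilde*n_wt
(a deterministic 1/R increment is available for variance-reduced growth
curves).  The simulation runs until no wildtype deme remains, which is an
absorbing state, so termination is guaranteed.

The inner loop is JIT-compiled with numba; category membership is maintained
with swap-and-pop index lists so every event is O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kernels import KernelSpec

__all__ = [
    "SweepConfig",
    "LatticeState",
    "EventCounts",
    "SweepResult",
    "run_sweep",
    "run_sweep_ensemble",
]

_DEFAULT_MAX_EVENTS = 20_000_000_000


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of one sweep simulation.

    Attributes
    ----------
    L : int
        Linear range size; the lattice holds L**dim demes.
    u_tilde : float
        Rescaled mutation rate (mutations per dispersal attempt per deme).
    kernel : KernelSpec
        Dispersal law; also fixes the habitat dimension.
    seed : int
        Seed for the replicate's random stream.
    snapshot_times : tuple of float
        Rescaled times at which to record full lattice snapshots.
    deterministic_time : bool
        Advance time by 1/R instead of an exponential increment of mean 1/R.
    record_fill_times : bool
        Store the time at which each deme was colonized.
    max_events : int
        Resource guard; the run aborts with a diagnostic if exceeded.
    """

    L: int
    u_tilde: float
    kernel: KernelSpec
    seed: int = 0
    snapshot_times: tuple = ()
    deterministic_time: bool = False
    record_fill_times: bool = False
    max_events: int = _DEFAULT_MAX_EVENTS

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not self.u_tilde > 0:
            raise ValueError(f"u_tilde must be positive, got {self.u_tilde}")

    @property
    def dim(self) -> int:
        return self.kernel.dim

    @property
    def n_demes(self) -> int:
        return self.L**self.dim


@dataclass
class LatticeState:
    """Integer lattice of allele identities (0 = wildtype)."""

    grid: np.ndarray  # shape (L,) in 1D, (L, L) in 2D

    @property
    def n_mutant(self) -> int:
        return int(np.count_nonzero(self.grid))

    @property
    def n_alleles(self) -> int:
        m = int(self.grid.max(initial=0))
        return m


@dataclass(frozen=True)
class EventCounts:
    mutations: int
    migrations_ok: int
    migrations_failed: int

    @property
    def total(self) -> int:
        return self.mutations + self.migrations_ok + self.migrations_failed


@dataclass
class SweepResult:
    """Complete output of one sweep: final lattice, per-allele origins, log."""

    final_state: LatticeState
    origin_demes: np.ndarray  # flat deme index of each allele's origin, 1-based labels
    origin_times: np.ndarray
    event_counts: EventCounts
    total_time: float
    config: SweepConfig
    seed: int
    fill_times: np.ndarray | None = None
    snapshots: list = field(default_factory=list)  # (time, grid) pairs

    @property
    def n_alleles(self) -> int:
        return len(self.origin_demes)

    def origin_coords(self, allele_id: int) -> tuple:
        """Lattice coordinates of the originating mutation of ``allele_id``."""
        flat = int(self.origin_demes[allele_id - 1])
        if self.config.dim == 1:
            return (flat,)
        return divmod(flat, self.config.L)

    def clone_masses(self) -> np.ndarray:
        """Number of demes per allele, in label order; sums to L**dim."""
        counts = np.bincount(self.final_state.grid.ravel(), minlength=self.n_alleles + 1)
        return counts[1:]


# ---------------------------------------------------------------------------
# numba event loops
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sweep_core(n_demes, L, dim, u_tilde, mu, seed, det_time, record_fill, snap_times, max_events):
    np.random.seed(seed)
    grid = np.zeros(n_demes, np.int64)
    wt = np.arange(n_demes)
    wt_pos = np.arange(n_demes)
    mut = np.empty(n_demes, np.int64)
    n_wt = n_demes
    n_mut = 0
    orig_deme = np.empty(n_demes, np.int64)
    orig_time = np.empty(n_demes, np.float64)
    if record_fill:
        fill = np.full(n_demes, np.nan)
    else:
        fill = np.empty(0, np.float64)
    n_snap = snap_times.size
    snaps = np.zeros((n_snap, n_demes), np.int64)
    snap_t = np.zeros(n_snap, np.float64)
    next_snap = 0
    n_alleles = 0
    t = 0.0
    n_mutation = 0
    n_ok = 0
    n_fail = 0
    inv_mu = 1.0 / mu
    two_pi = 2.0 * np.pi
    n_ev = 0
    while n_wt > 0:
        n_ev += 1
        if n_ev > max_events:
            return (grid, n_alleles, orig_deme, orig_time, t, n_mutation, n_ok, n_fail, fill, snaps, snap_t, next_snap, 1)
        rate = n_mut + u_tilde * n_wt
        if det_time:
            t += 1.0 / rate
        else:
            t += np.random.exponential(1.0 / rate)
        while next_snap < n_snap and t >= snap_times[next_snap]:
            snaps[next_snap, :] = grid
            snap_t[next_snap] = t
            next_snap += 1
        if np.random.random() * rate < u_tilde * n_wt:
            # mutation: fresh allele label at a uniform wildtype deme
            i = np.random.randint(0, n_wt)
            deme = wt[i]
            n_alleles += 1
            grid[deme] = n_alleles
            orig_deme[n_alleles - 1] = deme
            orig_time[n_alleles - 1] = t
            last = wt[n_wt - 1]
            wt[i] = last
            wt_pos[last] = i
            n_wt -= 1
            mut[n_mut] = deme
            n_mut += 1
            if record_fill:
                fill[deme] = t
            n_mutation += 1
        else:
            src = mut[np.random.randint(0, n_mut)]
            uu = 1.0 - np.random.random()  # (0, 1]
            r = uu**-inv_mu
            if r > 1.0e15:
                r = 1.0e15
            if dim == 1:
                k = np.int64(r + 0.5)
                if np.random.random() < 0.5:
                    tgt = (src + k) % L
                else:
                    tgt = (src - k) % L
            else:
                theta = two_pi * np.random.random()
                dx = np.int64(np.floor(r * np.cos(theta) + 0.5))
                dy = np.int64(np.floor(r * np.sin(theta) + 0.5))
                sx = src // L
                sy = src % L
                tgt = ((sx + dx) % L) * L + (sy + dy) % L
            if grid[tgt] == 0:
                grid[tgt] = grid[src]
                i = wt_pos[tgt]
                last = wt[n_wt - 1]
                wt[i] = last
                wt_pos[last] = i
                n_wt -= 1
                mut[n_mut] = tgt
                n_mut += 1
                if record_fill:
                    fill[tgt] = t
                n_ok += 1
            else:
                n_fail += 1
    return (grid, n_alleles, orig_deme, orig_time, t, n_mutation, n_ok, n_fail, fill, snaps, snap_t, next_snap, 0)


@njit(cache=True)
def _solitary_core(n_demes, L, dim, mu, seed, det_time, mass_max, t_max, max_events):
    """Single clone expanding into wildtype (no recurrent mutation).

    Starts from one mutant deme at the origin; records (time, mass) at every
    successful colonization.  Stops when the clone mass reaches ``mass_max``
    or time exceeds ``t_max``.
    """
    np.random.seed(seed)
    grid = np.zeros(n_demes, np.int64)
    mut = np.empty(mass_max, np.int64)
    grid[0] = 1
    mut[0] = 0
    n_mut = 1
    times = np.empty(mass_max, np.float64)
    masses = np.empty(mass_max, np.int64)
    times[0] = 0.0
    masses[0] = 1
    n_rec = 1
    t = 0.0
    inv_mu = 1.0 / mu
    two_pi = 2.0 * np.pi
    n_ev = 0
    while n_mut < mass_max and t < t_max:
        n_ev += 1
        if n_ev > max_events:
            return times, masses, n_rec, grid, t, 1
        if det_time:
            t += 1.0 / n_mut
        else:
            t += np.random.exponential(1.0 / n_mut)
        src = mut[np.random.randint(0, n_mut)]
        uu = 1.0 - np.random.random()
        r = uu**-inv_mu
        if r > 1.0e15:
            r = 1.0e15
        if dim == 1:
            k = np.int64(r + 0.5)
            if np.random.random() < 0.5:
                tgt = (src + k) % L
            else:
                tgt = (src - k) % L
        else:
            theta = two_pi * np.random.random()
            dx = np.int64(np.floor(r * np.cos(theta) + 0.5))
            dy = np.int64(np.floor(r * np.sin(theta) + 0.5))
            sx = src // L
            sy = src % L
            tgt = ((sx + dx) % L) * L + (sy + dy) % L
        if grid[tgt] == 0:
            grid[tgt] = 1
            mut[n_mut] = tgt
            n_mut += 1
            times[n_rec] = t
            masses[n_rec] = n_mut
            n_rec += 1
    return times, masses, n_rec, grid, t, 0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def run_sweep(config: SweepConfig) -> SweepResult:
    """Run one sweep to global fixation and return the complete result."""
    snap_times = np.asarray(sorted(config.snapshot_times), dtype=float)
    (grid, n_alleles, orig_deme, orig_time, t, n_mutation, n_ok, n_fail, fill, snaps, snap_t, n_snap_done, err) = _sweep_core(
        config.n_demes,
        config.L,
        config.dim,
        config.u_tilde,
        config.kernel.mu,
        config.seed,
        config.deterministic_time,
        config.record_fill_times,
        snap_times,
        config.max_events,
    )
    if err:
        raise RuntimeError(
            f"sweep aborted: event count exceeded max_events={config.max_events} "
            f"(L={config.L}, dim={config.dim}, mu={config.kernel.mu}, u_tilde={config.u_tilde})"
        )
    shape = (config.L,) if config.dim == 1 else (config.L, config.L)
    snapshots = [(float(snap_t[i]), snaps[i].reshape(shape).copy()) for i in range(n_snap_done)]
    return SweepResult(
        final_state=LatticeState(grid.reshape(shape)),
        origin_demes=orig_deme[:n_alleles].copy(),
        origin_times=orig_time[:n_alleles].copy(),
        event_counts=EventCounts(n_mutation, n_ok, n_fail),
        total_time=float(t),
        config=config,
        seed=config.seed,
        fill_times=fill.reshape(shape) if config.record_fill_times else None,
        snapshots=snapshots,
    )


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` distinct 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(2 * n, dtype=np.uint64)
    seeds: list[int] = []
    seen: set[int] = set()
    for v in state:
        s = int(v % (2**31 - 1)) + 1
        if s not in seen:
            seen.add(s)
            seeds.append(s)
        if len(seeds) == n:
            return seeds
    # astronomically unlikely fallback
    s = 1
    while len(seeds) < n:
        if s not in seen:
            seeds.append(s)
            seen.add(s)
        s += 1
    return seeds


def run_sweep_ensemble(config: SweepConfig, n_reps: int, seeds=None) -> list[SweepResult]:
    """Run independent replicates of ``config`` with distinct recorded seeds.

    If ``seeds`` is omitted, distinct per-replicate seeds are derived from
    ``config.seed`` via a seed sequence.  Duplicate explicit seeds are an
    error: replicates must be independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seeds is None:
        seeds = spawn_seeds(config.seed, n_reps)
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_reps:
        raise ValueError(f"need {n_reps} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds in ensemble")
    results = []
    for s in seeds:
        cfg = SweepConfig(
            L=config.L,
            u_tilde=config.u_tilde,
            kernel=config.kernel,
            seed=s,
            snapshot_times=config.snapshot_times,
            deterministic_time=config.deterministic_time,
            record_fill_times=config.record_fill_times,
            max_events=config.max_events,
        )
        results.append(run_sweep(cfg))
    return results
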