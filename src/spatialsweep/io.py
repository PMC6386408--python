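"""Result serialization, run manifests, and synthetic fixture lattices.

On-disk layout of a saved sweep (one directory per replicate):

* ``grid.tsv``    -- one row per deme: flat index (1D) or ``x  y`` (2D,
  row-major, 0-based), then the allele label;
* ``origins.tsv`` -- one row per allele: label, origin coordinates, origin
  time (rescaled units);
* ``meta.json``   -- config echo, seed, event counts, total time, format
  version.

Fixture generators produce labeled lattices with known geometry (equal
contiguous tessellations) or clone-mass ensembles drawn from a prescribed
size density, so every analysis stage can be tested without running sweeps.
All fixtures are synthetic and say so in their metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import EventCounts, LatticeState, SweepConfig, SweepResult
from .kernels import KernelSpec

__all__ = [
    "FORMAT_VERSION",
    "SchemaError",
    "RunManifest",
    "make_tessellation_fixture",
    "make_spectrum_fixture",
    "save_result",
    "load_result",
]

FORMAT_VERSION = 1


class SchemaError(ValueError):
    """Saved result does not match the expected on-disk schema/version."""


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_tessellation_fixture(L: int, n_clones: int, dim: int = 1) -> SweepResult:
    """Deterministic synthetic lattice of equal contiguous clones (1D).

    The ring is divided into ``n_clones`` segments of mass L/n_clones with
    origins at segment centers -- the geometry behind the equal-clone null
    model for subrange statistics.  ``n_clones`` must divide L.  The config
    echo carries placeholder kernel/mutation-rate values; the lattice is
    synthetic, not the outcome of a simulation.
    """
    if dim != 1:
        raise NotImplementedError("tessellation fixtures are 1D")
    if L % n_clones != 0:
        raise ValueError(f"n_clones={n_clones} must divide L={L}")
    X = L // n_clones
    grid = np.repeat(np.arange(1, n_clones + 1), X).astype(np.int64)
    origins = (np.arange(n_clones) * X + X // 2).astype(np.int64)
    cfg = SweepConfig(L=L, u_tilde=1.0, kernel=KernelSpec(mu=4.0, dim=1), seed=0)
    return SweepResult(
        final_state=LatticeState(grid),
        origin_demes=origins,
        origin_times=np.arange(1, n_clones + 1, dtype=float),
        event_counts=EventCounts(n_clones, L - n_clones, 0),
        total_time=float(n_clones),
        config=cfg,
        seed=0,
    )


def make_spectrum_fixture(
    n_clones: int,
    L: int,
    seed: int = 0,
    p: float | None = None,
    x_c: float | None = None,
    sampler=None,
    n_sims: int = 1,
) -> list[np.ndarray]:
    """Clone-mass lists drawn from a prescribed size density (synthetic).

    Either give the hard-cutoff power-law ansatz parameters ``(p, x_c)``
    (sizes ~ x**p on (0, x_c], drawn by inverse CDF) or an arbitrary
    ``sampler(rng, n) -> positive sizes``.  Sizes are renormalized and
    rounded to integers summing exactly to L**d by the largest-remainder
    method; zero-mass clones are dropped.
    """
    rng = np.random.default_rng(seed)
    if sampler is None:
        if p is None or x_c is None:
            raise ValueError("give (p, x_c) or a sampler")
        if not -1.0 < p <= 1.0 or not 0.0 < x_c <= 1.0:
            raise ValueError("degenerate density: need -1 < p <= 1 and 0 < x_c <= 1")

        def sampler(r, n):
            return x_c * r.random(n) ** (1.0 / (p + 1.0))

    out = []
    for _ in range(n_sims):
        sizes = np.asarray(sampler(rng, n_clones), dtype=float)
        if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)) or sizes.sum() <= 0:
            raise ValueError("degenerate density: sampler returned non-positive sizes")
        target = sizes / sizes.sum() * L
        base = np.floor(target).astype(np.int64)
        remainder = target - base
        deficit = L - int(base.sum())
        order = np.argsort(-remainder, kind="stable")
        base[order[:deficit]] += 1
        masses = base[base > 0]
        assert masses.sum() == L
        out.append(masses)
    return out


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def save_result(result: SweepResult, path) -> None:
    """Write a SweepResult to ``path`` (a directory) as TSV tables + JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    L, dim = cfg.L, cfg.dim
    flat = result.final_state.grid.ravel()
    with open(path / "grid.tsv", "w") as fh:
        if dim == 1:
            fh.write("# deme\tallele\n")
            for i, a in enumerate(flat):
                fh.write(f"{i}\t{a}\n")
        else:
            fh.write("# x\ty\tallele\n")
            for i, a in enumerate(flat):
                fh.write(f"{i // L}\t{i % L}\t{a}\n")
    with open(path / "origins.tsv", "w") as fh:
        if dim == 1:
            fh.write("# allele\tdeme\ttime\n")
            for k in range(result.n_alleles):
                fh.write(f"{k + 1}\t{result.origin_demes[k]}\t{float(result.origin_times[k])!r}\n")
        else:
            fh.write("# allele\tx\ty\ttime\n")
            for k in range(result.n_alleles):
                x, y = divmod(int(result.origin_demes[k]), L)
                fh.write(f"{k + 1}\t{x}\t{y}\t{float(result.origin_times[k])!r}\n")
    meta = {
        "format_version": FORMAT_VERSION,
        "L": L,
        "dim": dim,
        "mu": cfg.kernel.mu,
        "u_tilde": cfg.u_tilde,
        "seed": result.seed,
        "deterministic_time": cfg.deterministic_time,
        "n_alleles": result.n_alleles,
        "total_time": result.total_time,
        "event_counts": {
            "mutations": result.event_counts.mutations,
            "migrations_ok": result.event_counts.migrations_ok,
            "migrations_failed": result.event_counts.migrations_failed,
        },
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_result(path) -> SweepResult:
    """Read a SweepResult saved by :func:`save_result`; lossless round-trip.

    Raises :class:`SchemaError` on version mismatch, missing files,
    truncation, or inconsistent tables.
    """
    path = Path(path)
    try:
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError as e:
        raise SchemaError(f"not a saved result: {e}") from None
    except json.JSONDecodeError as e:
        raise SchemaError(f"corrupt meta.json: {e}") from None
    if meta.get("format_version") != FORMAT_VERSION:
        raise SchemaError(
            f"format version {meta.get('format_version')} != {FORMAT_VERSION}"
        )
    L, dim = int(meta["L"]), int(meta["dim"])
    n_demes = L**dim
    try:
        grid_tab = np.loadtxt(path / "grid.tsv", dtype=np.int64, ndmin=2)
        orig_tab = np.loadtxt(path / "origins.tsv", dtype=float, ndmin=2)
    except (OSError, ValueError) as e:
        raise SchemaError(f"corrupt table: {e}") from None
    if grid_tab.shape != (n_demes, dim + 1):
        raise SchemaError(
            f"grid.tsv has shape {grid_tab.shape}, expected {(n_demes, dim + 1)} (truncated?)"
        )
    if orig_tab.shape != (int(meta["n_alleles"]), dim + 2):
        raise SchemaError(
            f"origins.tsv has shape {orig_tab.shape}, expected "
            f"{(int(meta['n_alleles']), dim + 2)} (truncated?)"
        )
    flat_idx = (
        grid_tab[:, 0] if dim == 1 else grid_tab[:, 0] * L + grid_tab[:, 1]
    )
    grid = np.empty(n_demes, dtype=np.int64)
    grid[flat_idx] = grid_tab[:, -1]
    origin_demes = (
        orig_tab[:, 1].astype(np.int64)
        if dim == 1
        else (orig_tab[:, 1] * L + orig_tab[:, 2]).astype(np.int64)
    )
    cfg = SweepConfig(
        L=L,
        u_tilde=float(meta["u_tilde"]),
        kernel=KernelSpec(mu=float(meta["mu"]), dim=dim),
        seed=int(meta["seed"]),
        deterministic_time=bool(meta["deterministic_time"]),
    )
    ev = meta["event_counts"]
    shape = (L,) if dim == 1 else (L, L)
    return SweepResult(
        final_state=LatticeState(grid.reshape(shape)),
        origin_demes=origin_demes,
        origin_times=orig_tab[:, -1].copy(),
        event_counts=EventCounts(
            int(ev["mutations"]), int(ev["migrations_ok"]), int(ev["migrations_failed"])
        ),
        total_time=float(meta["total_time"]),
        config=cfg,
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one multi-replicate run: config, seeds, artifacts, timings."""

    config: dict
    seeds: list
    version: str
    outputs: list = field(default_factory=list)
    wall_times: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("manifest seeds must be unique")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": list(self.seeds),
                    "version": self.version,
                    "outputs": list(self.outputs),
                    "wall_times": self.wall_times,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=d["config"],
            seeds=d["seeds"],
            version=d["version"],
            outputs=d["outputs"],
            wall_times=d.get("wall_times", {}),
        )

    def validate(self, base_dir) -> None:
        """Check that every listed artifact exists under ``base_dir``."""
        base = Path(base_dir)
        missing = [p for p in self.outputs if not (base / p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest artifacts missing: {missing}")
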