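"""Per-clone geometry of completed sweeps: masses, extents, occupancy profiles.

A clone is the set of demes fixed for one mutational origin.  Distances are
always periodic (minimal image) and measured from the clone's originating
deme, which the engine records.  Key per-clone quantities:

* mass X (number of demes),
* mass-equivalent radius r_eq = (X / omega_d)**(1/d) -- the radius of the
  ball that would hold the clone's mass if it were compact,
* extent r_max -- in 1D half the largest pair separation on the ring
  (capped at L/2, the largest measurable extent under periodic boundaries);
  in 2D the eighth-root of the eighth central moment about the periodic
  centroid, a convention that emphasises the farthest satellites.

The occupancy profile rho(r) of a clone is the fraction of the lattice shell
at distance r from its origin occupied by the clone; profiles are binned in
the scaled coordinate r/r_eq, averaged over clones above a mass threshold
within each simulation and then across simulations.  For compact clones the
profile is supported in r/r_eq <= 2; long-range dispersal produces a
power-law tail rho ~ r**-(d+mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .engine import SweepResult
from .growth import omega

__all__ = [
    "Clone",
    "OccupancyProfile",
    "extract_clones",
    "clone_extent_1d",
    "clone_extent_2d",
    "occupancy_counts_1d",
    "occupancy_profile",
    "core_occupancy",
]


@dataclass
class Clone:
    """One allele's demes in a completed sweep, with derived geometry."""

    allele_id: int
    origin: tuple
    members: np.ndarray  # 1D: positions (X,); 2D: coords (X, 2)
    X: int
    r_eq: float
    r_max: float
    L: int
    dim: int


def clone_extent_1d(members, L: int) -> float:
    """Half the largest pair separation on a periodic ring, capped at L/2.

    Computed from the largest circular gap g between consecutive members:
    the farthest pair is separated by L - g along the occupied arc, so
    r_max = (L - g)/2.  A single deme has extent 0.
    """
    pos = np.asarray(members, dtype=np.int64).ravel()
    if pos.size == 0:
        raise ValueError("empty member set")
    if pos.size == 1:
        return 0.0
    p = np.sort(pos)
    gaps = np.diff(p)
    wrap = p[0] + L - p[-1]
    g = max(int(gaps.max()), int(wrap))
    return float(min((L - g) / 2.0, L / 2.0))


def clone_extent_2d(members, L: int) -> float:
    """Eighth-root of the mean eighth power of distances from the periodic
    centroid (circular mean per axis, minimal-image displacements)."""
    pts = np.asarray(members, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("2D members must have shape (n, 2)")
    if pts.shape[0] == 0:
        raise ValueError("empty member set")
    theta = 2.0 * np.pi * pts / L
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    centroid = (mean_angle / (2.0 * np.pi) * L) % L
    disp = (pts - centroid + L / 2.0) % L - L / 2.0
    d2 = (disp**2).sum(axis=1)
    return float(np.mean(d2**4) ** (1.0 / 8.0))


def extract_clones(result: SweepResult) -> list[Clone]:
    """Group the final lattice into one Clone per allele label.

    Raises a corruption error if an allele recorded in the origins log is
    absent from the grid (origin demes are never overwritten, so every label
    must survive to fixation).
    """
    cfg = result.config
    L, dim = cfg.L, cfg.dim
    flat = result.final_state.grid.ravel()
    n_alleles = result.n_alleles
    counts = np.bincount(flat, minlength=n_alleles + 1)
    if counts[0] != 0:
        raise ValueError("sweep incomplete: wildtype demes remain")
    missing = np.nonzero(counts[1 : n_alleles + 1] == 0)[0]
    if missing.size:
        raise ValueError(f"corrupt result: alleles {missing + 1} have no demes in the grid")
    order = np.argsort(flat, kind="stable")
    bounds = np.cumsum(counts)
    w = omega(dim)
    clones = []
    for aid in range(1, n_alleles + 1):
        idx = order[bounds[aid - 1] : bounds[aid]]
        X = int(counts[aid])
        origin = result.origin_coords(aid)
        if dim == 1:
            members = idx.astype(np.int64)
            r_max = clone_extent_1d(members, L)
        else:
            members = np.stack([idx // L, idx % L], axis=1).astype(np.int64)
            r_max = clone_extent_2d(members, L)
        r_eq = (X / w) ** (1.0 / dim)
        clones.append(
            Clone(
                allele_id=aid,
                origin=origin,
                members=members,
                X=X,
                r_eq=r_eq,
                r_max=r_max,
                L=L,
                dim=dim,
            )
        )
    return clones


def occupancy_counts_1d(clone: Clone):
    """Exact shell occupancy of a 1D clone at integer distances from its origin.

    Returns ``(r, rho, shell_size)`` for r = 1 .. L//2.  Shells hold the two
    demes origin +- r, except the antipodal shell r = L/2 on an even ring,
    which holds a single deme.  The identity
    sum_r rho(r) * shell_size(r) + 1 = X holds exactly for every clone.
    """
    if clone.dim != 1:
        raise ValueError("occupancy_counts_1d needs a 1D clone")
    L = clone.L
    o = clone.origin[0]
    fwd = (clone.members - o) % L
    dist = np.minimum(fwd, L - fwd)
    rmax = L // 2
    counts = np.bincount(dist, minlength=rmax + 1).astype(float)
    r = np.arange(1, rmax + 1)
    shell = np.full(rmax, 2.0)
    if L % 2 == 0:
        shell[-1] = 1.0
    rho = counts[1:] / shell
    return r, rho, shell


@lru_cache(maxsize=8)
def _shell_sizes_2d(L: int) -> np.ndarray:
    """Number of lattice sites at integer-rounded minimal-image distance r."""
    ax = np.arange(L)
    d1 = np.minimum(ax, L - ax).astype(float)
    dist = np.sqrt(d1[:, None] ** 2 + d1[None, :] ** 2)
    r_int = np.floor(dist + 0.5).astype(np.int64)
    return np.bincount(r_int.ravel())


@dataclass
class OccupancyProfile:
    """Ensemble-averaged occupancy versus scaled distance r/r_eq."""

    bin_edges: np.ndarray
    rho: np.ndarray  # NaN where no shell fell in a bin
    n_clones: np.ndarray  # clones contributing per bin (summed over sims)
    min_mass: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _clone_profile_binned(clone: Clone, edges: np.ndarray):
    """Per-clone mean occupancy in scaled-distance bins.

    numerator: clone members per bin; denominator: lattice demes in the
    shells whose scaled radius falls in the bin.
    """
    L = clone.L
    if clone.dim == 1:
        r, rho, shell = occupancy_counts_1d(clone)
        occupied = rho * shell
        sizes = shell
    else:
        o = clone.origin
        disp = (clone.members - np.asarray(o) + L / 2.0) % L - L / 2.0
        d = np.sqrt((disp**2).sum(axis=1))
        r_int = np.floor(d + 0.5).astype(np.int64)
        rmax = int(np.floor(np.sqrt(2.0) * (L / 2.0) + 0.5))
        occupied_full = np.bincount(r_int, minlength=rmax + 1).astype(float)
        sizes_full = _shell_sizes_2d(L).astype(float)
        n = min(len(occupied_full), len(sizes_full))
        r = np.arange(1, n)
        occupied = occupied_full[1:n]
        sizes = sizes_full[1:n]
    scaled = r / clone.r_eq
    which = np.digitize(scaled, edges) - 1
    nb = len(edges) - 1
    ok = (which >= 0) & (which < nb)
    num = np.bincount(which[ok], weights=occupied[ok], minlength=nb)
    den = np.bincount(which[ok], weights=sizes[ok], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = num / den
    prof[den == 0] = np.nan
    return prof


def occupancy_profile(
    clones,
    min_mass: int = 100,
    bin_width: float = 0.1,
    max_scaled: float = 50.0,
) -> OccupancyProfile:
    """Average occupancy profiles of clones with mass above ``min_mass``.

    ``clones`` is either a flat list (one simulation) or a list of per-
    simulation lists; profiles are averaged over clones within a simulation
    first, then across simulations.
    """
    if clones and isinstance(clones[0], Clone):
        sims = [clones]
    else:
        sims = list(clones)
    edges = np.arange(0.0, max_scaled + bin_width / 2, bin_width)
    nb = len(edges) - 1
    sim_means = []
    n_contrib = np.zeros(nb)
    for sim in sims:
        profs = [
            _clone_profile_binned(c, edges) for c in sim if c.X > min_mass
        ]
        if not profs:
            continue
        arr = np.vstack(profs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            sim_means.append(np.nanmean(arr, axis=0))
        n_contrib += np.sum(~np.isnan(arr), axis=0)
    if not sim_means:
        raise ValueError(f"no clone exceeds the mass threshold {min_mass}")
    stack = np.vstack(sim_means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.nanmean(stack, axis=0)
    return OccupancyProfile(bin_edges=edges, rho=rho, n_clones=n_contrib, min_mass=min_mass)


def core_occupancy(profile: OccupancyProfile, core_limit: float = 2.0) -> float:
    """Fraction of the integrated occupancy lying within r/r_eq <= ``core_limit``.

    For clones that remained compact and contiguous this is ~1 (their whole
    profile fits inside r/r_eq <= 2); haloes push weight beyond the limit.
    Trapezoidal integration on bin centers; empty bins contribute zero.
    """
    c = profile.bin_centers
    rho = np.nan_to_num(profile.rho, nan=0.0)
    total = np.trapezoid(rho, c)
    if total <= 0:
        raise ValueError("occupancy profile integrates to zero")
    inside = c <= core_limit
    num = np.trapezoid(rho[inside], c[inside])
    return float(num / total)
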