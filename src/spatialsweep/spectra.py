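"""Allele frequency spectra and global/local sampling statistics.

The allele frequency spectrum f(x) is defined so that f(x) dx is the
expected number of alleles with population frequency in (x, x + dx); its
normalization is the total-mass identity  integral x f(x) dx = 1.  Under the
self-similarity of sweep patterns, spectra at different mutation rates and
range sizes collapse when frequencies are scaled by X_ave / L^d and the
density by its square:

    f(x) = (L^d / X_ave)**2 * P(L^d x / X_ave),

with P the kernel-specific rescaled clone-size density.  The collapsed
spectra are summarized by a hard-cutoff power-law ansatz

    f(x) = (p + 2) / x_c**(p+2) * x**p   for x < x_c,  0 beyond,

with p in [-1, 1] (the panmictic and wavelike limits, respectively) and the
cutoff x_c located where the log-log curvature of the spectrum first drops
below -4.

Sampling statistics (with replacement): P_hard(j) = integral x^j f(x) dx is
the probability that a random sample of j individuals is monoallelic; the
panmictic reference is Ewens' monoallelic-sample probability
prod_{i<j} i/(theta+i).  Local protocols sample contiguous windows of linear
size L_s: the subrange homoallelicity P_hard,s(2) and the mean number of
distinct alleles per window n_c,s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencySpectrum",
    "AnsatzFit",
    "frequency_spectrum",
    "rescale_spectrum",
    "fit_ansatz",
    "p_hard_global",
    "p_hard_from_spectrum",
    "p_hard_scaled",
    "ewens_p_hard",
    "subrange_homoallelicity",
    "subrange_allele_count",
    "null_equal_clones",
]


@dataclass
class FrequencySpectrum:
    """Ensemble-averaged allele frequency spectrum on logarithmic bins."""

    bin_edges: np.ndarray  # length n_bins + 1, spanning [1/L^d, 1]
    density: np.ndarray  # f(x): mean count per unit frequency
    n_sims: int
    L: int
    dim: int

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])  # geometric centers

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def mass_integral(self) -> float:
        """integral x f(x) dx evaluated on the bins; ~1 up to binning error."""
        return float(np.sum(self.density * self.bin_widths * self.bin_centers))


def _masses_to_frequencies(mass_lists, L: int, dim: int):
    n_demes = L**dim
    freqs = []
    for m in mass_lists:
        m = np.asarray(m, dtype=float)
        if int(round(m.sum())) != n_demes:
            raise ValueError(
                f"clone masses sum to {m.sum():.0f}, expected L^d = {n_demes}; "
                "inconsistent L across simulations?"
            )
        freqs.append(m / n_demes)
    return freqs


def frequency_spectrum(mass_lists, L: int, dim: int = 1, n_bins: int = 50) -> FrequencySpectrum:
    """Estimate f(x) from per-simulation clone mass lists.

    Logarithmic bins span [1/L^d, 1] (1/L^d is a hard lower cutoff: no clone
    can be smaller than one deme; together with log-bin widths it produces
    the well-known uptick artifact in the lowest bin, which is reported
    as-is).  Histogram counts are divided by bin width and averaged across
    simulations.
    """
    freqs = _masses_to_frequencies(mass_lists, L, dim)
    n_demes = L**dim
    edges = np.logspace(np.log10(1.0 / n_demes), 0.0, n_bins + 1)
    edges[0] = 1.0 / n_demes / (1 + 1e-12)  # keep the x = 1/L^d clones inside
    counts = np.zeros(n_bins)
    for x in freqs:
        h, _ = np.histogram(x, bins=edges)
        counts += h
    density = counts / len(freqs) / np.diff(edges)
    return FrequencySpectrum(
        bin_edges=edges, density=density, n_sims=len(freqs), L=L, dim=dim
    )


def rescale_spectrum(spec: FrequencySpectrum, x_ave: float):
    """Collapse transform: returns (s, G) with s = L^d x / X_ave and
    G = (X_ave/L^d)**2 f(x).  ``x_ave`` is the mean clone mass X_ave in demes."""
    if not x_ave > 0:
        raise ValueError("X_ave must be positive")
    n_demes = spec.L**spec.dim
    scale = x_ave / n_demes
    s = spec.bin_centers / scale
    G = scale**2 * spec.density
    return s, G


@dataclass
class AnsatzFit:
    """Hard-cutoff power-law summary of a rescaled spectrum."""

    p: float
    x_c: float  # cutoff in scaled frequency s = L^d x / X_ave
    fit_window: tuple
    n_points: int
    cutoff_found: bool
    rms_log_residual: float


def fit_ansatz(
    s,
    G,
    curvature_threshold: float = -4.0,
    counts=None,
    min_count: float = 5.0,
    s_min: float | None = None,
) -> AnsatzFit:
    """Fit the (p, x_c) ansatz to a collapsed spectrum (s, G).

    x_c is the first scaled frequency at which the discrete second derivative
    of log G vs log s drops below ``curvature_threshold``; if no crossing is
    found the top of the support is used and flagged.  The exponent p is the least-squares log-log
    slope over the window between the 5th percentile of the (log) support and
    x_c / 3, which avoids both the lowest-bin artifact and the cutoff
    shoulder.  p is clipped to the theoretical range [-1, 1].

    ``counts`` (clones per bin over the whole ensemble, optional) serves two
    purposes: bins with fewer than ``min_count`` clones are dropped, and the
    Poisson uncertainty 1/sqrt(count) of each remaining bin is propagated
    through the curvature stencil so that only dips *significantly* below
    the threshold (by 3 sigma) count as the cutoff -- statistical wiggles in
    sparse bins do not.  ``s_min`` drops scaled frequencies below a floor;
    pass ``min_mass / X_ave`` (about 10 demes) to exclude the integer-mass
    comb artifact at the bottom of the spectrum.
    """
    s = np.asarray(s, dtype=float)
    G = np.asarray(G, dtype=float)
    ok = (s > 0) & (G > 0) & np.isfinite(G)
    cnt = None
    if counts is not None:
        cnt = np.asarray(counts, dtype=float)
        ok &= cnt >= min_count
    if s_min is not None:
        ok &= s >= s_min
    s, G = s[ok], G[ok]
    if cnt is not None:
        cnt = cnt[ok]
    if s.size < 10:
        raise ValueError("need at least 10 populated bins to fit the ansatz")
    z = np.log(s)
    y = np.log(G)
    # 3-point second difference on the (possibly uneven) log grid; tighter
    # stencil than repeated np.gradient, so the cutoff drop is not smeared
    h0 = z[1:-1] - z[:-2]
    h1 = z[2:] - z[1:-1]
    w_m = 2.0 / (h0 * (h0 + h1))
    w_c = 2.0 / (h0 * h1)
    w_p = 2.0 / (h1 * (h0 + h1))
    d2_mid = w_m * y[:-2] - w_c * y[1:-1] + w_p * y[2:]
    d2 = np.concatenate([[d2_mid[0]], d2_mid, [d2_mid[-1]]])
    if cnt is not None:
        var = 1.0 / cnt  # var of log of a Poisson-count bin estimate
        sig_mid = np.sqrt(w_m**2 * var[:-2] + w_c**2 * var[1:-1] + w_p**2 * var[2:])
        sigma = np.concatenate([[sig_mid[0]], sig_mid, [sig_mid[-1]]])
    else:
        sigma = np.zeros_like(d2)
    below = np.nonzero(d2 + 3.0 * sigma < curvature_threshold)[0]
    if below.size:
        i = below[0]
        if i < len(z) - 1:
            # curvature at bin i reflects the drop toward bin i+1; the cutoff
            # itself lies at or beyond bin i's upper edge
            x_c = float(np.exp(0.5 * (z[i] + z[i + 1])))
        else:
            x_c = float(s[i])
        found = True
    else:
        x_c = float(s[-1])
        found = False
    z_lo = z[0] + 0.05 * (z[-1] - z[0])
    z_hi = np.log(x_c / 3.0)
    win = (z >= z_lo) & (z <= z_hi)
    if win.sum() < 3:
        # degenerate window (cutoff very close to the lower support edge)
        win = z <= np.log(x_c)
    slope, icept = np.polyfit(z[win], y[win], 1)
    resid = y[win] - (slope * z[win] + icept)
    p = float(np.clip(slope, -1.0, 1.0))
    return AnsatzFit(
        p=p,
        x_c=x_c,
        fit_window=(float(np.exp(z_lo)), float(x_c / 3.0)),
        n_points=int(win.sum()),
        cutoff_found=found,
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
    )


def p_hard_global(mass_lists, L: int, dim: int = 1, j: int = 2) -> float:
    """Monoallelic-sample probability from clone lists: mean over simulations
    of sum_i x_i**j (sampling with replacement)."""
    if j < 2:
        raise ValueError("sample size j must be >= 2")
    freqs = _masses_to_frequencies(mass_lists, L, dim)
    return float(np.mean([np.sum(x**j) for x in freqs]))


def p_hard_from_spectrum(spec: FrequencySpectrum, j: int = 2) -> float:
    """integral x^j f(x) dx on the binned spectrum (cross-check of
    :func:`p_hard_global`; agreement is limited by binning resolution)."""
    if j < 2:
        raise ValueError("sample size j must be >= 2")
    return float(np.sum(spec.density * spec.bin_widths * spec.bin_centers**j))


def p_hard_scaled(p_hard: float, x_ave: float, L: int, dim: int = 1, j: int = 2) -> float:
    """Scale P_hard(j) by the equal-clone expectation (X_ave/L^d)**(j-1).

    An ensemble of identical clones of mass X_ave gives exactly 1; values
    above 1 quantify the excess weight of high-frequency clones.
    """
    return float(p_hard / (x_ave / L**dim) ** (j - 1))


def ewens_p_hard(theta: float, j: int) -> float:
    """Ewens monoallelic-sample probability prod_{i=1}^{j-1} i/(theta + i)
    for the panmictic (infinite-alleles) reference with scaled mutation rate
    theta."""
    if not theta >= 0:
        raise ValueError("theta must be non-negative")
    if j < 2:
        raise ValueError("sample size j must be >= 2")
    i = np.arange(1, j)
    return float(np.prod(i / (theta + i)))


def _window_starts(n_windows: int, L: int, rng) -> np.ndarray:
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return rng.integers(0, L, size=n_windows)


def _window_label_counts(grid: np.ndarray, start: int, L_s: int):
    L = grid.shape[0]
    idx = (np.arange(start, start + L_s)) % L
    return np.unique(grid[idx], return_counts=True)


def subrange_homoallelicity(lattice, L_s: int, n_windows: int = 100, rng=None) -> float:
    """Probability that two individuals drawn (with replacement) from a
    random contiguous subrange of linear size ``L_s`` share an allele:
    mean over windows of sum_a (n_a / L_s)**2.

    ``lattice`` is a 1D label array or a list of such arrays (ensemble).
    Windows are placed uniformly at random with periodic wrapping.
    """
    rng = np.random.default_rng(rng)
    grids = lattice if isinstance(lattice, (list, tuple)) else [lattice]
    vals = []
    for g in grids:
        g = np.asarray(g).ravel()
        L = g.shape[0]
        if not 1 <= L_s <= L:
            raise ValueError(f"L_s must be in [1, {L}]")
        for start in _window_starts(n_windows, L, rng):
            _, counts = _window_label_counts(g, int(start), L_s)
            vals.append(np.sum((counts / L_s) ** 2))
    return float(np.mean(vals))


def subrange_allele_count(lattice, L_s: int, n_windows: int = 100, rng=None) -> float:
    """Mean number of distinct alleles in a random contiguous subrange of
    size ``L_s`` (averaged over window placements and simulations)."""
    rng = np.random.default_rng(rng)
    grids = lattice if isinstance(lattice, (list, tuple)) else [lattice]
    vals = []
    for g in grids:
        g = np.asarray(g).ravel()
        L = g.shape[0]
        if not 1 <= L_s <= L:
            raise ValueError(f"L_s must be in [1, {L}]")
        for start in _window_starts(n_windows, L, rng):
            labels, _ = _window_label_counts(g, int(start), L_s)
            vals.append(len(labels))
    return float(np.mean(vals))


def null_equal_clones(x: float) -> float:
    """Homoallelicity of a window of size L_s = x * X_ave in a tessellation
    of equal contiguous clones:

        P_hard,s(2) = 1 - x/3             for x < 1,
                      1/x - 1/(3 x**2)    for x >= 1.

    Both branches give 2/3 at x = 1 (continuity).  The argument is
    x = L_s / X_ave (in 1D, X_ave = 2 <r_eq>).
    """
    if np.ndim(x):
        return np.vectorize(null_equal_clones)(x)
    if not x > 0:
        raise ValueError("x = L_s / X_ave must be positive")
    if x < 1.0:
        return 1.0 - x / 3.0
    return 1.0 / x - 1.0 / (3.0 * x**2)
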