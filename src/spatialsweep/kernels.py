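"""Power-law (fat-tailed) dispersal kernels on the integer lattice.

Dispersal distances follow the density J(r) = mu * r**-(1 + mu) on r >= 1,
normalized so that the integral over [1, inf) is one.  The exponent ``mu``
controls the heaviness of the tail: small ``mu`` produces frequent very long
jumps (approaching panmixia as mu -> 0), large ``mu`` recovers essentially
short-ranged, wavelike spread.  Directions are isotropic: a fair sign in one
dimension, a uniform angle in two.  Each real-valued jump component is rounded
to the nearest integer to land on a lattice deme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "R_CLAMP", "sample_jump_distance", "sample_jump_offset"]

# Clamp applied to sampled distances before integer rounding.  Distances this
# large exceed the resolution of float64 at unit lattice spacing; with periodic
# wrapping the clamp does not affect any feasible range size.
R_CLAMP = 1.0e15


@dataclass(frozen=True)
class KernelSpec:
    """Dispersal law J(r) = mu * r**-(1+mu) in ``dim`` dimensions.

    Parameters
    ----------
    mu : float
        Kernel exponent; must be positive for the kernel to be normalizable.
    dim : int
        Habitat dimension, 1 or 2.
    """

    mu: float
    dim: int = 1

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"kernel exponent mu must be positive, got {self.mu}")
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")

    def cdf(self, r):
        """Cumulative distribution of jump distances, P(R <= r) = 1 - r**-mu."""
        r = np.asarray(r, dtype=float)
        out = np.where(r < 1.0, 0.0, 1.0 - r ** (-self.mu))
        return out if out.ndim else float(out)

    def survival(self, r):
        """Tail probability P(R > r) = r**-mu for r >= 1."""
        r = np.asarray(r, dtype=float)
        out = np.where(r < 1.0, 1.0, r ** (-self.mu))
        return out if out.ndim else float(out)


def sample_jump_distance(kernel: KernelSpec, u):
    """Map uniform variates ``u`` in (0, 1] to jump distances r = u**(-1/mu).

    This is the inverse-CDF transform for the density mu * r**-(1+mu) on
    [1, inf): u = 1 maps to the lower support edge r = 1 and u -> 0+ produces
    arbitrarily long jumps.  Accepts scalars or arrays.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr > 1.0):
        raise ValueError("uniform variate u must lie in (0, 1]")
    r = u_arr ** (-1.0 / kernel.mu)
    r = np.minimum(r, R_CLAMP)
    return float(r) if r.ndim == 0 else r


def sample_jump_offset(kernel: KernelSpec, rng: np.random.Generator, size: int | None = None):
    """Draw integer jump vectors: distance from the kernel, isotropic direction.

    Returns an array of shape ``(dim,)`` for ``size=None``, else
    ``(size, dim)``.  Components are rounded half-up to the nearest integer;
    because r >= 1 the offset is never the zero vector in either dimension.
    """
    n = 1 if size is None else int(size)
    r = sample_jump_distance(kernel, 1.0 - rng.random(n))  # 1 - U in (0, 1]
    if kernel.dim == 1:
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        vec = (sign * r)[:, None]
    else:
        theta = rng.random(n) * 2.0 * np.pi
        vec = r[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    off = np.floor(vec + 0.5).astype(np.int64)  # round-half-up, sign-symmetric draw
    return off[0] if size is None else off
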