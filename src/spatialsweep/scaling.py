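"""Characteristic scales of spatial soft sweeps from mutation-expansion balance.

While a typical clone's core grows as l(t), new mutations arise in the swept
space-time volume at rate u_tilde per deme per unit time.  The characteristic
time t* balances the two: exactly one new mutation is expected inside the
space-time region swept by a growing core,

    u_tilde * t* * omega_d * l(t*)**d = 1.

Derived lengths:

    chi  = l(t*)      characteristic core extent (sets the mean clone mass,
                      X_ave ~ omega_d * chi**d up to an O(1) factor),
    psi  = l(2 t*)    extent of established satellite clusters of a typical
                      clone (key jumps at time t seed satellites out to
                      ~ l(2t)),
    zeta = u_tilde**(-1/mu)   outer limit of rare jumps: the distance beyond
                      which the ~1/u_tilde jumps made during t* send less
                      than one migrant.

A ``GrowthLaw`` wraps either the tabulated ensemble l(t) (monotone log-log
interpolation; the canonical choice) or a closed asymptotic form with
prefactors A (length) and B (time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.special import lambertw

from .growth import (
    EllCurve,
    GrowthLawFit,
    b_mu_coefficient,
    eta_exponent,
    growth_regime,
    omega,
)

__all__ = [
    "OutOfDomainError",
    "GrowthLaw",
    "ScaleSet",
    "solve_t_star",
    "characteristic_scales",
    "chi_asymptotic",
    "halo_core_ratio",
    "expected_allele_count",
]


class OutOfDomainError(ValueError):
    """Requested point lies outside the domain of a tabulated growth law."""


class GrowthLaw:
    """Strictly increasing core-growth function l(t) with a well-defined inverse."""

    def __init__(
        self,
        ell_fn: Callable[[float], float],
        inv_fn: Callable[[float], float],
        t_domain: tuple[float, float],
        mu: float | None,
        dim: int,
        kind: str,
    ):
        self._ell = ell_fn
        self._inv = inv_fn
        self.t_domain = t_domain
        self.mu = mu
        self.dim = dim
        self.kind = kind

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_table(cls, curve: EllCurve, mu: float | None = None) -> "GrowthLaw":
        """Monotone interpolant (PCHIP in log-log) of a tabulated EllCurve.

        Noise is removed with a running maximum; duplicate values are dropped
        so the interpolant is strictly increasing and invertible.
        """
        mask = (curve.times > 0) & (curve.ell > 0)
        t = curve.times[mask]
        ell = np.maximum.accumulate(curve.ell[mask])
        keep = np.concatenate([[True], np.diff(ell) > 0])
        t, ell = t[keep], ell[keep]
        if t.size < 2:
            raise ValueError("tabulated curve needs >= 2 strictly increasing points")
        lt, le = np.log(t), np.log(ell)
        fwd = PchipInterpolator(lt, le, extrapolate=False)
        bwd = PchipInterpolator(le, lt, extrapolate=False)
        dom = (float(t[0]), float(t[-1]))
        rng = (float(ell[0]), float(ell[-1]))

        def ell_fn(x: float) -> float:
            if not dom[0] <= x <= dom[1]:
                raise OutOfDomainError(
                    f"t={x:.4g} outside tabulated domain {dom}; simulate longer"
                )
            return float(np.exp(fwd(np.log(x))))

        def inv_fn(l: float) -> float:
            if not rng[0] <= l <= rng[1]:
                raise OutOfDomainError(
                    f"ell={l:.4g} outside tabulated range {rng}; simulate longer"
                )
            return float(np.exp(bwd(np.log(l))))

        return cls(ell_fn, inv_fn, dom, mu if mu is not None else curve.mu, curve.dim, "tabulated")

    @classmethod
    def from_asymptotic(
        cls,
        mu: float,
        dim: int,
        A: float = 1.0,
        B: float = 1.0,
        c: float | None = None,
        eta: float | None = None,
        B_mu: float | None = None,
    ) -> "GrowthLaw":
        """Closed asymptotic form l(t) = A * g(t/B) for the regime of ``mu``."""
        regime = growth_regime(mu, dim)
        if regime == "linear":

            def ell_fn(t):
                return A * t / B

            def inv_fn(l):
                return B * l / A

            dom = (0.0, np.inf)
        elif regime == "power":
            e = 1.0 / (mu - dim)

            def ell_fn(t):
                return A * (t / B) ** e

            def inv_fn(l):
                return B * (l / A) ** (1.0 / e)

            dom = (0.0, np.inf)
        elif regime == "marginal":
            if c is None:
                raise ValueError("the marginal form exp(c log^2 t) needs the coefficient c")

            def ell_fn(t):
                if t < B:
                    raise OutOfDomainError("marginal form is increasing only for t >= B")
                return A * np.exp(c * np.log(t / B) ** 2)

            def inv_fn(l):
                if l < A:
                    raise OutOfDomainError("marginal inverse needs ell >= A")
                return B * np.exp(np.sqrt(np.log(l / A) / c))

            dom = (B, np.inf)
        elif regime == "marginal_upper":
            if dim != 1:
                raise ValueError("t*log(t) marginal form implemented in 1D only")

            def ell_fn(t):
                s = t / B
                if s <= 1.0:
                    raise OutOfDomainError("t log t form is positive only for t > B")
                return A * s * np.log(s)

            def inv_fn(l):
                v = l / A
                if v <= 0:
                    raise OutOfDomainError("ell must be positive")
                # solve s*log(s) = v  =>  log(s) = W(v)
                return B * v / float(np.real(lambertw(v)))

            dom = (B, np.inf)
        else:  # stretched
            eta_v = eta if eta is not None else eta_exponent(mu, dim)
            bmu_v = B_mu if B_mu is not None else b_mu_coefficient(mu, dim)

            def ell_fn(t):
                return A * np.exp(bmu_v * (t / B) ** eta_v)

            def inv_fn(l):
                if l <= A:
                    raise OutOfDomainError("stretched inverse needs ell > A")
                return B * (np.log(l / A) / bmu_v) ** (1.0 / eta_v)

            dom = (0.0, np.inf)
        law = cls(ell_fn, inv_fn, dom, mu, dim, f"asymptotic:{regime}")
        law.A, law.B, law.c = A, B, c
        return law

    @classmethod
    def from_fit(cls, fit: GrowthLawFit) -> "GrowthLaw":
        return cls.from_asymptotic(
            fit.mu, fit.dim, A=fit.A, B=fit.B, c=fit.c, eta=fit.eta, B_mu=fit.B_mu
        )

    # -- evaluation ---------------------------------------------------------

    def ell(self, t: float) -> float:
        return self._ell(float(t))

    def ell_inverse(self, l: float) -> float:
        return self._inv(float(l))


@dataclass(frozen=True)
class ScaleSet:
    """Characteristic scales at one (kernel, u_tilde) point."""

    t_star: float
    chi: float
    psi: float
    zeta: float
    u_tilde: float
    dim: int
    omega_d: float

    def __post_init__(self):
        if not (self.t_star > 0 and self.chi > 0 and self.psi > 0 and self.zeta > 0):
            raise ValueError("characteristic scales must be positive")
        if self.psi < self.chi * (1 - 1e-12):
            raise ValueError("psi = l(2 t*) cannot be smaller than chi = l(t*)")


def solve_t_star(law: GrowthLaw, u_tilde: float, dim: int | None = None) -> float:
    """Root of u_tilde * t * omega_d * l(t)**d = 1 (unique: the LHS is increasing).

    Brackets are auto-expanded inside the law's domain, then the root is
    polished with Brent's method to ~1e-12 relative tolerance.  A root
    outside a tabulated domain raises :class:`OutOfDomainError` -- the caller
    should supply a longer simulation rather than extrapolate silently.
    """
    if not u_tilde > 0:
        raise ValueError("u_tilde must be positive")
    d = dim if dim is not None else law.dim
    w = omega(d)

    def excess(t: float) -> float:
        return np.log(u_tilde * t * w * law.ell(t) ** d)

    lo, hi = law.t_domain
    lo = max(lo, 1e-300)
    if np.isinf(hi):
        hi = max(2.0 * lo, 1.0)
        for _ in range(2000):
            if excess(hi) > 0:
                break
            hi *= 2.0
        else:
            raise RuntimeError("failed to bracket t*")
        lo_b = hi / 2.0
        while excess(lo_b) > 0 and lo_b > 1e-280:
            lo_b /= 2.0
        lo = lo_b
    else:
        if excess(hi) < 0:
            raise OutOfDomainError(
                "t* lies beyond the tabulated l(t); extend the growth ensemble"
            )
        if excess(lo) > 0:
            raise OutOfDomainError("t* lies below the tabulated l(t); refine early times")
    return float(brentq(excess, lo, hi, rtol=1e-12, maxiter=300))


def characteristic_scales(law: GrowthLaw, u_tilde: float, dim: int | None = None) -> ScaleSet:
    """Compute (t*, chi, psi, zeta) for one growth law and mutation rate."""
    d = dim if dim is not None else law.dim
    t_star = solve_t_star(law, u_tilde, d)
    chi = law.ell(t_star)
    psi = law.ell(2.0 * t_star)
    if law.mu is None:
        raise ValueError("law carries no kernel exponent; zeta = u_tilde**(-1/mu) undefined")
    zeta = u_tilde ** (-1.0 / law.mu)
    return ScaleSet(
        t_star=t_star, chi=chi, psi=psi, zeta=zeta, u_tilde=u_tilde, dim=d, omega_d=omega(d)
    )


def chi_asymptotic(mu: float, dim: int, u_tilde: float, c: float | None = None) -> float:
    """Closed-form characteristic core extent chi_as per growth regime.

    Obtained by solving the balance condition analytically with the
    asymptotic l(t) (unit prefactors):

    * d < mu < d+1 :  chi = (u_tilde * omega_d)**(-1/mu)
    * mu > d+1     :  chi = (u_tilde * omega_d)**(-1/(d+1))
    * mu < d       :  chi = [xi / W(xi)]**(1/(eta*d)),
                      xi = eta * d * B_mu * (u_tilde*omega_d)**(-eta)
    * mu = d       :  log t* solves  d*c*y^2 + y + log(u_tilde*omega_d) = 0,
                      chi = exp(c * y**2)   (requires the marginal coefficient c)
    * mu = d+1, 1D :  chi = (1/2) * sqrt(W(1/u_tilde) / u_tilde)

    Each expression is the exact root of the balance equation for the pure
    asymptotic form, and is cross-validated against the numerical solver in
    the test suite.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not u_tilde > 0:
        raise ValueError("u_tilde must be positive")
    w = omega(dim)
    regime = growth_regime(mu, dim)
    if regime == "power":
        return float((u_tilde * w) ** (-1.0 / mu))
    if regime == "linear":
        return float((u_tilde * w) ** (-1.0 / (dim + 1)))
    if regime == "stretched":
        eta = eta_exponent(mu, dim)
        bmu = b_mu_coefficient(mu, dim)
        xi = eta * dim * bmu * (u_tilde * w) ** (-eta)
        W = float(np.real(lambertw(xi)))
        return float((xi / W) ** (1.0 / (eta * dim)))
    if regime == "marginal":
        if c is None:
            raise ValueError("chi at mu = d needs the marginal coefficient c")
        q = np.log(u_tilde * w)
        if q >= 0:
            raise ValueError("marginal chi requires u_tilde * omega_d < 1")
        y = (-1.0 + np.sqrt(1.0 - 4.0 * dim * c * q)) / (2.0 * dim * c)
        return float(np.exp(c * y**2))
    # mu = d + 1
    if dim != 1:
        raise ValueError("the mu = d+1 closed form is implemented in 1D only")
    W = float(np.real(lambertw(1.0 / u_tilde)))
    return float(0.5 * np.sqrt(W / u_tilde))


def halo_core_ratio(law: GrowthLaw, core_extent: float) -> float:
    """Expected halo extent l' = l(2 * l^-1(core_extent)) of a clone with the
    given core size: satellites merging with the core at time t stem from key
    jumps near t/2 that spanned ~ l(t), so a core grown for time tau has
    seeded significant satellites out to ~ l(2*tau)."""
    tau = law.ell_inverse(core_extent)
    return law.ell(2.0 * tau)


def expected_allele_count(L: int, dim: int, scales: ScaleSet) -> float:
    """Expected number of mutational origins in the range: L^d / (omega_d chi^d)."""
    return float(L**dim / (scales.omega_d * scales.chi**dim))
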