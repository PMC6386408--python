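"""Shared simulation ensembles (session-scoped: sweeps are the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

from spatialsweep import (
    KernelSpec,
    SweepConfig,
    estimate_ell,
    run_solitary_ensemble,
    run_sweep_ensemble,
)


@pytest.fixture(scope="session")
def sweep_ens():
    """Memoized factory for 1D sweep ensembles keyed by parameters."""
    cache: dict = {}

    def get(mu: float, u_tilde: float, L: int, n_reps: int, seed: int):
        key = (mu, u_tilde, L, n_reps, seed)
        if key not in cache:
            cfg = SweepConfig(L=L, u_tilde=u_tilde, kernel=KernelSpec(mu=mu, dim=1), seed=seed)
            cache[key] = run_sweep_ensemble(cfg, n_reps)
        return cache[key]

    return get


# the headline study conditions (1D, rescaled mutation rate 1e-3, L=1e5)
@pytest.fixture(scope="session")
def ens_mu04(sweep_ens):
    return sweep_ens(0.4, 1e-3, 100_000, 20, 21)


@pytest.fixture(scope="session")
def ens_mu10(sweep_ens):
    return sweep_ens(1.0, 1e-3, 100_000, 20, 11)


@pytest.fixture(scope="session")
def ens_mu16(sweep_ens):
    return sweep_ens(1.6, 1e-3, 100_000, 20, 22)


@pytest.fixture(scope="session")
def ens_mu05(sweep_ens):
    return sweep_ens(0.5, 1e-3, 100_000, 20, 23)


@pytest.fixture(scope="session")
def ens_mu10_lower_rate(sweep_ens):
    return sweep_ens(1.0, 1e-4, 100_000, 20, 12)


# low-mutation-rate points
@pytest.fixture(scope="session")
def ens_mu16_u6(sweep_ens):
    return sweep_ens(1.6, 1e-6, 100_000, 20, 31)


@pytest.fixture(scope="session")
def ens_mu40_u6(sweep_ens):
    return sweep_ens(4.0, 1e-6, 30_000, 12, 32)


@pytest.fixture(scope="session")
def ens_mu40_u5(sweep_ens):
    # wavelike kernel with enough clones per sweep for spectrum shape work
    return sweep_ens(4.0, 1e-5, 30_000, 20, 44)


@pytest.fixture(scope="session")
def ens_fig_alleles(sweep_ens):
    # ten-allele condition: L=16384, mu=2.5, u_tilde=7e-7
    return sweep_ens(2.5, 7e-7, 16384, 100, 55)


@pytest.fixture(scope="session")
def ens_mu30_u4(sweep_ens):
    return sweep_ens(3.0, 1e-4, 100_000, 12, 33)


@pytest.fixture(scope="session")
def ens_trio(sweep_ens):
    """mu in {3, 1.5, 0.8} at fixed u_tilde = 1e-3 (compactness ordering)."""
    return {mu: sweep_ens(mu, 1e-3, 30_000, 20, 202) for mu in (3.0, 1.5, 0.8)}


@pytest.fixture(scope="session")
def ell_mu40_table():
    """Tabulated l(t) for the wavelike kernel mu=4 (1D)."""
    traces = run_solitary_ensemble(
        20_000, 1, KernelSpec(4.0, 1), {"mass_max": 4000}, n_reps=10, seed=13
    )
    t_hi = min(tr.t_end for tr in traces) * 0.999
    grid = np.logspace(np.log10(0.5), np.log10(t_hi), 200)
    return estimate_ell(traces, grid)
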