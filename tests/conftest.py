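"""Shared fixtures: small grids and simulated data sets.

Heavy simulations (the barrier-recovery MCMC run) are session-scoped so
that several tests can interrogate one chain.
"""

from __future__ import annotations

import numpy as np
import pytest

import migscape as ms


@pytest.fixture(scope="session")
def small_grid() -> ms.DemeGraph:
    """14-deme planar triangular grid (400x180 km, 100 km spacing)."""
    return ms.build_grid((0, 0, 400, 180), 100.0, "planar")


@pytest.fixture(scope="session")
def barrier_grid() -> ms.DemeGraph:
    """10x5-row planar grid (48 demes) used for recovery experiments."""
    return ms.build_grid((0, 0, 900, 370), 100.0, "planar")


@pytest.fixture(scope="session")
def barrier_field(barrier_grid) -> ms.TrueField:
    """Depth -1 vertical barrier strip through the middle of the grid."""
    strip = ms.RateStrip(400, 500, -10, 380, depth=-1.0, name="wall")
    return ms.make_rate_field(barrier_grid, [strip])


@pytest.fixture(scope="session")
def barrier_dataset(barrier_grid, barrier_field):
    """WF genotypes (192 individuals, 5000 SNPs), dissimilarities and
    deme assignment for the planted-barrier world."""
    cfg = ms.SimConfig(seed=11)
    geno = ms.simulate_wf_genotypes(barrier_field, cfg)
    D = ms.observed_dissimilarity(geno)
    asn = ms.assign_samples(geno.samples[["lon", "lat"]].to_numpy(), barrier_grid)
    return {"geno": geno, "D": D, "assignment": asn, "cfg": cfg}


@pytest.fixture(scope="session")
def barrier_posterior(barrier_grid, barrier_dataset) -> ms.PosteriorDraws:
    """100k-iteration chain on the planted-barrier data (the recovery run)."""
    mc = ms.McmcConfig(n_iter=100_000, burn_in=20_000, thin=200,
                       n_pilot=4, pilot_iter=5_000, seed=5)
    return ms.run_chain(barrier_dataset["D"], barrier_grid,
                        barrier_dataset["assignment"], mc,
                        p=barrier_dataset["cfg"].p_snps)


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> ms.DemeGraph:
    """Random connected weighted-graph scaffold for resistance oracles."""
    n = int(rng.integers(4, n_max + 1))
    coords = rng.uniform(0, 100, size=(n, 2))
    # random spanning tree + extra edges guarantees connectivity
    perm = rng.permutation(n)
    edges = {tuple(sorted((perm[i], perm[rng.integers(i)]))) for i in range(1, n)}
    n_extra = int(rng.integers(0, 2 * n))
    for _ in range(n_extra):
        u, v = rng.integers(n, size=2)
        if u != v:
            edges.add(tuple(sorted((int(u), int(v)))))
    return ms.DemeGraph(coords, np.array(sorted(edges)), 10.0)
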