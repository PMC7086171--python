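"""Synthetic stepping-stone worlds: planted rate fields, Wright-Fisher
forward simulation of genotypes, and model-exact dissimilarity draws.

The Wright-Fisher simulator is deliberately simple: per locus, deme allele
frequencies mix deterministically along grid edges (per-edge rate
proportional to the geometric mean of the endpoint migration rates), then
drift by binomial resampling of 2N chromosomes.  There is no mutation;
frequencies start at Uniform(0.1, 0.9) so that loci are exchangeable
replicates of the same demography.  Genotypes are Binomial(2, f_deme)
draws, i.e. Hardy-Weinberg sampling within demes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import wishart

from .genotypes import GenotypeMatrix
from .grids import DemeGraph
from .model import contrast_backproject, contrast_project


@dataclasses.dataclass
class RateStrip:
    """Axis-aligned rectangular strip of perturbed migration rate.

    ``depth`` is the log10 offset applied inside the strip: negative for a
    barrier, positive for a corridor.  Bounds are in the graph's coordinate
    units and inclusive.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    depth: float
    name: str = ""

    def contains(self, coords: np.ndarray) -> np.ndarray:
        x, y = coords[:, 0], coords[:, 1]
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    @property
    def label(self) -> str:
        return "barrier" if self.depth < 0 else "corridor"


@dataclasses.dataclass
class TrueField:
    """Ground-truth rate surfaces on a deme graph, with annotations."""

    graph: DemeGraph
    log10_m: np.ndarray
    log10_q: np.ndarray
    annotations: dict[str, np.ndarray]  # label -> vertex indices

    def __post_init__(self) -> None:
        self.log10_m = np.asarray(self.log10_m, dtype=float)
        self.log10_q = np.asarray(self.log10_q, dtype=float)
        if not np.all(np.isfinite(self.log10_m)):
            raise ValueError("log10_m must be finite everywhere")
        labeled = np.concatenate([v for v in self.annotations.values()]) if self.annotations else np.array([])
        if len(labeled) != len(np.unique(labeled)):
            raise ValueError("annotation labels must be disjoint")

    def vertices_with_label(self, kind: str) -> np.ndarray:
        """All vertex indices whose annotation label starts with ``kind``."""
        hits = [v for k, v in self.annotations.items() if k.startswith(kind)]
        return np.sort(np.concatenate(hits)) if hits else np.array([], dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "log10_m": self.log10_m.tolist(),
            "log10_q": self.log10_q.tolist(),
            "annotations": {k: np.asarray(v).tolist() for k, v in self.annotations.items()},
        }))


@dataclasses.dataclass
class SimConfig:
    """Wright-Fisher simulation settings.

    ``deme_size`` is diploid individuals per deme (2N chromosomes drift
    each generation); ``base_m`` is the per-edge migration fraction at
    log10 rate 0.  Defaults give moderate equilibrium differentiation on a
    grid of ~50 demes (neighbour FST of a few percent), which is the
    regime the surface model is meant to resolve.
    """

    deme_size: int = 100
    n_generations: int = 200
    p_snps: int = 5000
    n_sampled_per_deme: int = 4
    base_m: float = 0.05
    outflow_cap: float = 0.95
    jitter_frac: float = 0.01  # coordinate jitter sd, fraction of grid spacing
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("deme_size", "n_generations", "p_snps", "n_sampled_per_deme"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")


def make_rate_field(graph: DemeGraph, strips: Sequence[RateStrip] = (),
                    background_m: float = 0.0, background_q: float = 0.0) -> TrueField:
    """Plant barrier/corridor strips on a background rate surface.

    Every vertex inside a strip gets ``background_m + depth``; strips must
    not overlap (annotations partition a subset of vertices).
    """
    log10_m = np.full(graph.n_vertices, background_m, dtype=float)
    log10_q = np.full(graph.n_vertices, background_q, dtype=float)
    annotations: dict[str, np.ndarray] = {}
    claimed = np.zeros(graph.n_vertices, dtype=bool)
    for i, strip in enumerate(strips):
        if strip.depth == 0:
            raise ValueError("strip depth must be non-zero")
        inside = strip.contains(graph.coords)
        if not inside.any():
            raise ValueError(f"strip {strip.name or i} does not intersect the grid")
        if (inside & claimed).any():
            raise ValueError(f"strip {strip.name or i} overlaps another strip")
        claimed |= inside
        log10_m[inside] = background_m + strip.depth
        key = f"{strip.label}:{strip.name or i}"
        annotations[key] = np.flatnonzero(inside)
    background = np.flatnonzero(~claimed)
    if background.size:
        annotations["background:"] = background
    return TrueField(graph, log10_m, log10_q, annotations)


def migration_matrix(field: TrueField, base_m: float, outflow_cap: float) -> np.ndarray:
    """Row-stochastic per-generation mixing matrix from the rate field.

    Edge (u, v) carries ``base_m * 10 ** ((lm_u + lm_v) / 2)`` in each
    direction; the diagonal keeps the rest.  Total per-vertex outflow must
    stay below ``outflow_cap``.
    """
    g = field.graph
    n = g.n_vertices
    A = np.zeros((n, n))
    u, v = g.edges.T
    rate = base_m * 10.0 ** ((field.log10_m[u] + field.log10_m[v]) / 2.0)
    A[u, v] = rate
    A[v, u] = rate
    outflow = A.sum(axis=1)
    if np.any(outflow > outflow_cap):
        worst = int(outflow.argmax())
        raise ValueError(
            f"total migration outflow {outflow[worst]:.3f} at vertex {worst} exceeds "
            f"cap {outflow_cap}; rescale base_m or the rate field"
        )
    np.fill_diagonal(A, 1.0 - outflow)
    return A


def simulate_wf_genotypes(field: TrueField, cfg: SimConfig) -> GenotypeMatrix:
    """Forward Wright-Fisher simulation on the deme graph.

    Migration acts before drift each generation: frequencies mix
    deterministically through the row-stochastic migration matrix, then
    each deme redraws Binomial(2N, f) / 2N.  Returns a GenotypeMatrix whose
    sample table carries jittered deme coordinates and a per-deme
    population label ``deme<i>``.
    """
    g = field.graph
    if not g.is_connected():
        raise ValueError("deme graph must be connected")
    rng = np.random.default_rng(cfg.seed)
    A = migration_matrix(field, cfg.base_m, cfg.outflow_cap)
    two_n = 2 * cfg.deme_size
    f = rng.uniform(0.1, 0.9, size=(g.n_vertices, cfg.p_snps))
    for _ in range(cfg.n_generations):
        f = np.clip(A @ f, 0.0, 1.0)  # clip float rounding outside [0, 1]
        f = rng.binomial(two_n, f) / two_n
    # sample diploid individuals per deme under Hardy-Weinberg
    n_per = cfg.n_sampled_per_deme
    deme_idx = np.repeat(np.arange(g.n_vertices), n_per)
    calls = rng.binomial(2, f[deme_idx]).astype(np.int8)
    jitter_sd = cfg.jitter_frac * g.spacing_km
    coords = g.coords[deme_idx] + rng.normal(0.0, jitter_sd, size=(len(deme_idx), 2))
    samples = pd.DataFrame({
        "sample_id": [f"d{d}_i{i}" for d, i in zip(deme_idx, np.tile(np.arange(n_per), g.n_vertices))],
        "lon": coords[:, 0],
        "lat": coords[:, 1],
        "pop": [f"deme{d}" for d in deme_idx],
        "deme": deme_idx,
    })
    snps = pd.DataFrame({
        "chrom": np.repeat("1", cfg.p_snps),
        "snp_id": [f"snp{j}" for j in range(cfg.p_snps)],
        "cm": 0.0,
        "pos": np.arange(1, cfg.p_snps + 1) * 1000,
        "a1": "A",
        "a2": "G",
    })
    return GenotypeMatrix(calls, snps, samples)


def deme_frequencies(field: TrueField, cfg: SimConfig) -> np.ndarray:
    """Run the frequency process only (no genotype sampling); for oracles."""
    g = field.graph
    rng = np.random.default_rng(cfg.seed)
    A = migration_matrix(field, cfg.base_m, cfg.outflow_cap)
    two_n = 2 * cfg.deme_size
    f = rng.uniform(0.1, 0.9, size=(g.n_vertices, cfg.p_snps))
    for _ in range(cfg.n_generations):
        f = np.clip(A @ f, 0.0, 1.0)
        f = rng.binomial(two_n, f) / two_n
    return f


def simulate_model_exact(delta: np.ndarray, sigma2: float, p: int,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw a dissimilarity matrix from the fitted model's own likelihood.

    ``delta`` is the individual-level expected dissimilarity (symmetric,
    zero diagonal).  A scatter matrix S is drawn from a Wishart with p
    degrees of freedom and mean ``p * sigma2 * M`` where
    ``M = -1/2 C delta C^T``; S / p is then back-transformed to the unique
    zero-diagonal symmetric D with ``-1/2 C D C^T = S / p``.  Elementwise,
    ``E[D] = sigma2 * delta``.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ValueError("delta must be square")
    if not np.allclose(np.diag(delta), 0.0):
        raise ValueError("delta must have a zero diagonal (individual level)")
    M = -0.5 * contrast_project(delta)
    # positive-definiteness check via Cholesky
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise ValueError("contrast-projected delta is not positive definite") from None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = wishart.rvs(df=p, scale=sigma2 * M, random_state=rng)
    return contrast_backproject(S / p)


def write_truth(field: TrueField, cfg: SimConfig, path: str | Path) -> None:
    """Serialize the ground truth (field + config) for recovery scoring."""
    Path(path).write_text(json.dumps({
        "log10_m": field.log10_m.tolist(),
        "log10_q": field.log10_q.tolist(),
        "annotations": {k: np.asarray(v).tolist() for k, v in field.annotations.items()},
        "config": dataclasses.asdict(cfg),
    }))
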