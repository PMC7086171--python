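"""Observed dissimilarities, PCA, fit evaluation, FST, and Mantel tests.

These are the summaries used to feed the surface model (observed genetic
dissimilarity), to compare its fit against a PCA-based alternative, and to
relate inferred surfaces to stepping-stone theory and language boundaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grids import haversine_km


def observed_dissimilarity(g: GenotypeMatrix) -> np.ndarray:
    """Mean squared genotype difference over pairwise-complete loci.

    ``D[i, j]`` is the average of ``(g_il - g_jl)**2`` over loci typed in
    both i and j (allele-count units, so a 0 vs 2 homozygote difference
    contributes 4).  Raises if any pair shares no typed locus.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    X = g.calls.astype(float)
    obs = g.calls != -1
    X[~obs] = 0.0
    O = obs.astype(float)
    # sum over shared loci of (x_i - x_j)^2, expanded into masked products
    X2 = X * X
    sq_i = X2 @ O.T        # sum_l x_il^2 [l observed in j]
    cross = X @ X.T        # sum_l x_il x_jl (zeros where missing)
    shared = O @ O.T
    if np.any(shared[~np.eye(len(shared), dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(len(shared), dtype=bool))[0]
        a, b = g.samples["sample_id"].iloc[i], g.samples["sample_id"].iloc[j]
        raise ValueError(f"samples {a!r} and {b!r} share no typed locus")
    D = (sq_i + sq_i.T - 2 * cross) / shared
    np.fill_diagonal(D, 0.0)
    return D


@dataclasses.dataclass
class PcaResult:
    scores: np.ndarray       # (n, k)
    loadings: np.ndarray     # (p, k)
    eigenvalues: np.ndarray  # (k,)


def pca_decompose(g: GenotypeMatrix, k: int, scale: bool = False) -> PcaResult:
    """Genotype PCA: per-SNP mean imputation and centering, then a
    truncated eigendecomposition of the sample covariance.

    No per-SNP variance scaling by default (``scale=True`` divides by the
    per-SNP standard deviation).  Sign convention: the largest-magnitude
    loading on each PC is positive, making the decomposition deterministic.
    """
    n, p = g.calls.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds rank bound min(n-1, p)")
    X = g.calls.astype(float)
    miss = g.calls == -1
    if miss.all(axis=0).any():
        raise ValueError("SNP with all calls missing")
    X[miss] = np.nan
    mean = np.nanmean(X, axis=0)
    X = np.where(miss, mean[None, :], X) - mean[None, :]
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    # n x n trick: eigendecompose X X^T
    G = X @ X.T
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    U = U[:, order]
    sv = np.sqrt(w)
    scores = U * sv[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = np.where(sv > 0, (X.T @ U) / sv, 0.0)
    # deterministic sign: largest-|loading| entry positive per PC
    for j in range(k):
        i = np.abs(loadings[:, j]).argmax()
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    eigenvalues = w / (n - 1)
    return PcaResult(scores, loadings, eigenvalues)


def expected_distance_from_pcs(scores: np.ndarray, pops: np.ndarray,
                               k: int) -> tuple[np.ndarray, np.ndarray]:
    """Squared Euclidean distance between population medians in PC space.

    Per population, the coordinatewise median of its individuals' first k
    scores; typical choices are k in {2, 10, 100}.  Returns (matrix,
    population labels in sorted order).
    """
    scores = np.asarray(scores)
    if k > scores.shape[1]:
        raise ValueError(f"k={k} PCs not available in scores")
    pops = np.asarray(pops)
    labels = np.array(sorted(set(pops.tolist())))
    medians = []
    for lab in labels:
        members = scores[pops == lab, :k]
        if len(members) == 0:
            raise ValueError(f"population {lab!r} has no individuals")
        medians.append(np.median(members, axis=0))
    med = np.array(medians)
    diff = med[:, None, :] - med[None, :, :]
    return (diff ** 2).sum(axis=2), labels


def population_mean_matrix(D: np.ndarray, pops: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average an individual-level matrix into population blocks.

    Within-population entries average over distinct pairs only.
    """
    pops = np.asarray(pops)
    labels = np.array(sorted(set(pops.tolist())))
    k = len(labels)
    out = np.zeros((k, k))
    idx = [np.flatnonzero(pops == lab) for lab in labels]
    for a in range(k):
        for b in range(a, k):
            block = D[np.ix_(idx[a], idx[b])]
            if a == b:
                iu = np.triu_indices(len(idx[a]), k=1)
                out[a, a] = block[iu].mean() if iu[0].size else 0.0
            else:
                out[a, b] = out[b, a] = block.mean()
    return out, labels


def expected_distance_from_posterior(draws, assignment) -> tuple[np.ndarray, np.ndarray]:
    """Population-level expected distance matrix implied by the posterior.

    Per draw, the deme-level expected dissimilarity Delta is computed from
    that draw's surfaces and scaled by its sigma2; the matrices are then
    averaged over draws.  Populations are the observed demes.  Returns
    (matrix over observed demes, observed deme indices).
    """
    from .mcmc import PosteriorDraws  # local import to avoid a cycle
    from .model import expected_dissimilarity, rates_on_edges, resistance_distances

    assert isinstance(draws, PosteriorDraws)
    demes = assignment.observed_vertices
    graph = draws.graph
    acc = np.zeros((len(demes), len(demes)))
    for i in range(draws.n_draws):
        cond = rates_on_edges(draws.vertex_log10_m[i], graph)
        R = resistance_distances(graph, cond)
        q = 10.0 ** draws.vertex_log10_q[i]
        delta = expected_dissimilarity(R, q, demes)
        acc += draws.sigma2[i] * delta.between
    return acc / draws.n_draws, demes


@dataclasses.dataclass
class FitResult:
    method: str
    expected: np.ndarray
    observed: np.ndarray
    pearson_r: float


def fit_correlation(expected: np.ndarray, observed: np.ndarray,
                    method: str = "model") -> FitResult:
    """Pearson correlation between expected and observed pairwise distances
    (upper triangle, diagonal excluded)."""
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if expected.shape != observed.shape:
        raise ValueError("matrices must have matching shapes")
    if expected.shape[0] < 3:
        raise ValueError("need at least 3 populations")
    iu = np.triu_indices(expected.shape[0], k=1)
    x, y = expected[iu], observed[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in pairwise distances")
    r = float(np.corrcoef(x, y)[0, 1])
    return FitResult(method, expected, observed, r)


def fst_empirical(g: GenotypeMatrix, pops: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham (1984) FST, ratio-of-sums form.

    Per-locus variance components a (between populations), b (between
    individuals within populations) and c (within individuals) are summed
    over polymorphic loci; FST = sum(a) / sum(a + b + c).
    """
    pops = np.asarray(pops)
    labels = sorted(set(pops.tolist()))
    r = len(labels)
    if r < 2:
        raise ValueError("need at least 2 populations")
    calls = g.calls
    masks = [pops == lab for lab in labels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each population needs at least 2 individuals")

    # per-locus, per-pop sample sizes (non-missing), allele freqs, het freqs
    n_i = np.stack([(calls[m] != -1).sum(axis=0) for m in masks])  # (r, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.stack([
            np.where(calls[m] != -1, calls[m], 0).sum(axis=0) / (2 * (calls[m] != -1).sum(axis=0))
            for m in masks
        ])
        h_i = np.stack([
            ((calls[m] == 1).sum(axis=0)) / (calls[m] != -1).sum(axis=0)
            for m in masks
        ])
    usable = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]

    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    nc = (n_total - (n_i ** 2).sum(axis=0) / n_total) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / n_total
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / n_total

    poly = (p_bar > 0) & (p_bar < 1)
    if not poly.any():
        raise ValueError("all loci are monomorphic")
    n_bar, nc, p_bar, s2, h_bar = (x[poly] for x in (n_bar, nc, p_bar, s2, h_bar))

    pq = p_bar * (1 - p_bar)
    a = (n_bar / nc) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("zero total variance; FST undefined")
    return float(a.sum() / denom)


def island_kappa(n_demes: int) -> float:
    """Finite-island geometry constant (d / (d - 1))^2 for the
    equilibrium FST formula; for two demes this gives FST = 1/(1 + 16Nm)."""
    if n_demes < 2:
        raise ValueError("need at least 2 demes")
    return (n_demes / (n_demes - 1)) ** 2


def fst_stepping_stone(mean_m: float, deme_size_scaling: float = 1.0,
                       kappa: float = 1.0) -> float:
    """Equilibrium stepping-stone FST from a mean migration rate.

    ``FST = 1 / (1 + 4 M kappa)`` with ``M = deme_size_scaling * mean_m``
    (the number of migrants Nm when ``deme_size_scaling`` is the deme
    size).  ``kappa`` is a lattice-geometry constant; the default 1 is the
    infinite-island approximation, :func:`island_kappa` gives the
    finite-island correction.  An approximation in either case.
    """
    if mean_m <= 0 or deme_size_scaling <= 0 or kappa <= 0:
        raise ValueError("mean_m, deme_size_scaling and kappa must be positive")
    M = deme_size_scaling * mean_m
    return 1.0 / (1.0 + 4.0 * M * kappa)


def great_circle_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) for lon/lat coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    D = haversine_km(coords, coords)
    np.fill_diagonal(D, 0.0)
    return D


def language_distance(labels: pd.Series | np.ndarray) -> np.ndarray:
    """0/1 same/different language-group matrix; unassigned (null) labels
    give NaN rows, which callers should drop before testing."""
    lab = pd.Series(labels).to_numpy(dtype=object)
    same = lab[:, None] == lab[None, :]
    out = 1.0 - same.astype(float)
    null = pd.isna(pd.Series(labels)).to_numpy()
    out[null, :] = np.nan
    out[:, null] = np.nan
    np.fill_diagonal(out, 0.0)
    return out


@dataclasses.dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.c_[np.ones_like(x), x]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(D_gen: np.ndarray, D_lang: np.ndarray, D_geo: np.ndarray,
                   n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Partial Mantel test of D_gen vs D_lang controlling for D_geo.

    The statistic is the Pearson correlation of upper-triangle residuals
    after regressing both D_gen and D_lang on D_geo.  The null distribution
    permutes rows and columns of D_gen jointly; the one-sided upper p-value
    is ``(1 + #{perm r >= observed r}) / (n_perm + 1)``.

    Caveat: Mantel-type tests are poorly calibrated under strong spatial
    autocorrelation; treat p-values as indicative.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    D_gen, D_lang, D_geo = (np.asarray(m, dtype=float) for m in (D_gen, D_lang, D_geo))
    if not (D_gen.shape == D_lang.shape == D_geo.shape):
        raise ValueError("matrices must have matching shapes")
    n = D_gen.shape[0]
    iu = np.triu_indices(n, k=1)
    geo = D_geo[iu]
    lang_res = _residualize(D_lang[iu], geo)
    if lang_res.std() == 0 or D_gen[iu].std() == 0:
        raise ValueError("constant matrix: Mantel statistic undefined")

    def stat(Dg: np.ndarray) -> float:
        gen_res = _residualize(Dg[iu], geo)
        if gen_res.std() == 0:
            return 0.0
        return float(np.corrcoef(gen_res, lang_res)[0, 1])

    r_obs = stat(D_gen)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(D_gen[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm)
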