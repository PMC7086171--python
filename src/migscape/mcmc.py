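"""Reversible-jump MCMC over rate tessellations, posterior summaries,
trough/corridor consensus, and Bayes factors against uniform migration.

The sampler explores two Voronoi tessellations (migration m and diversity
q) with a variable number of tiles, plus the scalar parameters sigma2,
omega2_m, omega2_q and the diversity level mu_q (the migration level mu_m
is fixed at 0: migration rates are relative, their scale being absorbed
jointly by sigma2).  Priors:

* tile counts K ~ zero-truncated Poisson(lambda), default lambda = 10;
* tile effects ~ Normal(0, omega2) truncated to +/- effect_bound;
* tile seeds ~ Uniform over the region bounding box;
* omega2 ~ Uniform(0, 1); mu_q ~ Uniform(-6, 6); sigma2 ~ Inv-Gamma(1, 1).

Birth proposals draw the new tile from its prior and death picks a tile
uniformly, so the reversible-jump acceptance ratio reduces to the
likelihood ratio times lambda/(K+1) for birth and K/lambda for death
(unordered-tile convention).  Marginal likelihoods for Bayes factors are
estimated by power posteriors with a temperature ladder t_k = (k/(K-1))^5
and trapezoidal thermodynamic integration, which is stable at desk scale
where harmonic-mean estimators are not.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln, ndtr
from scipy.spatial.distance import cdist

from .grids import DemeGraph, SampleAssignment
from .model import (
    EFFECT_BOUND_DEFAULT,
    ModelState,
    RateTessellation,
    contrast_project,
    expected_dissimilarity,
    graph_laplacian,
    individual_expected_matrix,
)

MOVE_NAMES = ("effect", "seed", "birth", "death", "sigma2", "omega2", "mu")


@dataclasses.dataclass
class McmcConfig:
    """Sampler schedule, proposal scales and prior hyperparameters.

    The field names mirror the run protocol used for the continental
    panels: several pilot runs, the best of which seeds the final run;
    long final runs with an initial burn-in discarded and sparse thinning
    (panel-scale analyses use up to 8e6 pilot iterations, 5e5 burn-in and
    thinning every 2e4 iterations; synthetic-data runs use far less).
    """

    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 200
    n_pilot: int = 4
    pilot_iter: int = 5_000
    seed: int = 0
    # priors
    lambda_tiles: float = 10.0
    effect_bound: float = EFFECT_BOUND_DEFAULT
    omega2_max: float = 1.0
    mu_q_range: tuple[float, float] = (-6.0, 6.0)
    sigma2_shape: float = 1.0
    sigma2_scale: float = 1.0
    # proposal scales
    effect_step: float = 0.1
    seed_step: float | None = None  # default: grid spacing
    sigma2_logstep: float = 0.3
    omega2_step: float = 0.1
    mu_step: float = 0.2
    move_weights: tuple[float, ...] = (0.25, 0.2, 0.1, 0.1, 0.1, 0.1, 0.15)
    # marginal-likelihood ladder
    n_temperatures: int = 16
    ladder_power: float = 5.0
    ti_iter: int = 2_000
    # posterior raster resolution
    raster_shape: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        w = np.asarray(self.move_weights, dtype=float)
        if len(w) != len(MOVE_NAMES) or not np.isclose(w.sum(), 1.0):
            raise ValueError("move_weights must be 7 values summing to 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def temperatures(self) -> np.ndarray:
        k = np.arange(self.n_temperatures)
        return (k / (self.n_temperatures - 1)) ** self.ladder_power


def _log_truncnorm(x: np.ndarray, omega2: float, bound: float) -> float:
    """Sum of log N(0, omega2) densities truncated to [-bound, bound]."""
    sd = math.sqrt(omega2)
    z = 2.0 * ndtr(bound / sd) - 1.0
    x = np.atleast_1d(x)
    return float(
        (-0.5 * np.log(2 * np.pi * omega2) - x ** 2 / (2 * omega2)).sum()
        - len(x) * np.log(z)
    )


class SurfaceLikelihood:
    """Precomputed data terms for fast Wishart log-likelihood evaluation.

    Holds the contrast-projected observed scatter S = -1/2 C D C^T p and
    the constants of the Wishart density, and maps a pair of tessellations
    to (logdet M, tr(M^-1 S)) where Sigma = sigma2 * M.
    """

    def __init__(self, D_obs: np.ndarray, graph: DemeGraph,
                 assignment: SampleAssignment, p: int):
        D_obs = np.asarray(D_obs, dtype=float)
        n = D_obs.shape[0]
        if n < 3:
            raise ValueError("need at least 3 individuals")
        if p < n:
            raise ValueError("p < n: Wishart density undefined")
        self.graph = graph
        self.p = int(p)
        self.n = n
        self.m_dim = n - 1
        self.deme_of_individual = np.asarray(assignment.vertex_of_sample, dtype=int)
        self.observed_demes = assignment.observed_vertices
        self.S = -0.5 * contrast_project(D_obs) * p
        cS = cho_factor(self.S, lower=True)
        self.logdet_S = 2.0 * np.log(np.diag(cS[0])).sum()
        from scipy.special import multigammaln

        m = self.m_dim
        self.const = (
            0.5 * (p - m - 1) * self.logdet_S
            - 0.5 * p * m * np.log(2.0)
            - multigammaln(p / 2.0, m)
        )

    def aux(self, m_seeds: np.ndarray, m_effects: np.ndarray,
            q_seeds: np.ndarray, q_effects: np.ndarray,
            mu_q: float) -> tuple[float, float] | None:
        """(logdet M, tr(M^-1 S)) for the given surfaces, or None if M is
        numerically not positive definite."""
        g = self.graph
        lm = m_effects[cdist(g.coords, np.atleast_2d(m_seeds)).argmin(axis=1)]
        u, v = g.edges.T
        cond = 10.0 ** ((lm[u] + lm[v]) / 2.0)
        L = graph_laplacian(g, cond)
        nv = g.n_vertices
        try:
            Linv = np.linalg.inv(L + 1.0 / nv)
        except np.linalg.LinAlgError:
            return None
        Lplus_diag = np.diag(Linv) - 1.0 / nv
        demes = self.observed_demes
        sub = Linv[np.ix_(demes, demes)] - 1.0 / nv
        d = np.diag(sub)
        Rsub = d[:, None] + d[None, :] - 2.0 * sub
        lq = mu_q + q_effects[cdist(g.coords[demes], np.atleast_2d(q_seeds)).argmin(axis=1)]
        qa = 10.0 ** lq
        between = (qa[:, None] + qa[None, :]) / 2.0 + Rsub / 4.0
        np.fill_diagonal(between, qa)
        # individual-level Delta* (zero diagonal), then M = -1/2 C Delta* C^T
        local = np.searchsorted(demes, self.deme_of_individual)
        Dstar = between[np.ix_(local, local)].copy()
        np.fill_diagonal(Dstar, 0.0)
        M = -0.5 * contrast_project(Dstar)
        try:
            cM = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            return None
        diag = np.diag(cM[0])
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            return None
        logdet_M = 2.0 * np.log(diag).sum()
        tr = float(np.trace(cho_solve(cM, self.S)))
        return float(logdet_M), tr

    def loglik(self, aux: tuple[float, float] | None, sigma2: float) -> float:
        if aux is None:
            return -np.inf
        logdet_M, tr = aux
        m, p = self.m_dim, self.p
        return float(
            self.const
            - 0.5 * tr / sigma2
            - 0.5 * p * (m * np.log(sigma2) + logdet_M)
        )


@dataclasses.dataclass
class _Chain:
    """Mutable sampler state (internal)."""

    m_seeds: np.ndarray
    m_effects: np.ndarray
    q_seeds: np.ndarray
    q_effects: np.ndarray
    mu_q: float
    sigma2: float
    omega2_m: float
    omega2_q: float
    aux: tuple[float, float] | None = None
    loglik: float = 0.0

    def to_model_state(self, cfg: McmcConfig) -> ModelState:
        return ModelState(
            RateTessellation(self.m_seeds.copy(), self.m_effects.copy(), 0.0,
                             cfg.effect_bound),
            RateTessellation(self.q_seeds.copy(), self.q_effects.copy(), self.mu_q,
                             cfg.effect_bound),
            self.sigma2, self.omega2_m, self.omega2_q, self.loglik,
        )


def _log_prior(chain: _Chain, cfg: McmcConfig, log_area: float) -> float:
    lam = cfg.lambda_tiles
    lp = 0.0
    for k, effects, om2 in (
        (len(chain.m_effects), chain.m_effects, chain.omega2_m),
        (len(chain.q_effects), chain.q_effects, chain.omega2_q),
    ):
        lp += k * np.log(lam) - gammaln(k + 1) - np.log(np.expm1(lam))
        lp += _log_truncnorm(effects, om2, cfg.effect_bound)
        lp += -k * log_area
    lo, hi = cfg.mu_q_range
    if not (lo <= chain.mu_q <= hi):
        return -np.inf
    lp -= np.log(hi - lo)
    if not (0 < chain.omega2_m <= cfg.omega2_max and 0 < chain.omega2_q <= cfg.omega2_max):
        return -np.inf
    a, b = cfg.sigma2_shape, cfg.sigma2_scale
    lp += a * np.log(b) - gammaln(a) - (a + 1) * np.log(chain.sigma2) - b / chain.sigma2
    return float(lp)


class Sampler:
    """One reversible-jump chain over a fixed data set.

    ``ev=None`` runs the prior only (likelihood identically zero), used for
    prior-recovery checks.  ``uniform_m=True`` pins the migration surface
    to a single tile (no birth/death/seed moves for m), the constrained
    model of the Bayes-factor comparison.  ``temperature`` tempers the
    likelihood for power-posterior estimation.
    """

    def __init__(self, ev: SurfaceLikelihood | None, graph: DemeGraph,
                 cfg: McmcConfig, rng: np.random.Generator,
                 uniform_m: bool = False, temperature: float = 1.0):
        self.ev = ev
        self.graph = graph
        self.cfg = cfg
        self.rng = rng
        self.uniform_m = uniform_m
        self.temperature = temperature
        lo = graph.coords.min(axis=0)
        hi = graph.coords.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        self.bbox_lo, self.bbox_hi = lo, hi
        self.log_area = float(np.log(span).sum())
        self.seed_step = cfg.seed_step if cfg.seed_step is not None else graph.spacing_km
        self.proposed = dict.fromkeys(MOVE_NAMES, 0)
        self.accepted = dict.fromkeys(MOVE_NAMES, 0)
        self.state = self._initial_state()

    def _initial_state(self) -> _Chain:
        center = (self.bbox_lo + self.bbox_hi) / 2.0
        mu_q0 = 0.0
        sigma20 = 1.0
        if self.ev is not None:
            # start mu_q near the scale of the observed dissimilarities
            mean_d = float(np.mean(self.ev.S.diagonal())) / self.ev.p
            mu_q0 = float(np.clip(np.log10(max(mean_d, 1e-6)), *self.cfg.mu_q_range))
        chain = _Chain(
            m_seeds=np.atleast_2d(center.copy()),
            m_effects=np.zeros(1),
            q_seeds=np.atleast_2d(center.copy()),
            q_effects=np.zeros(1),
            mu_q=mu_q0,
            sigma2=sigma20,
            omega2_m=0.25,
            omega2_q=0.25,
        )
        self._refresh(chain)
        return chain

    def _refresh(self, chain: _Chain) -> None:
        if self.ev is None:
            chain.aux, chain.loglik = None, 0.0
        else:
            chain.aux = self.ev.aux(chain.m_seeds, chain.m_effects,
                                    chain.q_seeds, chain.q_effects, chain.mu_q)
            chain.loglik = self.ev.loglik(chain.aux, chain.sigma2)

    def log_posterior(self, chain: _Chain) -> float:
        return self.temperature * chain.loglik + _log_prior(chain, self.cfg, self.log_area)

    # -- individual moves ------------------------------------------------

    def _loglik_for(self, chain: _Chain, m_seeds, m_effects, q_seeds, q_effects,
                    mu_q, sigma2) -> tuple[tuple | None, float]:
        if self.ev is None:
            return None, 0.0
        aux = self.ev.aux(m_seeds, m_effects, q_seeds, q_effects, mu_q)
        return aux, self.ev.loglik(aux, sigma2)

    def step(self) -> tuple[str, bool]:
        """One Metropolis-Hastings / reversible-jump move; returns the move
        name and whether it was accepted."""
        rng = self.rng
        cfg = self.cfg
        chain = self.state
        surface = "m" if rng.random() < 0.5 else "q"
        move = MOVE_NAMES[rng.choice(len(MOVE_NAMES), p=cfg.move_weights)]
        if self.uniform_m and surface == "m" and move in ("seed", "birth", "death"):
            # constrained model: single migration tile, position irrelevant
            self.proposed[move] += 1
            return move, False
        self.proposed[move] += 1
        accept = False
        t = self.temperature

        if move in ("effect", "seed", "birth", "death"):
            seeds = chain.m_seeds if surface == "m" else chain.q_seeds
            effects = chain.m_effects if surface == "m" else chain.q_effects
            omega2 = chain.omega2_m if surface == "m" else chain.omega2_q
            K = len(effects)
            if move == "effect":
                i = rng.integers(K)
                new_effects = effects.copy()
                new_effects[i] += rng.normal(0.0, cfg.effect_step)
                if abs(new_effects[i]) <= cfg.effect_bound:
                    dprior = _log_truncnorm(new_effects[i], omega2, cfg.effect_bound) \
                        - _log_truncnorm(effects[i], omega2, cfg.effect_bound)
                    aux, ll = self._try(chain, surface, seeds, new_effects)
                    if np.log(rng.random()) < t * (ll - chain.loglik) + dprior:
                        self._commit(chain, surface, seeds, new_effects, aux, ll)
                        accept = True
            elif move == "seed":
                i = rng.integers(K)
                new_seeds = seeds.copy()
                new_seeds[i] += rng.normal(0.0, self.seed_step, size=2)
                if np.all((new_seeds[i] >= self.bbox_lo) & (new_seeds[i] <= self.bbox_hi)):
                    aux, ll = self._try(chain, surface, new_seeds, effects)
                    if np.log(rng.random()) < t * (ll - chain.loglik):
                        self._commit(chain, surface, new_seeds, effects, aux, ll)
                        accept = True
            elif move == "birth":
                new_seed = rng.uniform(self.bbox_lo, self.bbox_hi)
                new_effect = self._draw_effect(omega2)
                new_seeds = np.vstack([seeds, new_seed])
                new_effects = np.append(effects, new_effect)
                log_ratio = np.log(cfg.lambda_tiles / (K + 1))
                aux, ll = self._try(chain, surface, new_seeds, new_effects)
                if np.log(rng.random()) < t * (ll - chain.loglik) + log_ratio:
                    self._commit(chain, surface, new_seeds, new_effects, aux, ll)
                    accept = True
            else:  # death
                if K >= 2:  # K=0 has zero prior mass under the zero-truncated Poisson
                    i = rng.integers(K)
                    new_seeds = np.delete(seeds, i, axis=0)
                    new_effects = np.delete(effects, i)
                    log_ratio = np.log(K / cfg.lambda_tiles)
                    aux, ll = self._try(chain, surface, new_seeds, new_effects)
                    if np.log(rng.random()) < t * (ll - chain.loglik) + log_ratio:
                        self._commit(chain, surface, new_seeds, new_effects, aux, ll)
                        accept = True
        elif move == "sigma2":
            # symmetric two-scale mixture: coarse steps traverse the prior,
            # fine steps match the sharply peaked posterior at large n*p
            sd = cfg.sigma2_logstep * (1.0 if rng.random() < 0.5 else 0.02)
            new_sigma2 = chain.sigma2 * np.exp(rng.normal(0.0, sd))
            a, b = cfg.sigma2_shape, cfg.sigma2_scale
            dprior = (-(a + 1) * np.log(new_sigma2) - b / new_sigma2) \
                - (-(a + 1) * np.log(chain.sigma2) - b / chain.sigma2)
            jac = np.log(new_sigma2 / chain.sigma2)
            ll = 0.0 if self.ev is None else self.ev.loglik(chain.aux, new_sigma2)
            if np.log(rng.random()) < t * (ll - chain.loglik) + dprior + jac:
                chain.sigma2 = float(new_sigma2)
                chain.loglik = ll
                accept = True
        elif move == "omega2":
            if surface == "m":
                old, effects = chain.omega2_m, chain.m_effects
            else:
                old, effects = chain.omega2_q, chain.q_effects
            new = old + rng.normal(0.0, cfg.omega2_step)
            if 0 < new <= cfg.omega2_max:
                dprior = _log_truncnorm(effects, new, cfg.effect_bound) \
                    - _log_truncnorm(effects, old, cfg.effect_bound)
                if np.log(rng.random()) < dprior:  # likelihood unchanged
                    if surface == "m":
                        chain.omega2_m = float(new)
                    else:
                        chain.omega2_q = float(new)
                    accept = True
        else:  # mu (diversity level; the migration level is pinned at 0)
            sd = cfg.mu_step * (1.0 if rng.random() < 0.5 else 0.02)
            new_mu = chain.mu_q + rng.normal(0.0, sd)
            lo, hi = cfg.mu_q_range
            if lo <= new_mu <= hi:
                aux, ll = self._loglik_for(chain, chain.m_seeds, chain.m_effects,
                                           chain.q_seeds, chain.q_effects,
                                           new_mu, chain.sigma2)
                if np.log(rng.random()) < t * (ll - chain.loglik):
                    chain.mu_q = float(new_mu)
                    chain.aux, chain.loglik = aux, ll
                    accept = True
        if accept:
            self.accepted[move] += 1
        return move, accept

    def _draw_effect(self, omega2: float) -> float:
        bound = self.cfg.effect_bound
        sd = math.sqrt(omega2)
        while True:  # truncated normal by rejection; acceptance >= erf(2/sd)
            x = self.rng.normal(0.0, sd)
            if abs(x) <= bound:
                return float(x)

    def _try(self, chain: _Chain, surface: str, seeds, effects):
        if surface == "m":
            return self._loglik_for(chain, seeds, effects, chain.q_seeds,
                                    chain.q_effects, chain.mu_q, chain.sigma2)
        return self._loglik_for(chain, chain.m_seeds, chain.m_effects,
                                seeds, effects, chain.mu_q, chain.sigma2)

    def _commit(self, chain: _Chain, surface: str, seeds, effects, aux, ll) -> None:
        if surface == "m":
            chain.m_seeds, chain.m_effects = np.atleast_2d(seeds), np.asarray(effects)
        else:
            chain.q_seeds, chain.q_effects = np.atleast_2d(seeds), np.asarray(effects)
        chain.aux, chain.loglik = aux, ll

    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self.step()

    def acceptance_rates(self) -> dict[str, float]:
        return {m: (self.accepted[m] / self.proposed[m] if self.proposed[m] else np.nan)
                for m in MOVE_NAMES}


def mcmc_step(sampler: Sampler) -> tuple[str, bool]:
    """Advance a sampler by one move; returns (move name, accepted)."""
    return sampler.step()


@dataclasses.dataclass
class PosteriorDraws:
    """Thinned posterior samples with rasterized migration surfaces."""

    graph: DemeGraph
    states: list[ModelState]
    vertex_log10_m: np.ndarray  # (ndraw, V)
    vertex_log10_q: np.ndarray  # (ndraw, V)
    sigma2: np.ndarray
    loglik: np.ndarray
    k_m: np.ndarray
    k_q: np.ndarray
    cell_to_vertex: np.ndarray  # (rows*cols,) nearest-vertex index per raster cell
    raster_shape: tuple[int, int]
    acceptance_rates: dict[str, float]

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)

    def rasters(self) -> np.ndarray:
        """(ndraw, rows, cols) stack of log10 m rasters (graph-Voronoi cells
        sampled on the fixed lattice over the region bounding box)."""
        flat = self.vertex_log10_m[:, self.cell_to_vertex]
        return flat.reshape(self.n_draws, *self.raster_shape)

    def cell_truth(self, vertex_values: np.ndarray) -> np.ndarray:
        """Rasterize a per-vertex quantity on the same cell grid."""
        return np.asarray(vertex_values)[self.cell_to_vertex].reshape(self.raster_shape)


def raster_cell_map(graph: DemeGraph, shape: tuple[int, int]) -> np.ndarray:
    """Nearest graph vertex for each cell center of a shape-(r, c) lattice
    over the graph's bounding box."""
    lo = graph.coords.min(axis=0)
    hi = graph.coords.max(axis=0)
    rows, cols = shape
    xs = lo[0] + (np.arange(cols) + 0.5) / cols * (hi[0] - lo[0])
    ys = lo[1] + (np.arange(rows) + 0.5) / rows * (hi[1] - lo[1])
    XX, YY = np.meshgrid(xs, ys)
    pts = np.c_[XX.ravel(), YY.ravel()]
    return graph.distance_matrix(pts).argmin(axis=1)


def _vertex_rates(chain: _Chain, graph: DemeGraph) -> tuple[np.ndarray, np.ndarray]:
    lm = chain.m_effects[cdist(graph.coords, chain.m_seeds).argmin(axis=1)]
    lq = chain.mu_q + chain.q_effects[cdist(graph.coords, chain.q_seeds).argmin(axis=1)]
    return lm, lq


def run_chain(D_obs: np.ndarray | None, graph: DemeGraph,
              assignment: SampleAssignment | None, cfg: McmcConfig,
              p: int | None = None, uniform_m: bool = False) -> PosteriorDraws:
    """Pilot-then-final sampling protocol.

    Runs ``cfg.n_pilot`` pilot chains of ``cfg.pilot_iter`` steps from
    independent seeds, selects the end state with the highest posterior
    log-density, continues the final chain from it for ``cfg.n_iter``
    steps, discards ``cfg.burn_in`` and keeps every ``cfg.thin``-th state.

    ``D_obs=None`` samples the prior (no likelihood); then ``assignment``
    and ``p`` are unused.
    """
    root = np.random.SeedSequence(cfg.seed)
    ev = None
    if D_obs is not None:
        if p is None:
            raise ValueError("p (number of loci) required with data")
        ev = SurfaceLikelihood(D_obs, graph, assignment, p)

    pilot_seeds = root.spawn(cfg.n_pilot + 1)
    best: Sampler | None = None
    best_lp = -np.inf
    if cfg.n_pilot > 0 and cfg.pilot_iter > 0:
        for ss in pilot_seeds[:-1]:
            s = Sampler(ev, graph, cfg, np.random.default_rng(ss),
                        uniform_m=uniform_m)
            s.run(cfg.pilot_iter)
            lp = s.log_posterior(s.state)
            if np.isfinite(lp) and lp > best_lp:
                best_lp, best = lp, s
        if best is None:
            raise RuntimeError("all pilot chains diverged (non-finite posterior)")
    final = Sampler(ev, graph, cfg, np.random.default_rng(pilot_seeds[-1]),
                    uniform_m=uniform_m)
    if best is not None:
        final.state = best.state
        final._refresh(final.state)

    cell_map = raster_cell_map(graph, cfg.raster_shape)
    states: list[ModelState] = []
    vm, vq, s2, ll, km, kq = [], [], [], [], [], []
    for it in range(1, cfg.n_iter + 1):
        final.step()
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            chain = final.state
            states.append(chain.to_model_state(cfg))
            lm_v, lq_v = _vertex_rates(chain, graph)
            vm.append(lm_v)
            vq.append(lq_v)
            s2.append(chain.sigma2)
            ll.append(chain.loglik)
            km.append(len(chain.m_effects))
            kq.append(len(chain.q_effects))
    if not states:
        raise ValueError("schedule yields no draws (n_iter too close to burn_in)")
    return PosteriorDraws(
        graph, states, np.array(vm), np.array(vq), np.array(s2), np.array(ll),
        np.array(km), np.array(kq), cell_map, cfg.raster_shape,
        final.acceptance_rates(),
    )


def posterior_mean_surface(draws: PosteriorDraws) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise posterior mean and sd (ddof=1) of log10 m across draws."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws")
    r = draws.rasters()
    return r.mean(axis=0), r.std(axis=0, ddof=1)


def detect_troughs(draws: PosteriorDraws, threshold: float = 0.95
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Consensus trough/corridor labels on the raster grid.

    Per cell, ``f_low`` is the fraction of draws in which the cell's
    log10 m lies below that draw's across-cell mean.  A cell is a trough
    when ``f_low >= threshold`` and a corridor when ``1 - f_low >=
    threshold`` — the cell-wise realization of features "present in >95%
    of MCMC iterations" at the default threshold.

    Returns (labels, f_low); labels are 0 = neither, -1 = trough,
    +1 = corridor.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    if draws.n_draws < 20:
        raise ValueError("need at least 20 draws for a consensus call")
    r = draws.rasters().reshape(draws.n_draws, -1)
    below = r < r.mean(axis=1, keepdims=True)
    f_low = below.mean(axis=0)
    labels = np.zeros(f_low.shape, dtype=int)
    labels[f_low >= threshold] = -1
    labels[(1.0 - f_low) >= threshold] = 1
    shape = draws.raster_shape
    return labels.reshape(shape), f_low.reshape(shape)


def _power_posterior_logz(ev: SurfaceLikelihood, graph: DemeGraph,
                          cfg: McmcConfig, rng_seq: np.random.SeedSequence,
                          uniform_m: bool) -> float:
    """log marginal likelihood via power posteriors + trapezoidal
    thermodynamic integration; chains are warm-started up the ladder."""
    temps = cfg.temperatures()
    seeds = rng_seq.spawn(len(temps))
    means = []
    state = None
    for t, ss in zip(temps, seeds):
        s = Sampler(ev, graph, cfg, np.random.default_rng(ss),
                    uniform_m=uniform_m, temperature=float(t))
        if state is not None:
            s.state = state
            s._refresh(s.state)
        burn = cfg.ti_iter // 2
        s.run(burn)
        total, count = 0.0, 0
        for _ in range(cfg.ti_iter - burn):
            s.step()
            total += s.state.loglik
            count += 1
        if count == 0 or not np.isfinite(total):
            raise RuntimeError(f"power-posterior chain failed at temperature {t}")
        means.append(total / count)
        state = s.state
    return float(np.trapezoid(means, temps))


def log_bayes_factor(D_obs: np.ndarray, graph: DemeGraph,
                     assignment: SampleAssignment, cfg: McmcConfig,
                     p: int) -> float:
    """log Bayes factor: heterogeneous migration vs uniform migration.

    Both marginal likelihoods are estimated by power posteriors on the
    ladder ``t_k = (k/(K-1))^ladder_power``; the constrained model fixes
    the migration tessellation to a single tile (one migration rate, free
    diversity tessellation).  Positive values favour heterogeneous
    migration.
    """
    ev = SurfaceLikelihood(D_obs, graph, assignment, p)
    root = np.random.SeedSequence(cfg.seed)
    full_seq, unif_seq = root.spawn(2)
    logz_full = _power_posterior_logz(ev, graph, cfg, full_seq, uniform_m=False)
    logz_unif = _power_posterior_logz(ev, graph, cfg, unif_seq, uniform_m=True)
    return logz_full - logz_unif
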