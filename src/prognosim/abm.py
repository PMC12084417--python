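"""Discrete-time agent-based simulator of tumor growth.

Cancer-cell agents live on a fixed 2-D lattice. Each carries a position,
a size ``S`` and a per-gene expression vector ``E``. Per step, synchronously
from previous-step values:

1. nutrient diffusion (4-neighbor mixing, zero-flux boundary);
2. size update ΔS(t) = f(E_growth(t−1), N(t−1)) − d, where the growth
   term f couples a weighted growth-gene signal, local nutrient
   (Michaelis–Menten) and logistic crowding (1 − N/K);
3. expression update (logistic self-limiting law, or an additive
   production − degradation ± interaction law);
4. division when a cell reaches twice its initial size (daughter placed
   on a free neighbor site, blocked when none is free or N ≥ K) and
   death when S falls to 0;
5. immune agents move one lattice step toward the nearest cancer cell,
   activate on adjacency, and when activated remove ``kill_rate`` size
   units from an adjacent target;
6. nutrient consumption by cancer cells plus a vascular replenishment
   term relaxing the field toward its initial level.

Relapse is the first step at which total tumor size reaches a threshold,
and simulated overall survival is the time to that endpoint, capped at
the simulation horizon.

Population-level counterparts (the logistic-minus-death growth law, its
closed-form trajectory, and Nelder–Mead / MCMC calibration against
observed trajectories) live here too.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import yaml

from .gene_link import GrowthGeneSet, growth_signal, interaction_term

__all__ = [
    "GrowthParams",
    "ExpressionDynParams",
    "SimulationConfig",
    "SimulationResult",
    "Simulation",
    "growth_increment",
    "logistic_trajectory",
    "expression_update",
    "run",
    "relapse_time",
    "overall_survival",
    "virtual_knockout",
    "KnockoutComparison",
    "sensitivity_analysis",
    "calibrate",
    "CalibrationResult",
    "load_sim_config",
    "save_sim_config",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Logistic-minus-death growth law parameters.

    r : proliferation rate per step; K : carrying capacity (cells);
    d : death rate per step; dt : step length in simulation time units.
    """

    r: float = 0.25
    K: float = 200.0
    d: float = 0.02
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.r < 0 or self.d < 0:
            raise ValueError("r and d must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class ExpressionDynParams:
    """Per-gene expression dynamics.

    mode="logistic": dE/dt = Signals·E·(1 − E/h), h acting as a capacity.
    mode="additive": dE/dt = g(S, Signals) − h ± k·A, h a flat degradation
    rate and ±k·A an interaction with a molecule at concentration A.
    Both readings of the update law are supported because they describe
    different biology (self-limiting activation vs constant turnover).
    """

    mode: str = "logistic"
    signals: float = 0.0
    h: float = 2.0
    production: Union[float, Callable[[float, float], float]] = 0.0
    k: float = 0.0
    A: float = 0.0
    interaction_sign: int = -1

    def __post_init__(self) -> None:
        if self.mode not in ("logistic", "additive"):
            raise ValueError("mode must be 'logistic' or 'additive'")
        if self.mode == "logistic" and self.h <= 0:
            raise ValueError("logistic mode requires h > 0")


@dataclass
class SimulationConfig:
    """Full simulator configuration; see module docstring for the rules."""

    grid_shape: tuple = (21, 21)
    n_cancer: int = 25
    n_immune: int = 0
    initial_cell_size: float = 1.0
    initial_expression: tuple = (1.0, 1.0)
    genes: GrowthGeneSet = field(default_factory=lambda: GrowthGeneSet((0, 1), (0.5, 0.5)))
    growth: GrowthParams = field(default_factory=GrowthParams)
    expr: ExpressionDynParams = field(default_factory=ExpressionDynParams)
    expression_coupling: float = 0.5
    nutrient_init: float = 1.0
    diffusion_coeff: float = 0.2
    consumption_rate: float = 0.01
    replenish_rate: float = 0.05
    half_saturation: float = 0.5
    kill_rate: float = 0.1
    division_factor: float = 2.0
    S_threshold: float = 300.0
    T_max: int = 150
    knockout_genes: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.diffusion_coeff <= 1.0):
            raise ValueError("diffusion_coeff must lie in [0, 1]")
        if self.kill_rate < 0:
            raise ValueError("kill_rate must be nonnegative")
        if self.T_max < 0:
            raise ValueError("T_max must be nonnegative")
        self.initial_expression = tuple(float(e) for e in self.initial_expression)
        if any(e < 0 for e in self.initial_expression):
            raise ValueError("initial expression must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.initial_expression)


@dataclass
class SimulationResult:
    """Recorded trajectories plus derived endpoints.

    Series have length T+1 (step 0 is the initial state). ``T_relapse`` is
    a step index or None; ``OS`` is in simulation time units.
    """

    N_series: np.ndarray
    S_series: np.ndarray
    E_series: np.ndarray  # (T+1, n_genes) mean expression per gene
    T_relapse: Optional[int]
    OS: float
    dt: float = 1.0

    def to_frame(self):
        import pandas as pd

        cols = {"step": np.arange(len(self.N_series)), "N": self.N_series, "S_total": self.S_series}
        for g in range(self.E_series.shape[1]):
            cols[f"mean_E_{g + 1}"] = self.E_series[:, g]
        return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# population-level growth law
# --------------------------------------------------------------------------


def growth_increment(N: float, p: GrowthParams) -> float:
    """One-step population increment dt·(r·N·(1 − N/K) − d·N)."""
    if N < 0:
        raise ValueError("N must be nonnegative")
    return p.dt * (p.r * N * (1.0 - N / p.K) - p.d * N)


def logistic_trajectory(
    r: float, K: float, N0: float, d: float = 0.0, times: Sequence[float] = (0.0,)
) -> np.ndarray:
    """Closed-form solution of dN/dt = r·N·(1 − N/K) − d·N.

    Written as dN/dt = a·N − b·N² with a = r − d and b = r/K this is a
    logistic curve toward the shifted capacity a/b = K·(r−d)/r; the a = 0
    and r = 0 special cases are the harmonic-decay and exponential-decay
    limits.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    times = np.asarray(times, dtype=float)
    if N0 == 0:
        return np.zeros_like(times)
    a = r - d
    b = r / K
    if b == 0.0:  # pure exponential growth/decay
        return N0 * np.exp(a * times)
    if a == 0.0:  # dN/dt = -b N^2
        return N0 / (1.0 + b * N0 * times)
    expat = np.exp(-a * times)
    return a / (b + (a / N0 - b) * expat)


# --------------------------------------------------------------------------
# expression update
# --------------------------------------------------------------------------


def expression_update(
    E: Union[float, np.ndarray],
    S: Union[float, np.ndarray],
    p: ExpressionDynParams,
    dt: float = 1.0,
) -> Union[float, np.ndarray]:
    """One-step expression update, clamped at zero.

    logistic: E ← E + dt·Signals·E·(1 − E/h)
    additive: E ← E + dt·(g(S, Signals) − h ± k·A)
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("expression must be nonnegative")
    if p.mode == "logistic":
        out = E + dt * p.signals * E * (1.0 - E / p.h)
    else:
        g = p.production(S, p.signals) if callable(p.production) else p.production
        out = E + dt * (np.asarray(g, dtype=float) - p.h + interaction_term(p.k, p.A, p.interaction_sign))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# the simulator
# --------------------------------------------------------------------------


def _diffuse(nut: np.ndarray, alpha: float) -> np.ndarray:
    """4-neighbor mixing with zero-flux (edge-mirrored) boundaries."""
    if alpha == 0.0:
        return nut.copy()
    pad = np.pad(nut, 1, mode="edge")
    lap = pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:] - 4.0 * nut
    return nut + (alpha / 4.0) * lap


_NEIGH = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])


class Simulation:
    """Stateful simulator; ``run`` is the usual entry point."""

    def __init__(self, config: SimulationConfig, seed: Optional[int] = None):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self._init_state()

    # -- state ------------------------------------------------------------

    def _init_state(self) -> None:
        cfg = self.cfg
        H, W = cfg.grid_shape
        if cfg.n_cancer > H * W:
            raise ValueError("more initial cancer cells than grid sites")
        # central compact block of sites, nearest-to-center first
        rows, cols = np.mgrid[0:H, 0:W]
        dist = (rows - (H - 1) / 2) ** 2 + (cols - (W - 1) / 2) ** 2
        order = np.argsort(dist.ravel(), kind="stable")[: cfg.n_cancer]
        self.pos = np.column_stack([rows.ravel()[order], cols.ravel()[order]]).astype(int)
        self.S = np.full(cfg.n_cancer, cfg.initial_cell_size, dtype=float)
        E0 = np.asarray(cfg.initial_expression, dtype=float).copy()
        E0[list(cfg.knockout_genes)] = 0.0
        self.E = np.tile(E0, (cfg.n_cancer, 1))
        self.occ = np.zeros((H, W), dtype=bool)
        self.occ[self.pos[:, 0], self.pos[:, 1]] = True
        self.nutrient = np.full((H, W), cfg.nutrient_init, dtype=float)
        self.immune_pos = np.column_stack(
            [self.rng.integers(0, H, cfg.n_immune), self.rng.integers(0, W, cfg.n_immune)]
        ).astype(int)
        self.immune_active = np.zeros(cfg.n_immune, dtype=bool)

    @property
    def N(self) -> int:
        return self.S.size

    def total_size(self) -> float:
        return float(self.S.sum())

    def mean_expression(self) -> np.ndarray:
        if self.N == 0:
            return np.zeros(self.cfg.n_genes)
        return self.E.mean(axis=0)

    # -- one step ---------------------------------------------------------

    def step(self) -> None:
        cfg = self.cfg
        gp = cfg.growth
        N_prev = self.N
        S_prev = self.S.copy()

        # 1. nutrient diffusion
        self.nutrient = _diffuse(self.nutrient, cfg.diffusion_coeff)

        if N_prev:
            # 2. size update from previous-step expression / count
            Eg = growth_signal(self.E, cfg.genes)
            local = self.nutrient[self.pos[:, 0], self.pos[:, 1]]
            nu = local / (local + cfg.half_saturation)
            f = gp.r * (1.0 + cfg.expression_coupling * Eg) * nu * max(0.0, 1.0 - N_prev / gp.K)
            self.S = self.S + gp.dt * (f - gp.d)

            # 3. expression update from previous-step sizes
            self.E = np.atleast_2d(expression_update(self.E, S_prev[:, None], cfg.expr, gp.dt))
            if cfg.knockout_genes:
                self.E[:, list(cfg.knockout_genes)] = 0.0

            # 4a. division
            self._divide()
            # 4b. death
            self._reap()

        # 5. immune agents
        self._immune_phase()

        # 6. nutrient consumption + vascular replenishment
        if self.N:
            np.subtract.at(
                self.nutrient, (self.pos[:, 0], self.pos[:, 1]), cfg.consumption_rate
            )
        np.maximum(self.nutrient, 0.0, out=self.nutrient)
        self.nutrient += cfg.replenish_rate * (cfg.nutrient_init - self.nutrient)

    def _divide(self) -> None:
        cfg = self.cfg
        thresh = cfg.division_factor * cfg.initial_cell_size
        ready = np.flatnonzero(self.S >= thresh)
        if ready.size == 0:
            return
        H, W = cfg.grid_shape
        new_pos, new_S, new_E = [], [], []
        for i in self.rng.permutation(ready):
            if self.N + len(new_pos) >= cfg.growth.K:
                break
            nb = self.pos[i] + _NEIGH
            ok = (
                (nb[:, 0] >= 0) & (nb[:, 0] < H) & (nb[:, 1] >= 0) & (nb[:, 1] < W)
            )
            nb = nb[ok]
            free = nb[~self.occ[nb[:, 0], nb[:, 1]]]
            if free.shape[0] == 0:
                continue  # blocked: no free neighbor
            site = free[self.rng.integers(free.shape[0])]
            self.S[i] *= 0.5
            new_pos.append(site)
            new_S.append(self.S[i])
            new_E.append(self.E[i].copy())
            self.occ[site[0], site[1]] = True
        if new_pos:
            self.pos = np.vstack([self.pos, np.array(new_pos, dtype=int)])
            self.S = np.concatenate([self.S, np.array(new_S)])
            self.E = np.vstack([self.E, np.array(new_E)])

    def _reap(self) -> None:
        dead = self.S <= 0.0
        if not dead.any():
            return
        gone = self.pos[dead]
        self.occ[gone[:, 0], gone[:, 1]] = False
        keep = ~dead
        self.pos, self.S, self.E = self.pos[keep], self.S[keep], self.E[keep]

    def _immune_phase(self) -> None:
        cfg = self.cfg
        if self.immune_pos.shape[0] == 0 or self.N == 0:
            return
        for m in range(self.immune_pos.shape[0]):
            delta = self.pos - self.immune_pos[m]
            dist = np.abs(delta).sum(axis=1)
            j = int(np.argmin(dist))
            dr, dc = delta[j]
            if dist[j] > 1:  # move one step toward the nearest cancer cell
                if abs(dr) > abs(dc):
                    move = (np.sign(dr), 0)
                elif abs(dc) > abs(dr):
                    move = (0, np.sign(dc))
                else:
                    move = (np.sign(dr), 0) if self.rng.random() < 0.5 else (0, np.sign(dc))
                self.immune_pos[m] += np.array(move, dtype=int)
                delta = self.pos - self.immune_pos[m]
                dist = np.abs(delta).sum(axis=1)
                j = int(np.argmin(dist))
            if dist[j] <= 1:
                self.immune_active[m] = True
                if self.immune_active[m]:
                    self.S[j] = max(0.0, self.S[j] - cfg.kill_rate)

    # -- full run ---------------------------------------------------------

    def run(self, T_max: Optional[int] = None) -> SimulationResult:
        cfg = self.cfg
        T = cfg.T_max if T_max is None else T_max
        if T < 0:
            raise ValueError("T_max must be nonnegative")
        n_series = np.empty(T + 1, dtype=int)
        s_series = np.empty(T + 1, dtype=float)
        e_series = np.empty((T + 1, cfg.n_genes), dtype=float)
        n_series[0], s_series[0], e_series[0] = self.N, self.total_size(), self.mean_expression()
        for t in range(1, T + 1):
            self.step()
            n_series[t], s_series[t], e_series[t] = self.N, self.total_size(), self.mean_expression()
        t_rel = relapse_time(s_series, cfg.S_threshold)
        res = SimulationResult(n_series, s_series, e_series, t_rel, 0.0, cfg.growth.dt)
        res.OS = overall_survival(res, T)
        return res


def run(config: SimulationConfig, T_max: Optional[int] = None, seed: Optional[int] = None) -> SimulationResult:
    """Run a fresh simulation; series have length T_max + 1."""
    if (config.T_max if T_max is None else T_max) < 1:
        raise ValueError("T_max must be at least 1")
    return Simulation(config, seed=seed).run(T_max)


# --------------------------------------------------------------------------
# endpoints
# --------------------------------------------------------------------------


def relapse_time(S_series: Sequence[float], S_threshold: float) -> Optional[int]:
    """First step t with S(t) ≥ S_threshold (inclusive), or None."""
    S = np.asarray(S_series, dtype=float)
    if S.size == 0:
        raise ValueError("S_series must be nonempty")
    hits = np.flatnonzero(S >= S_threshold)
    return int(hits[0]) if hits.size else None


def overall_survival(result: SimulationResult, T_max: int) -> float:
    """Simulated time to the relapse endpoint, capped at the horizon.

    OS = T_relapse·dt when the endpoint fires, else T_max·dt.
    """
    if result.T_relapse is not None:
        return min(result.T_relapse, T_max) * result.dt
    return T_max * result.dt


# --------------------------------------------------------------------------
# in-silico experiments
# --------------------------------------------------------------------------


@dataclass
class KnockoutComparison:
    gene_index: int
    baseline: SimulationResult
    knockout: SimulationResult
    delta_T_relapse: float


def _relapse_or_horizon(res: SimulationResult, T_max: int) -> float:
    return float(res.T_relapse) if res.T_relapse is not None else float(T_max)


def virtual_knockout(config: SimulationConfig, gene_index: int, seed: Optional[int] = None) -> KnockoutComparison:
    """Force one gene's expression to zero for the whole run and compare.

    Baseline and knockout runs share the same seed, so any divergence is
    attributable to the silenced gene. ΔT_relapse > 0 means the knockout
    delayed relapse (never-relapsing runs count as the horizon T_max).
    """
    if not (0 <= gene_index < config.n_genes):
        raise IndexError("gene_index out of range")
    base = run(config, seed=seed)
    ko_cfg = dataclasses.replace(
        config, knockout_genes=tuple(sorted(set(config.knockout_genes) | {gene_index}))
    )
    ko = run(ko_cfg, seed=seed)
    delta = _relapse_or_horizon(ko, config.T_max) - _relapse_or_horizon(base, config.T_max)
    return KnockoutComparison(gene_index, base, ko, delta)


def sensitivity_analysis(
    config: SimulationConfig,
    gene_index: int,
    multipliers: Sequence[float],
    n_replicates: int = 5,
    seed: int = 0,
):
    """Scale one gene's initial expression and tabulate mean relapse time.

    Returns a DataFrame (multiplier, mean_T_relapse) with replicate-averaged
    relapse times; runs that never relapse contribute the horizon T_max.
    """
    import pandas as pd

    if not (0 <= gene_index < config.n_genes):
        raise IndexError("gene_index out of range")
    multipliers = list(multipliers)
    if any(m <= 0 for m in multipliers):
        raise ValueError("multipliers must be positive")
    rows = []
    for mult in multipliers:
        expr = list(config.initial_expression)
        expr[gene_index] *= mult
        cfg = dataclasses.replace(config, initial_expression=tuple(expr))
        ts = [
            _relapse_or_horizon(run(cfg, seed=seed + 1000 * rep), config.T_max)
            for rep in range(n_replicates)
        ]
        rows.append({"multiplier": mult, "mean_T_relapse": float(np.mean(ts))})
    return pd.DataFrame(rows, columns=["multiplier", "mean_T_relapse"])


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    params: GrowthParams
    sse: float
    samples: Optional[np.ndarray] = None  # (n_samples, 2) of (r, K) when MCMC


def _traj_sse(theta: np.ndarray, obs: np.ndarray, times: np.ndarray, N0: float, d: float) -> float:
    r, K = np.exp(theta)
    pred = logistic_trajectory(r, K, N0, d, times)
    return float(np.sum((pred - obs) ** 2))


def calibrate(
    observed: Sequence[float],
    init: GrowthParams,
    method: str = "nelder_mead",
    seed: int = 0,
) -> CalibrationResult:
    """Fit (r, K) of the deterministic growth law to an observed trajectory.

    Minimizes the sum of squared errors between the closed-form
    logistic-minus-death curve (death rate held at ``init.d``) and the
    observations, assumed sampled at steps 0, dt, 2·dt, …  Two methods:

    * ``nelder_mead`` — derivative-free simplex search in (log r, log K);
    * ``mcmc`` — affine-invariant ensemble sampling under a Gaussian error
      model; the returned parameters are posterior medians and ``samples``
      holds the flattened post-burn-in chain in (r, K).
    """
    from scipy.optimize import minimize

    obs = np.asarray(observed, dtype=float)
    if obs.size < 3:
        raise ValueError("calibration needs at least 3 observations")
    times = np.arange(obs.size) * init.dt
    N0 = float(obs[0])
    x0 = np.log([max(init.r, 1e-6), max(init.K, 1e-6)])

    if method == "nelder_mead":
        best = None
        for start in (x0, x0 + np.array([0.5, 0.5]), x0 - np.array([0.5, 0.5])):
            res = minimize(
                _traj_sse,
                start,
                args=(obs, times, N0, init.d),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        r, K = np.exp(best.x)
        return CalibrationResult(GrowthParams(r, K, init.d, init.dt), float(best.fun))

    if method == "mcmc":
        import emcee

        sigma = 0.01 * max(obs.max(), 1.0)

        def log_prob(theta):
            if np.any(np.abs(theta - x0) > 8.0):  # broad log-uniform prior box
                return -np.inf
            return -_traj_sse(theta, obs, times, N0, init.d) / (2.0 * sigma**2)

        nwalkers, ndim = 16, 2
        rng = np.random.default_rng(seed)
        p0 = x0 + 1e-3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
        state = sampler.run_mcmc(p0, 600, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=250, flat=True)
        samples = np.exp(chain)
        r, K = np.median(samples, axis=0)
        sse = _traj_sse(np.log([r, K]), obs, times, N0, init.d)
        return CalibrationResult(GrowthParams(r, K, init.d, init.dt), sse, samples)

    raise ValueError("method must be 'nelder_mead' or 'mcmc'")


# --------------------------------------------------------------------------
# YAML config IO
# --------------------------------------------------------------------------


def save_sim_config(config: SimulationConfig, path) -> None:
    doc = dataclasses.asdict(config)
    doc["genes"] = {"gene_indices": list(config.genes.gene_indices), "W": list(config.genes.W)}
    doc["grid_shape"] = list(config.grid_shape)
    doc["initial_expression"] = list(config.initial_expression)
    doc["knockout_genes"] = list(config.knockout_genes)
    if callable(config.expr.production):
        raise ValueError("cannot serialize a callable production term")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_sim_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    doc["genes"] = GrowthGeneSet(tuple(doc["genes"]["gene_indices"]), tuple(doc["genes"]["W"]))
    doc["growth"] = GrowthParams(**doc["growth"])
    doc["expr"] = ExpressionDynParams(**doc["expr"])
    doc["grid_shape"] = tuple(doc["grid_shape"])
    doc["initial_expression"] = tuple(doc["initial_expression"])
    doc["knockout_genes"] = tuple(doc["knockout_genes"])
    return SimulationConfig(**doc)
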