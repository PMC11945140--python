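"""Staged genetic-algorithm calibration of the module parameters.

Calibration proceeds in three sequential stages mirroring the model's
structure: (1) the protein parameters (npf0, delta) against observed grain
protein accumulation; (2) the starch kinetic parameters (igsa0, istr_m, km,
gdd_m, gamma) against observed grain starch accumulation; (3) with the
starch stage fixed, the partition parameters (alpha, beta) against observed
amylose and amylopectin accumulation jointly.  Each stage minimizes an RMSE
objective with a real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation, elitism), optionally followed by a bounded
least-squares refinement of the best candidates — the usual memetic hybrid,
which recovers noiseless synthetic truths to machine precision where the GA
alone stalls at the scale of its mutation kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .crop_state import CropStateSeries
from .protein import ProteinParams
from .starch import PartitionParams, StarchParams, simulate_starch
from .stress import nitrogen_stress, water_stress
from .synthetic import ObservationSet

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "Bounds", "CalibrationResult", "ga_minimize",
           "calibrate_protein", "calibrate_starch", "calibrate_partition"]

#: Penalty returned for structurally infeasible candidates (e.g. a
#: remobilization onset at or beyond maturity).
_PENALTY = 1e9


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (conventional defaults)."""

    population_size: int = 50
    generations: int = 100
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sigma_fraction: float = 0.05
    elitism: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")


@dataclass(frozen=True)
class Bounds:
    """Per-parameter box constraints."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "Bounds":
        names = tuple(d)
        lower = np.array([d[k][0] for k in names], dtype=float)
        upper = np.array([d[k][1] for k in names], dtype=float)
        if np.any(lower >= upper):
            bad = [n for n, lo, hi in zip(names, lower, upper) if lo >= hi]
            raise ValueError(f"lower must be < upper for {bad}")
        return cls(names=names, lower=lower, upper=upper)

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class CalibrationResult:
    """Outcome of one calibration stage.

    ``history`` is the best objective seen up to each generation (hence
    nonincreasing); ``evaluations`` counts objective calls; ``notes``
    records degeneracy or at-bound warnings.
    """

    best_params: dict[str, float]
    best_objective: float
    history: list[float]
    evaluations: int
    notes: list[str] = field(default_factory=list)
    final_population: np.ndarray | None = None
    final_fitness: np.ndarray | None = None


def ga_minimize(objective, bounds: Bounds, cfg: GAConfig = GAConfig()
                ) -> CalibrationResult:
    """Minimize a nonnegative objective over a box with a real-coded GA.

    Tournament selection, blend (BLX-0.5) crossover, per-gene Gaussian
    mutation with sigma proportional to the bound range, and elitism.
    Every evaluated candidate lies within bounds; identical seeds give
    identical results.
    """
    rng = np.random.default_rng(cfg.seed)
    dim = len(bounds.names)
    evaluations = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        val = float(objective(x))
        if not np.isfinite(val):
            raise ValueError(
                f"objective returned non-finite value {val} at candidate "
                f"{dict(zip(bounds.names, x))}")
        return val

    pop = bounds.lower + rng.random((cfg.population_size, dim)) * bounds.span
    fitness = np.array([evaluate(x) for x in pop])

    best_idx = int(np.argmin(fitness))
    best_x = pop[best_idx].copy()
    best_f = float(fitness[best_idx])
    history = [best_f]

    sigma = cfg.mutation_sigma_fraction * bounds.span

    def tournament() -> np.ndarray:
        idx = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
        return pop[idx[np.argmin(fitness[idx])]]

    for _ in range(cfg.generations):
        order = np.argsort(fitness)
        elite = pop[order[:cfg.elitism]].copy()
        elite_f = fitness[order[:cfg.elitism]].copy()

        n_off = cfg.population_size - cfg.elitism
        offspring = np.empty((n_off, dim))
        for j in range(0, n_off, 2):
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                # BLX-0.5: sample uniformly in the parent interval extended
                # by half its width on each side
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                width = hi - lo
                c1 = rng.uniform(lo - 0.5 * width, hi + 0.5 * width)
                c2 = rng.uniform(lo - 0.5 * width, hi + 0.5 * width)
            else:
                c1, c2 = p1.copy(), p2.copy()
            offspring[j] = c1
            if j + 1 < n_off:
                offspring[j + 1] = c2

        mutate = rng.random(offspring.shape) < cfg.mutation_rate
        offspring = offspring + mutate * rng.normal(0.0, 1.0, offspring.shape) * sigma
        offspring = bounds.clip(offspring)

        off_fitness = np.array([evaluate(x) for x in offspring])
        pop = np.vstack([elite, offspring])
        fitness = np.concatenate([elite_f, off_fitness])

        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_f = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        history.append(best_f)

    return CalibrationResult(
        best_params=dict(zip(bounds.names, best_x.astype(float))),
        best_objective=best_f, history=history, evaluations=evaluations,
        final_population=pop, final_fitness=fitness,
    )


def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _obs_positions(series: CropStateSeries, obs: ObservationSet) -> np.ndarray:
    day_to_pos = {int(d): i for i, d in
                  enumerate(series.frame["day_index"].to_numpy())}
    missing = [int(d) for d in obs.days() if int(d) not in day_to_pos]
    if missing:
        raise ValueError(f"observation days {missing} absent from the series")
    return np.array([day_to_pos[int(d)] for d in obs.days()], dtype=int)


def _flag_at_bounds(result: CalibrationResult, bounds: Bounds) -> None:
    x = np.array([result.best_params[n] for n in bounds.names])
    rel = np.minimum(x - bounds.lower, bounds.upper - x) / bounds.span
    for name, r in zip(bounds.names, rel):
        if r < 1e-3:
            msg = (f"parameter '{name}' calibrated at or near its bound; "
                   f"the bounds may exclude the optimum")
            logger.warning(msg)
            result.notes.append(msg)


def _polish(result: CalibrationResult, bounds: Bounds, residual_fn,
            objective_fn, n_starts: int = 3) -> None:
    """Refine the best GA candidates with bounded least squares (in place)."""
    starts = [np.array([result.best_params[n] for n in bounds.names])]
    if result.final_population is not None:
        order = np.argsort(result.final_fitness)
        for i in order[:n_starts]:
            cand = result.final_population[i]
            if all(np.max(np.abs(cand - s) / bounds.span) > 1e-6
                   for s in starts):
                starts.append(cand.copy())
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, x0,
                                bounds=(bounds.lower, bounds.upper),
                                method="trf", xtol=1e-15, ftol=1e-15,
                                gtol=1e-15)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("least-squares polish failed from %s: %s", x0, exc)
            continue
        val = float(objective_fn(sol.x))
        result.evaluations += int(sol.nfev)
        if val < result.best_objective:
            result.best_objective = val
            result.best_params = dict(zip(bounds.names, sol.x.astype(float)))
    result.history.append(result.best_objective)


DEFAULT_PROTEIN_BOUNDS = Bounds.from_dict({"npf0": (5.0, 6.5),
                                           "delta": (0.0, 1.0)})
DEFAULT_STARCH_BOUNDS = Bounds.from_dict({
    "igsa0": (0.0, 0.5), "istr_m": (0.1, 5.0), "km": (0.05, 5.0),
    "gdd_m": (50.0, 600.0), "gamma": (1e-6, 0.01),
})
DEFAULT_PARTITION_BOUNDS = Bounds.from_dict({"alpha": (0.0, 2.0),
                                             "beta": (0.0, 5.0)})


def calibrate_protein(
    series: CropStateSeries,
    obs: ObservationSet,
    bounds: Bounds = DEFAULT_PROTEIN_BOUNDS,
    cfg: GAConfig = GAConfig(),
    polish: bool = True,
) -> tuple[ProteinParams, CalibrationResult]:
    """Fit (npf0, delta) by minimizing the RMSE of simulated vs observed
    grain protein accumulation at the sampled days."""
    pos = _obs_positions(series, obs)
    fw = water_stress(series.col("ta"), series.col("tp"))
    fn = nitrogen_stress(series.col("anp"), series.col("cnp"),
                         series.col("mnp"))
    minwf = np.minimum(fw, fn)[pos]
    gna = series.col("gna")[pos]
    target = obs.values()
    i_npf0 = bounds.names.index("npf0")
    i_delta = bounds.names.index("delta")

    def residuals(x: np.ndarray) -> np.ndarray:
        return gna * (x[i_delta] * minwf + x[i_npf0]) - target

    def objective(x: np.ndarray) -> float:
        return float(np.sqrt(np.mean(residuals(x) ** 2)))

    result = ga_minimize(objective, bounds, cfg)
    if polish:
        _polish(result, bounds, residuals, objective)
    _flag_at_bounds(result, bounds)
    params = ProteinParams(npf0=result.best_params["npf0"],
                           delta=result.best_params["delta"])
    return params, result


def calibrate_starch(
    series: CropStateSeries,
    obs: ObservationSet,
    bounds: Bounds = DEFAULT_STARCH_BOUNDS,
    cfg: GAConfig = GAConfig(),
    polish: bool = True,
    base_params: StarchParams = StarchParams(),
) -> tuple[StarchParams, CalibrationResult]:
    """Fit the five starch kinetic parameters by minimizing the RMSE of
    simulated vs observed canopy starch accumulation.

    Cardinal temperatures are kept at ``base_params`` values (they are
    model constants, not calibrated).  Candidates whose remobilization
    onset reaches the maturity thermal time are structurally infeasible
    and receive a large finite penalty.
    """
    pos = _obs_positions(series, obs)
    target = obs.values()
    gdd = series.col("gdd")
    topwt = series.col("topwt")
    vwt = series.col("vwt")
    dtop = np.diff(topwt)
    dvwt = np.diff(vwt)
    fw = water_stress(series.col("ta"), series.col("tp"))
    fn = nitrogen_stress(series.col("anp"), series.col("cnp"),
                         series.col("mnp"))
    from .starch import temperature_factor
    f_t = temperature_factor(series.col("tavg"), base_params)
    env = f_t * fw * fn
    grains = series.sp * series.ng
    gdd_am = series.gdd_am
    n = len(series)
    idx = {name: bounds.names.index(name) for name in
           ("igsa0", "istr_m", "km", "gdd_m", "gamma")}

    def predict(x: np.ndarray) -> np.ndarray | None:
        gdd_m = x[idx["gdd_m"]]
        if gdd_m >= gdd_am:
            return None
        gamma = x[idx["gamma"]]
        post = gdd[1:] >= gdd_m
        gcp = np.maximum(0.0, np.where(post, dtop, dtop - dvwt))
        gct = np.maximum(0.0, np.where(post, -dvwt, 0.0))
        gca = np.zeros(n)
        gca[1:] = 1e6 * (gcp + gct) / grains
        rising = (gdd / gdd_m) * np.exp(gamma * (gdd_m - gdd))
        falling = (gdd_am - gdd) / (gdd_am - gdd_m)
        f_gdd = np.clip(np.where(gdd <= gdd_m, rising, falling), 0.0, 1.0)
        eact = f_gdd * env
        istr = x[idx["istr_m"]] * eact * gca / (x[idx["km"]] + gca)
        if base_params.cap_rate_to_supply:
            istr = np.minimum(istr, gca)
        istr[0] = 0.0
        igsa = x[idx["igsa0"]] + np.cumsum(istr)
        return grains * igsa[pos] * 1e-6

    def residuals(x: np.ndarray) -> np.ndarray:
        pred = predict(x)
        if pred is None:
            return np.full(target.shape, _PENALTY)
        return pred - target

    def objective(x: np.ndarray) -> float:
        pred = predict(x)
        if pred is None:
            return _PENALTY
        return _rmse(pred, target)

    result = ga_minimize(objective, bounds, cfg)
    if polish:
        # The objective is discontinuous in gdd_m wherever it crosses a
        # day's accumulated thermal time (the day classification flips), so
        # a single local refinement can stall on a bin edge.  Between
        # consecutive daily gdd values it is smooth; refine within each such
        # bin and keep the best.
        i_gddm = idx["gdd_m"]
        lo_b, hi_b = bounds.lower[i_gddm], min(bounds.upper[i_gddm],
                                               gdd_am * (1 - 1e-12))
        interior = np.unique(gdd)
        interior = interior[(interior > lo_b) & (interior < hi_b)]
        edges = np.concatenate([[lo_b], interior, [hi_b]])
        x0 = np.array([result.best_params[name] for name in bounds.names])
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi - lo < 1e-9:
                continue
            margin = 1e-6 * (hi - lo)
            sub_lower = bounds.lower.copy()
            sub_upper = bounds.upper.copy()
            sub_lower[i_gddm] = lo + margin
            sub_upper[i_gddm] = hi - margin
            start = np.clip(x0, sub_lower, sub_upper)
            try:
                sol = least_squares(residuals, start,
                                    bounds=(sub_lower, sub_upper),
                                    method="trf", xtol=1e-15, ftol=1e-15,
                                    gtol=1e-15)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("starch polish failed in bin (%g, %g): %s",
                               lo, hi, exc)
                continue
            val = objective(sol.x)
            result.evaluations += int(sol.nfev)
            if val < result.best_objective:
                result.best_objective = val
                result.best_params = dict(zip(bounds.names,
                                              sol.x.astype(float)))
        result.history.append(result.best_objective)
    _flag_at_bounds(result, bounds)
    params = StarchParams(
        igsa0=result.best_params["igsa0"],
        istr_m=result.best_params["istr_m"],
        km=result.best_params["km"],
        gdd_m=result.best_params["gdd_m"],
        gamma=result.best_params["gamma"],
        tb=base_params.tb, tol=base_params.tol, toh=base_params.toh,
        tm=base_params.tm,
        cap_rate_to_supply=base_params.cap_rate_to_supply,
    )
    return params, result


def calibrate_partition(
    series: CropStateSeries,
    obs_gasa: ObservationSet,
    obs_gapa: ObservationSet,
    starch_params: StarchParams,
    bounds: Bounds = DEFAULT_PARTITION_BOUNDS,
    cfg: GAConfig = GAConfig(),
    polish: bool = True,
) -> tuple[PartitionParams, CalibrationResult]:
    """Fit (alpha, beta) by minimizing the summed RMSE of amylose and
    amylopectin accumulation, with the starch stage held fixed.

    When nitrogen stress annihilates the amylose ratio on every observed
    day the two parameters are unidentifiable; the result is returned with
    a degeneracy note.
    """
    qs = simulate_starch(series, starch_params)
    gsa = qs.col("gsa")
    fn = qs.col("fn")
    gdd = qs.col("gdd")
    pos_a = _obs_positions(series, obs_gasa)
    pos_p = _obs_positions(series, obs_gapa)
    tgt_a = obs_gasa.values()
    tgt_p = obs_gapa.values()
    i_alpha = bounds.names.index("alpha")
    i_beta = bounds.names.index("beta")
    loggdd = np.where(gdd > 0, np.log(np.where(gdd > 0, gdd, 1.0)), 0.0)

    def ra_of(x: np.ndarray) -> np.ndarray:
        raw = np.where(gdd > 0, (x[i_alpha] * loggdd - x[i_beta]) * fn, 0.0)
        return np.clip(raw, 0.0, 1.0)

    def residuals(x: np.ndarray) -> np.ndarray:
        ra = ra_of(x)
        return np.concatenate([(gsa * ra)[pos_a] - tgt_a,
                               (gsa * (1.0 - ra))[pos_p] - tgt_p])

    def objective(x: np.ndarray) -> float:
        ra = ra_of(x)
        return (_rmse((gsa * ra)[pos_a], tgt_a)
                + _rmse((gsa * (1.0 - ra))[pos_p], tgt_p))

    result = ga_minimize(objective, bounds, cfg)
    if polish:
        _polish(result, bounds, residuals, objective)
    _flag_at_bounds(result, bounds)
    if np.max(fn[pos_a] * (gdd[pos_a] > 0)) == 0:
        msg = ("amylose ratio is identically zero on every observed day "
               "(nitrogen stress annihilation); alpha and beta are "
               "unidentifiable")
        logger.warning(msg)
        result.notes.append(msg)
    params = PartitionParams(alpha=result.best_params["alpha"],
                             beta=result.best_params["beta"])
    return params, result
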