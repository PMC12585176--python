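"""Estimation of the temporal constants by multi-start bounded search.

The three time constants (tau_bpV, tau_bpA, tau_lp) are fitted to a corpus
of lag-manipulation experiments by minimizing either 1 minus the Pearson
correlation between observed and model psychometric curves (averaged over
experiments with equal weights) or their mean squared error.  At every
candidate tau the three decision parameters of each experiment are refitted
by the probit GLM (a convex inner problem needing no initialization), so the
search runs over the temporal constants only.

The global stage draws log-uniform starting points within the bounds
(default 1 ms - 1.5 s) and runs a bounded derivative-free simplex search in
log-tau space from each; the best start is then refined locally with
tighter tolerances.  Reports are fully reproducible from (seed, inputs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .params import MCDParams
from .temporal import TemporalExperiment, fit_decision_params, lag_sweep_pairs

__all__ = ["FitSpec", "FitReport", "pearson_cost", "mse_cost",
           "corpus_cost", "fit_temporal_constants"]


@dataclass(frozen=True)
class FitSpec:
    """Search configuration for the temporal-constant fit."""

    bounds: tuple[float, float] = (0.001, 1.5)
    cost: str = "one_minus_pearson"          # or "mse"
    n_starts: int = 200
    seed: int = 0
    tie_av: bool = False                     # tie tau_bpV = tau_bpA (rat fits)
    maxiter: int = 150
    grid_resolution: int = 5                 # coarse log-grid scan; 0 = off

    def __post_init__(self) -> None:
        if self.bounds[0] <= 0 or self.bounds[1] <= self.bounds[0]:
            raise ValueError("bounds must be positive and increasing")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.cost not in ("one_minus_pearson", "mse"):
            raise ValueError(f"unknown cost {self.cost!r}")


@dataclass
class FitReport:
    """Multi-start fit outcome: best parameters plus per-start trajectories."""

    params: MCDParams
    best_cost: float
    cost_name: str
    starts: list = field(default_factory=list)   # (start_taus, final_taus, cost)
    n_discarded: int = 0
    alt_cost: float | None = None                # best taus under the other cost

    def to_dict(self) -> dict:
        return {
            "tau_bpv": self.params.tau_bpv,
            "tau_bpa": self.params.tau_bpa,
            "tau_lp": self.params.tau_lp,
            "best_cost": self.best_cost,
            "cost": self.cost_name,
            "alt_cost": self.alt_cost,
            "n_discarded": self.n_discarded,
            "starts": [{"start": list(s), "final": list(f), "cost": c}
                       for s, f, c in self.starts],
        }


def pearson_cost(model_curves, observed_curves) -> float:
    """Mean over experiments of 1 - Pearson r (equal weights).

    Affine rescaling of the model curves leaves the cost unchanged; a
    zero-variance curve is an error.
    """
    costs = []
    for m, o in zip(model_curves, observed_curves):
        m, o = np.asarray(m, float), np.asarray(o, float)
        if len(m) != len(o) or len(m) < 3:
            raise ValueError("curves must be matched with >= 3 points")
        if np.std(m) == 0 or np.std(o) == 0:
            raise ValueError("zero-variance curve: Pearson cost undefined")
        costs.append(1.0 - pearsonr(m, o)[0])
    return float(np.mean(costs))


def mse_cost(model_curves, observed_curves) -> float:
    """Mean over experiments of the per-experiment mean squared error."""
    return float(np.mean([np.mean((np.asarray(m) - np.asarray(o)) ** 2)
                          for m, o in zip(model_curves, observed_curves)]))


def _model_curves(experiments, params: MCDParams):
    curves = []
    for exp in experiments:
        X, Y = lag_sweep_pairs(exp.pairs, params)
        fit = fit_decision_params(X, Y, exp.n_resp, exp.n_trials)
        curves.append(fit.predict(X, Y))
    return curves


def corpus_cost(experiments, taus, cost: str = "one_minus_pearson",
                template: MCDParams | None = None) -> float:
    """Cost of temporal constants ``taus = (bpV, bpA, lp)`` on a corpus."""
    from .params import HUMAN

    template = template or HUMAN
    params = template.with_taus(*taus)
    curves = _model_curves(experiments, params)
    observed = [e.p_obs for e in experiments]
    fn = pearson_cost if cost == "one_minus_pearson" else mse_cost
    return fn(curves, observed)


def fit_temporal_constants(experiments: "list[TemporalExperiment]",
                           spec: FitSpec = FitSpec(),
                           starts: "np.ndarray | None" = None) -> FitReport:
    """Multi-start estimate of (tau_bpV, tau_bpA, tau_lp) from a corpus.

    ``starts`` may supply explicit starting tau triplets; otherwise
    ``spec.n_starts`` points are drawn log-uniformly within the bounds.
    Candidates with non-finite cost are discarded and counted.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = np.log(spec.bounds[0]), np.log(spec.bounds[1])
    ndim = 2 if spec.tie_av else 3

    def unpack(z):
        taus = np.exp(z)
        if spec.tie_av:
            return (taus[0], taus[0], taus[1])
        return tuple(taus)

    def objective(z):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = corpus_cost(experiments, unpack(z), cost=spec.cost)
        except Exception:
            return np.inf
        return c if np.isfinite(c) else np.inf

    if starts is None:
        # redraw infeasible points (e.g. tau too short for the corpus rate)
        # so every requested start actually searches
        start_z = []
        n_discarded = 0
        for _ in range(spec.n_starts):
            for _ in range(50):
                z = rng.uniform(lo, hi, size=ndim)
                if np.isfinite(objective(z)):
                    start_z.append(z)
                    break
                n_discarded += 1
    else:
        starts = np.asarray(starts, float)
        if spec.tie_av:
            starts = np.column_stack([starts[:, 0], starts[:, -1]])
        start_z = list(np.log(starts))
        n_discarded = 0

    if spec.grid_resolution:
        # deterministic coarse scan of the log-tau box; its best cell seeds
        # one extra local search (the landscape is multimodal)
        axis = np.linspace(lo, hi, spec.grid_resolution)
        grid = np.stack(np.meshgrid(*([axis] * ndim),
                                    indexing="ij"), axis=-1).reshape(-1, ndim)
        costs = np.array([objective(z) for z in grid])
        if np.isfinite(costs).any():
            start_z.append(grid[int(np.nanargmin(
                np.where(np.isfinite(costs), costs, np.nan)))])

    report_starts = []
    best = None
    for z0 in start_z:
        if not np.isfinite(objective(z0)):
            n_discarded += 1
            continue
        res = minimize(objective, z0, method="Nelder-Mead",
                       bounds=[(lo, hi)] * ndim,
                       options={"maxiter": spec.maxiter, "xatol": 1e-3,
                                "fatol": 1e-5})
        report_starts.append((unpack(z0), unpack(res.x), float(res.fun)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("every starting point produced a non-finite cost")

    refined = minimize(objective, best.x, method="Nelder-Mead",
                       bounds=[(lo, hi)] * ndim,
                       options={"maxiter": 4 * spec.maxiter, "xatol": 1e-4,
                                "fatol": 1e-7})
    final = refined if refined.fun <= best.fun else best
    taus = unpack(final.x)
    other = "mse" if spec.cost == "one_minus_pearson" else "one_minus_pearson"
    try:
        alt = corpus_cost(experiments, taus, cost=other)
    except Exception:
        alt = None
    from .params import HUMAN

    return FitReport(params=HUMAN.with_taus(*taus), best_cost=float(final.fun),
                     cost_name=spec.cost, starts=report_starts,
                     n_discarded=n_discarded, alt_cost=alt)
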