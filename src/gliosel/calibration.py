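"""Bounded Levenberg-Marquardt calibration of one variant to noisy scans.

The observable is the pair of normalized density fields at the imaging
days. Calibration is initialized from the measured (noisy) baseline
scan and the midpoint of the parameter bounds, and minimizes the
residual sum of squares over both species, all brain-mask voxels and
the three during-treatment imaging days (weeks 1-3 of RT); the
post-treatment scan is held out for prediction assessment. The damped
Gauss-Newton iteration uses a forward finite-difference Jacobian,
increases the damping on rejected steps and relaxes it on accepted
ones, clamps parameters to their bounds, and stops at 250 iterations or
when the relative parameter change drops below 0.01 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .forward import SimulationWorkspace, SolverConfig, TumourState, simulate
from .params import ParameterBounds, ParameterSet
from .variants import get_variant


@dataclass
class Observations:
    """Noisy imaging series for one tumour.

    ``fields`` maps day -> ``TumourState``; the final (post-RT) day never
    enters the calibration residual.
    """

    days: tuple
    fields: dict
    noise_level: float = 0.0
    calibration_days: tuple = None
    prediction_day: int = None

    def __post_init__(self):
        days = tuple(int(d) for d in self.days)
        if self.calibration_days is None:
            self.calibration_days = days[1:-1]
        if self.prediction_day is None:
            self.prediction_day = days[-1]
        self.days = days

    @property
    def baseline(self) -> TumourState:
        return self.fields[self.days[0]]

    @classmethod
    def from_states(cls, states, noise_level=0.0) -> "Observations":
        days = tuple(int(s.day) for s in states)
        return cls(days=days, fields={int(s.day): s for s in states}, noise_level=noise_level)


@dataclass(frozen=True)
class CalibrationConfig:
    max_iterations: int = 250
    param_change_tol: float = 1e-4      # 0.01 % relative change
    jacobian_step: float = 1e-3         # relative finite-difference step
    central_differences: bool = False
    fit_combined_density: bool = False  # residual on N_E + N_N instead of stacked species
    mu0: float = 1e-3
    mu_increase: float = 2.0
    mu_decrease: float = 10.0
    mu_max: float = 1e14

    def __post_init__(self):
        if self.max_iterations < 1 or self.param_change_tol <= 0 or self.jacobian_step <= 0:
            raise ValueError("tolerances and iteration cap must be positive")


@dataclass
class CalibrationResult:
    variant_id: str
    params_hat: ParameterSet
    rss: float
    n_points: int
    k: int
    iterations: int
    converged: bool
    termination: str
    n_simulations: int = 0
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_id,
            "params": self.params_hat.to_dict(),
            "rss": self.rss,
            "n_points": self.n_points,
            "k": self.k,
            "iterations": self.iterations,
            "converged": self.converged,
            "termination": self.termination,
        }


def profile_log_likelihood(rss: float, n_points: int) -> float:
    """Gaussian log-likelihood profiled over the noise variance.

    At the MLE ``sigma^2 = RSS/n`` the log-likelihood reduces to
    ``-(n/2) ln(2 pi RSS/n) - n/2``; strictly decreasing in RSS. A zero
    RSS returns ``+inf`` as a documented sentinel (perfect fit).
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        return math.inf
    s2 = rss / n_points
    return -0.5 * n_points * math.log(2.0 * math.pi * s2) - 0.5 * n_points


class ResidualModel:
    """Callable residual vector (observations - simulation) for one tumour."""

    def __init__(
        self,
        variant,
        anatomy,
        schedule,
        observations: Observations,
        constants: ModelConstants = DEFAULT_CONSTANTS,
        solver: SolverConfig = SolverConfig(),
        workspace: SimulationWorkspace | None = None,
        combined_density: bool = False,
    ):
        self.variant = get_variant(variant)
        self.anatomy = anatomy
        self.schedule = schedule
        self.obs = observations
        self.constants = constants
        self.solver = solver
        self.workspace = workspace or SimulationWorkspace(anatomy, constants)
        self.combined = combined_density
        grid = anatomy.grid
        self.sim_days = (self.obs.days[0],) + tuple(self.obs.calibration_days)
        target = []
        for day in self.obs.calibration_days:
            st = self.obs.fields[day]
            if combined_density:
                target.append(grid.flatten(st.N_E) + grid.flatten(st.N_N))
            else:
                target.append(grid.flatten(st.N_E))
                target.append(grid.flatten(st.N_N))
        self.target = np.concatenate(target)
        self.n_points = self.target.size
        self.n_simulations = 0

    def __call__(self, params: ParameterSet) -> np.ndarray:
        out = simulate(
            self.variant, params, self.anatomy, self.schedule, self.sim_days,
            constants=self.constants, config=self.solver,
            initial_state=self.obs.baseline, workspace=self.workspace,
        )
        self.n_simulations += 1
        grid = self.anatomy.grid
        model = []
        for st in out.states[1:]:
            if self.combined:
                model.append(grid.flatten(st.N_E) + grid.flatten(st.N_N))
            else:
                model.append(grid.flatten(st.N_E))
                model.append(grid.flatten(st.N_N))
        return self.target - np.concatenate(model)


def residual_vector(
    variant,
    params: ParameterSet,
    anatomy,
    schedule,
    observations: Observations,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: SolverConfig = SolverConfig(),
    workspace=None,
) -> np.ndarray:
    """Stacked residuals (Y - model) over both species, mask voxels and
    the during-treatment imaging days; length ``2 * |mask| * 3``."""
    model = ResidualModel(
        variant, anatomy, schedule, observations, constants, solver, workspace
    )
    return model(params)


def levenberg_marquardt(
    variant,
    anatomy,
    schedule,
    observations: Observations,
    bounds: ParameterBounds | None = None,
    config: CalibrationConfig = CalibrationConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: SolverConfig = SolverConfig(),
    workspace=None,
    x0: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit the variant's free parameters by damped Gauss-Newton.

    Parameters are scaled to the unit box defined by their bounds;
    iterates are clamped to the box after every accepted step, so the
    returned parameters always respect the bounds.
    """
    variant = get_variant(variant)
    bounds = bounds or ParameterBounds()
    names = variant.free_params
    lo = bounds.lower(names)
    hi = bounds.upper(names)
    span = hi - lo
    base = ParameterSet(**variant.fixed_params)

    def unscale(x):
        return base.with_values(names, lo + span * x)

    model = ResidualModel(
        variant, anatomy, schedule, observations, constants, solver, workspace,
        combined_density=config.fit_combined_density,
    )

    k = len(names)
    x = np.full(k, 0.5) if x0 is None else np.clip(np.asarray(x0, float), 0.0, 1.0)
    r = model(unscale(x))
    rss = float(r @ r)
    mu = config.mu0
    trace = [(0, rss, mu)]
    converged = False
    termination = "max_iterations"
    h = config.jacobian_step
    iterations = 0

    for iterations in range(1, config.max_iterations + 1):
        if rss == 0.0:  # perfect fit: nothing left to minimize
            converged = True
            termination = "zero_rss"
            break
        jac = np.empty((r.size, k))
        for j in range(k):
            step = h if x[j] + h <= 1.0 else -h
            xp = x.copy()
            xp[j] += step
            rp = model(unscale(xp))
            if config.central_differences:
                xm = x.copy()
                xm[j] -= step
                np.clip(xm, 0.0, 1.0, out=xm)
                rm = model(unscale(xm))
                jac[:, j] = (rp - rm) / (xp[j] - xm[j])
            else:
                jac[:, j] = (rp - r) / step
        jtj = jac.T @ jac
        jtr = jac.T @ r
        diag = np.diag(jtj).copy()
        floor = max(diag.max(), 1e-300) * 1e-12
        diag = np.maximum(diag, floor)

        accepted = False
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(jtj + mu * np.diag(diag), -jtr)
            except np.linalg.LinAlgError:
                mu *= config.mu_increase
                continue
            x_new = np.clip(x + delta, 0.0, 1.0)
            r_new = model(unscale(x_new))
            rss_new = float(r_new @ r_new)
            if np.isfinite(rss_new) and rss_new < rss:
                p_old = lo + span * x
                p_new = lo + span * x_new
                rel_change = np.max(
                    np.abs(p_new - p_old) / np.maximum(np.abs(p_old), 1e-12)
                )
                x, r, rss = x_new, r_new, rss_new
                mu = max(mu / config.mu_decrease, 1e-12)
                accepted = True
                trace.append((iterations, rss, mu))
                if rel_change < config.param_change_tol:
                    converged = True
                    termination = "parameter_change_below_tolerance"
                break
            mu *= config.mu_increase
        if not accepted:
            termination = "damping_overflow"
            break
        if converged:
            break

    return CalibrationResult(
        variant_id=variant.id,
        params_hat=unscale(x),
        rss=rss,
        n_points=model.n_points,
        k=variant.n_params,
        iterations=iterations,
        converged=converged,
        termination=termination,
        n_simulations=model.n_simulations,
        trace=trace,
    )
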