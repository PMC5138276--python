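"""Parameter calibration against temperature recordings, and the human
extrapolation.

The published parameter table pins only part of the model; the
least-constrained quantities (collar contact conductances, environment
couplings) are fitted here by bounded least squares against either the
cohort's four summary statistics (two baselines, two cooling rates) or
the full cooling-hour traces.  A multi-start strategy guards against
local minima.  The fitted device-side values can then be carried into
the human anatomical catalog to predict human cooling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .params import ParameterSet, build_collar, build_network
from .simulate import SimulationProtocol, TemperatureTrace, cooling_rate, run_protocol
from .stats import moving_average

__all__ = [
    "FreeParameter",
    "CalibrationSpec",
    "CalibrationResult",
    "calibrate",
    "extrapolate_human",
    "simulate_summary",
]

OBJECTIVES = ("match_rates_and_baselines", "sse_on_traces")

#: device-spec keys carried from a fitted sheep set into the human set
DEVICE_CARRY_KEYS = (
    "collar.source_power_W",
    "collar.efficiency",
    "collar.n_elements",
    "collar.skin_floor_C",
    "collar.guard_band_C",
    "collar.element_mode",
)
COUPLING_CARRY_KEYS = (
    "collar.g_elem_neck_W_C",
    "collar.g_elem_env_W_C",
    "collar.g_elem_elem_W_C",
)


@dataclass(frozen=True)
class FreeParameter:
    """One fitted quantity: a dotted path into the parameter set plus bounds."""

    path: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.lower, self.upper]).all() or self.lower >= self.upper:
            raise ValueError(f"bounds for {self.path!r} must be finite and ordered")


@dataclass
class CalibrationSpec:
    free_parameters: list[FreeParameter]
    records: list
    objective: str = "match_rates_and_baselines"
    window_s: float = 60.0
    n_starts: int = 3
    seed: int = 0
    xtol: float = 1e-10
    ftol: float = 1e-10
    #: decimation step (s) for trace-based objectives
    trace_step_s: float = 60.0

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")


@dataclass
class CalibrationResult:
    params: ParameterSet
    objective_value: float
    residuals: np.ndarray
    free_values: dict[str, float]
    converged: bool
    n_starts: int
    start_costs: list[float] = field(default_factory=list)
    message: str = ""


def _apply(base: ParameterSet, free: Sequence[FreeParameter], theta: np.ndarray) -> ParameterSet:
    p = base
    for fp, v in zip(free, theta):
        p = p.with_value(fp.path, float(v))
    return p


def simulate_summary(params: ParameterSet, window_s: float = 60.0) -> dict[str, float]:
    """Steady-state baselines and cooling-hour rates for one parameter set."""
    net = build_network(params)
    collar = build_collar(params)
    protocol = SimulationProtocol(settling_duration_s=0.0)
    trace = run_protocol(net, collar, protocol)
    t_on = trace.phase_marks["cooling_on"]
    t_off = trace.phase_marks["cooling_off"]
    return {
        "baseline_brain_C": float(trace.series("head")[0]),
        "baseline_body_C": float(trace.series("body")[0]),
        "rate_brain_C_per_h": cooling_rate(trace, "head", t_on, t_off, window_s),
        "rate_body_C_per_h": cooling_rate(trace, "body", t_on, t_off, window_s),
        "element_T_C": float(trace.series("element_1")[-1]),
    }


def _record_targets(records, window_s: float) -> dict[str, float]:
    from .stats import summarize_cohort

    rep = summarize_cohort(records, window_s)
    return {
        "baseline_brain_C": rep.baseline_brain_mean_C,
        "baseline_body_C": rep.baseline_body_mean_C,
        "rate_brain_C_per_h": rep.rate_brain_mean_C_per_h,
        "rate_body_C_per_h": rep.rate_body_mean_C_per_h,
    }


def _residual_builder(spec: CalibrationSpec, base: ParameterSet):
    if spec.objective == "match_rates_and_baselines":
        targets = _record_targets(spec.records, spec.window_s)

        def residuals(theta: np.ndarray) -> np.ndarray:
            summary = simulate_summary(_apply(base, spec.free_parameters, theta),
                                       spec.window_s)
            return np.array([
                summary["baseline_brain_C"] - targets["baseline_brain_C"],
                summary["baseline_body_C"] - targets["baseline_body_C"],
                summary["rate_brain_C_per_h"] - targets["rate_brain_C_per_h"],
                summary["rate_body_C_per_h"] - targets["rate_body_C_per_h"],
            ])

        return residuals

    # sse_on_traces: cohort-mean brain/body series over the cooling hour
    rec_t = spec.records[0].time_s
    dt = float(np.median(np.diff(rec_t)))
    step = max(1, int(round(spec.trace_step_s / dt)))
    brain_mean = np.vstack([
        moving_average(r.brain_C, spec.window_s, dt) for r in spec.records
    ]).mean(axis=0)[::step]
    body_mean = np.vstack([
        moving_average(r.body_C, spec.window_s, dt) for r in spec.records
    ]).mean(axis=0)[::step]
    grid = rec_t[::step]

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _apply(base, spec.free_parameters, theta)
        net = build_network(p)
        collar = build_collar(p)
        trace = run_protocol(net, collar, SimulationProtocol(settling_duration_s=0.0))
        t_rel = trace.times - trace.phase_marks["cooling_on"]
        sim_brain = np.interp(grid, t_rel, moving_average(
            trace.series("head"), spec.window_s, 1.0))
        sim_body = np.interp(grid, t_rel, moving_average(
            trace.series("body"), spec.window_s, 1.0))
        return np.concatenate([sim_brain - brain_mean, sim_body - body_mean])

    return residuals


def calibrate(spec: CalibrationSpec, base: ParameterSet) -> CalibrationResult:
    """Bounded least-squares fit of the free parameters, multi-start.

    The first start is the base catalog value (clipped into bounds);
    further starts are drawn uniformly inside the bounds from the
    calibration seed.  The best accepted iterate is returned even when
    the optimizer reports non-convergence (flagged in the result).
    """
    residuals = _residual_builder(spec, base)
    free = spec.free_parameters
    if not free:
        r = residuals(np.empty(0))
        return CalibrationResult(
            params=base,
            objective_value=0.5 * float(np.sum(r**2)),
            residuals=r,
            free_values={},
            converged=True,
            n_starts=0,
            message="no free parameters; base misfit reported",
        )

    lo = np.array([fp.lower for fp in free])
    hi = np.array([fp.upper for fp in free])
    base_theta = np.clip([base.get(fp.path) for fp in free], lo, hi)
    rng = np.random.default_rng(spec.seed)
    starts = [base_theta] + [
        lo + rng.uniform(size=len(free)) * (hi - lo) for _ in range(spec.n_starts - 1)
    ]

    best = None
    start_costs = []
    for x0 in starts:
        try:
            fit = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=spec.xtol, ftol=spec.ftol, gtol=1e-12)
        except Exception as exc:  # simulator failure inside the objective
            start_costs.append(float("inf"))
            continue
        start_costs.append(float(fit.cost))
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise RuntimeError("every calibration start failed inside the simulator")

    fitted = _apply(base, free, best.x)
    return CalibrationResult(
        params=fitted,
        objective_value=float(best.cost),
        residuals=np.asarray(best.fun),
        free_values={fp.path: float(v) for fp, v in zip(free, best.x)},
        converged=bool(best.status > 0),
        n_starts=len(starts),
        start_costs=start_costs,
        message=str(best.message),
    )


def extrapolate_human(
    fitted_sheep: ParameterSet,
    human_anatomy: ParameterSet,
    carry_couplings: bool = False,
    protocol: SimulationProtocol | None = None,
) -> tuple[TemperatureTrace, dict[str, float]]:
    """Run the cooling protocol on the human catalog with the fitted device.

    The device spec (power, efficiency, element count, skin floor) is
    carried over from the sheep fit; the element–skin geometric
    conductances stay with the anatomy catalog unless
    ``carry_couplings`` is set, because the human neck geometry (both
    carotid and vertebral arteries reachable) differs from the sheep's.
    """
    human = human_anatomy
    keys = DEVICE_CARRY_KEYS + (COUPLING_CARRY_KEYS if carry_couplings else ())
    for key in keys:
        human = human.with_value(
            key, fitted_sheep.get(key),
            provenance=fitted_sheep.provenance.get(key, "calibrated"),
        )
    net = build_network(human)
    collar = build_collar(human)
    protocol = protocol or SimulationProtocol(settling_duration_s=0.0)
    trace = run_protocol(net, collar, protocol)
    t_on = trace.phase_marks["cooling_on"]
    t_off = trace.phase_marks["cooling_off"]
    rates = {
        "rate_brain_C_per_h": cooling_rate(trace, "head", t_on, t_off),
        "rate_body_C_per_h": cooling_rate(trace, "body", t_on, t_off),
        "baseline_brain_C": float(trace.series("head")[0]),
        "baseline_body_C": float(trace.series("body")[0]),
    }
    return trace, rates
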