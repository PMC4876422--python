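"""Inverse calibration of the saturated conductivity sigmaMax.

The calibration protocol has two regimes.  In Run1, sigmaMax is optimised
independently for each pulse sequence by minimising avg dI — the mean
absolute difference between the measured and simulated electrode current —
while every other parameter stays fixed.  In Run2, the mean of the Run1
optima is frozen and shared across all sequences, and the metrics are merely
re-evaluated; restricting the parameter space this way can only keep or
worsen the fitted objective.

The objective is smooth and scalar, so a bounded Brent search (tolerance
1e-4 S/m) is used.  The default bounds are the plausible range of the
saturated conductivity for liver tissue, (0.125, 0.1675) S/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .fem_engine import SolverControls, run_simulation
from .mesh_geometry import Mesh
from .observables import FitMetrics, fit_metrics
from .params import TissueParameters
from .traces_io import Trace

__all__ = ["CalibrationResult", "fit_sigma_max", "run_calibration", "evaluate_run2",
           "DEFAULT_SIGMA_MAX_BOUNDS"]

DEFAULT_SIGMA_MAX_BOUNDS = (0.125, 0.1675)   # S/m


@dataclass
class CalibrationResult:
    """Fitted parameters and per-sequence fit metrics for one run."""

    runLabel: str                               # "Run1" | "Run2"
    fittedSigmaMax: dict[int, float]            # per sequence (shared value repeated in Run2)
    metrics: dict[int, FitMetrics]
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_sigma_max(self) -> float:
        return float(np.mean(list(self.fittedSigmaMax.values())))

    @property
    def mean_rel_deviation(self) -> float:
        return float(np.mean([m.relDeviation for m in self.metrics.values()]))

    def table_rows(self) -> list[tuple]:
        """(sequence, iMax, avgDeltaI, relDeviation) per sequence."""
        return [(n, m.iMax, m.avgDeltaI, m.relDeviation)
                for n, m in sorted(self.metrics.items())]


def _objective_factory(measuredVoltage: Trace, measuredCurrent: Trace,
                       mesh: Mesh, params: TissueParameters,
                       controls: SolverControls | None):
    def metrics_at(sigma_max: float) -> FitMetrics:
        trial = params.replace(sigmaMax=float(sigma_max))
        sim = run_simulation(mesh, measuredVoltage, trial, controls)
        return fit_metrics(measuredCurrent, sim)
    return metrics_at


def fit_sigma_max(
    measuredVoltage: Trace,
    measuredCurrent: Trace,
    mesh: Mesh,
    params: TissueParameters,
    bounds: tuple[float, float] = DEFAULT_SIGMA_MAX_BOUNDS,
    controls: SolverControls | None = None,
    xatol: float = 1e-4,
) -> tuple[float, FitMetrics]:
    """Optimise sigmaMax against one measured voltage/current pair.

    The measured (down-sampled, replicate-averaged) voltage drives the
    simulation; avg dI against the measured current is minimised over the
    bounded interval with Brent's method.  Deterministic for fixed inputs.
    A warning is issued when the optimum sticks to a bound.
    """
    lo, hi = bounds
    if not (lo > params.sigma0):
        raise ValueError("lower bound must exceed sigma0")
    if not (hi > lo):
        raise ValueError("bounds must be an increasing pair")
    metrics_at = _objective_factory(measuredVoltage, measuredCurrent, mesh,
                                    params, controls)
    res = minimize_scalar(lambda s: metrics_at(s).avgDeltaI,
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    s_opt = float(res.x)
    if min(s_opt - lo, hi - s_opt) < 2 * xatol:
        warnings.warn(f"sigmaMax optimum {s_opt:.5g} sits at a search bound "
                      f"{bounds}", RuntimeWarning, stacklevel=2)
    return s_opt, metrics_at(s_opt)


def run_calibration(
    sequences: dict[int, tuple[Trace, Trace]],
    mesh: Mesh,
    params: TissueParameters,
    bounds: tuple[float, float] = DEFAULT_SIGMA_MAX_BOUNDS,
    controls: SolverControls | None = None,
    xatol: float = 1e-4,
) -> CalibrationResult:
    """Run1: per-sequence sigmaMax optimisation.

    ``sequences`` maps a sequence label to its preprocessed
    (voltage, current) trace pair.
    """
    fitted, metrics, notes = {}, {}, []
    for label, (v, i) in sorted(sequences.items()):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            s_opt, m = fit_sigma_max(v, i, mesh, params, bounds, controls, xatol)
        fitted[label] = s_opt
        metrics[label] = m
        notes.extend(f"sequence {label}: {w.message}" for w in caught)
    return CalibrationResult("Run1", fitted, metrics, notes)


def evaluate_run2(
    sequences: dict[int, tuple[Trace, Trace]],
    sharedSigmaMax: float,
    mesh: Mesh,
    params: TissueParameters,
    controls: SolverControls | None = None,
) -> CalibrationResult:
    """Run2: evaluate every sequence with one shared, fixed sigmaMax."""
    metrics = {}
    for label, (v, i) in sorted(sequences.items()):
        metrics_at = _objective_factory(v, i, mesh, params, controls)
        metrics[label] = metrics_at(sharedSigmaMax)
    fitted = {label: float(sharedSigmaMax) for label in sequences}
    return CalibrationResult("Run2", fitted, metrics)


def write_metrics_table(result: CalibrationResult, path) -> None:
    """One delimited row per sequence, mirroring the calibration table."""
    with open(path, "w") as fh:
        fh.write("sequence,sigmaMax,I_MAX,avgDeltaI,relDeviation\n")
        for n, imax, adi, rel in result.table_rows():
            fh.write(f"{n},{result.fittedSigmaMax[n]:.6g},{imax:.6g},"
                     f"{adi:.6g},{rel:.6g}\n")
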