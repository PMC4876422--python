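"""Synthetic oscilloscope-like experiments with known ground truth.

No measured traces are distributed with the package, so every stage of the
pipeline — down-sampling, replicate averaging, current extraction, inverse
calibration — is exercised against synthetic experiments: the forward model
run with a known parameter set, dressed with the acquisition artefacts of
the real protocol (finite rise/fall trapezoids, plateau ripple of a few
tenths of a percent, additive Gaussian current noise, five replicates,
recording windows restricted to the pulses for the low-repetition-rate
sequences).

Regenerating with the same seed reproduces identical traces bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fem_engine import SolverControls, run_simulation, schedule_time_steps
from .mesh_geometry import Mesh
from .params import TissueParameters
from .traces_io import PulseTrain, Trace, write_trace

__all__ = ["SyntheticExperiment", "generate_experiment", "write_experiment"]


@dataclass
class SyntheticExperiment:
    """Specification of one synthetic measurement campaign."""

    sequenceSpec: PulseTrain
    trueParams: TissueParameters
    replicates: int = 5
    noiseSigma: float = 0.01        # fraction of the peak simulated current
    seed: int = 0
    voltageJitter: float = 0.005    # fractional plateau ripple
    samplesPerPulse: int = 30_000   # raw acquisition samples per pulse window
    sigma0Spread: float = 0.0       # optional per-replicate biological variability

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noiseSigma < 0 or self.voltageJitter < 0 or self.sigma0Spread < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.samplesPerPulse < 10:
            raise ValueError("samplesPerPulse too small to resolve a pulse")


def _acquisition_times(train: PulseTrain, samples_per_pulse: int) -> np.ndarray:
    """Recording windows around each pulse (gaps between pulses at low f)."""
    pad = 10e-6
    width = train.riseTime + train.pulseDuration + train.fallTime + pad
    windows = []
    for k in range(train.pulseCount):
        t0 = train.startTime + k * train.period
        windows.append(np.linspace(t0, t0 + width, samples_per_pulse,
                                   endpoint=False))
    return np.concatenate(windows)


def generate_experiment(
    spec: SyntheticExperiment,
    mesh: Mesh,
    controls: SolverControls | None = None,
) -> list[tuple[Trace, Trace]]:
    """Produce per-replicate (voltage, current) raw trace pairs.

    Each replicate applies plateau ripple to the nominal trapezoid, runs the
    forward model with the ground-truth parameters on the adaptive schedule,
    interpolates the simulated current onto the dense acquisition grid and
    adds i.i.d. Gaussian noise scaled by the replicate's peak current.
    """
    train = spec.sequenceSpec
    controls = controls or SolverControls.from_params(spec.trueParams)
    sched = schedule_time_steps(train, controls,
                                until=train.end_time + controls.edgeRefinementWindow)
    acq = _acquisition_times(train, spec.samplesPerPulse)
    nominal = train.voltage_at(sched)
    plateau = nominal > 0.5 * abs(train.peakVoltage)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(spec.seed).spawn(spec.replicates)]

    out = []
    for rng in streams:
        v = nominal.copy()
        if spec.voltageJitter > 0:
            v[plateau] *= 1.0 + spec.voltageJitter * rng.standard_normal(plateau.sum())
        params = spec.trueParams
        if spec.sigma0Spread > 0:
            params = params.replace(
                sigma0=spec.trueParams.sigma0
                * (1.0 + spec.sigma0Spread * rng.standard_normal()))
        drive = Trace(sched, v, kind="voltage", meta={"source": "synthetic"})
        sim = run_simulation(mesh, drive, params, controls)
        v_raw = np.interp(acq, sched, v)
        i_raw = np.interp(acq, sim.times, sim.simulatedCurrent)
        i_peak = float(np.max(np.abs(i_raw)))
        if spec.noiseSigma > 0 and i_peak > 0:
            i_raw = i_raw + spec.noiseSigma * i_peak * rng.standard_normal(acq.size)
        out.append((
            Trace(acq, v_raw, kind="voltage", meta={"replicate": len(out)}),
            Trace(acq, i_raw, kind="current", meta={"replicate": len(out)}),
        ))
    return out


def write_experiment(pairs: list[tuple[Trace, Trace]], outdir: str | Path,
                     prefix: str = "rep") -> list[tuple[Path, Path]]:
    """Write per-replicate CSV pairs as ``<prefix><k>_{voltage,current}.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (v, i) in enumerate(pairs):
        pv = outdir / f"{prefix}{k}_voltage.csv"
        pi = outdir / f"{prefix}{k}_current.csv"
        write_trace(v, pv)
        write_trace(i, pi)
        paths.append((pv, pi))
    return paths
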