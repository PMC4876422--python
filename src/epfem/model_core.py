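"""Constitutive law of the dynamic electroporation conductivity model.

Local tissue conductivity is driven by three subsidiary state variables:

* ``p`` — level of poration in [0, 1].  The local field magnitude sets a
  target through a linear ramp between ``Emin`` and ``Emax``; the level jumps
  to the target when it rises (fast pore creation) and relaxes toward it
  exponentially with ``tauRelax`` when it falls (pore closing).
* ``dP`` — poration damage indicator.  Accumulates at rate ``alphaP * E``
  while a pulse is applied and decays exponentially between pulses; it feeds
  an exponential-saturation conductivity term of amplitude ``Apg``.
* ``dT`` — thermal damage indicator, the analogous slow variable standing in
  for Joule heating, with amplitude ``AT`` and specific time ``tauT``.

The composed conductivity is

    sigma = [sigma0 + (sigmaMax - sigma0) * p]
            * [1 + Apg * (1 - exp(-dP / tauPg))]
            * [1 + AT  * (1 - exp(-dT / tauT))]

so a virgin element conducts at ``sigma0``, a fully porated undamaged one at
``sigmaMax``, and the law is bounded by ``sigmaMax * (1+Apg) * (1+AT)``.

The capacitive current density is a per-element first-order RC filter on the
local potential: a potential step dU launches a spike of magnitude
``AC * dU / R`` that decays with time constant ``R*C``.  All functions accept
scalars or element-wise numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import TissueParameters

__all__ = [
    "TissueState",
    "target_poration",
    "update_poration",
    "poration_slope",
    "update_damage",
    "conductivity",
    "conductivity_and_slope",
    "capacitive_current_density",
    "advance_state",
]


def target_poration(Emag, params: TissueParameters):
    """Field-determined ceiling of the poration level.

    Linear ramp clamped to [0, 1]: 0 at or below ``Emin``, 1 at or above
    ``Emax`` (thresholds map inclusively).  Raises on negative field
    magnitudes — callers pass |E|.
    """
    Emag = np.asarray(Emag, dtype=float)
    if np.any(Emag < 0):
        raise ValueError("field magnitude must be non-negative")
    out = np.clip((Emag - params.Emin) / (params.Emax - params.Emin), 0.0, 1.0)
    return out if out.ndim else float(out)


def update_poration(pPrev, Emag, dt: float, params: TissueParameters):
    """Advance the poration level over one time step.

    Rising target is attained instantly; a falling target is approached as
    ``pT + (pPrev - pT) * exp(-dt/tauRelax)``.  Result stays in [0, 1].
    """
    pPrev = np.asarray(pPrev, dtype=float)
    if np.any(pPrev < 0) or np.any(pPrev > 1):
        raise ValueError("poration level must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    pT = np.asarray(target_poration(Emag, params))
    relaxed = pT + (pPrev - pT) * np.exp(-dt / params.tauRelax)
    out = np.where(pT >= pPrev, pT, relaxed)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def poration_slope(pPrev, Emag, dt: float, params: TissueParameters):
    """d(update_poration)/dEmag at fixed previous level (for Newton).

    One-sided at the ramp clamps: zero outside (Emin, Emax).  In the rising
    branch the slope is that of the linear ramp; in the relaxing branch it is
    scaled by ``1 - exp(-dt/tauRelax)``.
    """
    pPrev = np.asarray(pPrev, dtype=float)
    Emag = np.asarray(Emag, dtype=float)
    ramp = 1.0 / (params.Emax - params.Emin)
    inside = (Emag > params.Emin) & (Emag < params.Emax)
    pT = np.clip((Emag - params.Emin) * ramp, 0.0, 1.0)
    factor = np.where(pT >= pPrev, 1.0, 1.0 - np.exp(-dt / params.tauRelax))
    out = np.where(inside, ramp * factor, 0.0)
    return out if out.ndim else float(out)


def update_damage(dPrev, Emag, dt: float, pulseOn: bool, alpha: float, tauDecay: float):
    """Advance a damage indicator over one time step.

    During a pulse the indicator grows linearly with the field,
    ``dPrev + alpha*Emag*dt``; between pulses it decays as
    ``dPrev * exp(-dt/tauDecay)``.
    """
    dPrev = np.asarray(dPrev, dtype=float)
    if np.any(dPrev < 0):
        raise ValueError("damage indicator must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if pulseOn:
        out = dPrev + alpha * np.asarray(Emag, dtype=float) * dt
    else:
        out = dPrev * np.exp(-dt / tauDecay)
    return out if out.ndim else float(out)


def conductivity(p, dP, dT, params: TissueParameters):
    """Compose the conductivity from the three subsidiary variables."""
    p = np.asarray(p, dtype=float)
    base = params.sigma0 + (params.sigmaMax - params.sigma0) * p
    growth = 1.0 + params.Apg * (-np.expm1(-np.asarray(dP, float) / params.tauPg))
    thermal = 1.0 + params.AT * (-np.expm1(-np.asarray(dT, float) / params.tauT))
    out = base * growth * thermal
    return out if out.ndim else float(out)


def conductivity_and_slope(pPrev, dP, dT, Emag, dt: float, params: TissueParameters):
    """Conductivity and its field derivative for the Newton linearisation.

    Within a time step the poration level is the deterministic response
    ``update_poration(pPrev, E, dt)`` of the frozen previous level, so sigma
    is an explicit function of the trial field; ``dP``/``dT`` are held at
    their previous values (they are committed only after convergence).
    """
    p = update_poration(pPrev, Emag, dt, params)
    sig = conductivity(p, dP, dT, params)
    dp_dE = poration_slope(pPrev, Emag, dt, params)
    growth = 1.0 + params.Apg * (-np.expm1(-np.asarray(dP, float) / params.tauPg))
    thermal = 1.0 + params.AT * (-np.expm1(-np.asarray(dT, float) / params.tauT))
    dsig_dE = (params.sigmaMax - params.sigma0) * dp_dE * growth * thermal
    return sig, dsig_dE


def capacitive_current_density(uLocal, capMemory, dt: float, Edir, params: TissueParameters):
    """Per-element RC charging current density and updated filter state.

    ``Edir`` is the unit direction of the local field; the current points
    along it with the sign of ``uLocal - capMemory``.  Returns
    ``(jCap, capMemoryNew)`` where ``|jCap| = AC * |uLocal - capMemory|
    * exp(-dt/RC) / R``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    uLocal = np.asarray(uLocal, dtype=float)
    capMemory = np.asarray(capMemory, dtype=float)
    f = np.exp(-dt / (params.R * params.C))
    delta = uLocal - capMemory
    magnitude = params.AC * np.abs(delta) * f / params.R
    Edir = np.asarray(Edir, dtype=float)
    jCap = (np.sign(delta) * magnitude)[..., None] * Edir if Edir.ndim > 1 \
        else np.sign(delta) * magnitude * Edir
    capMemoryNew = uLocal + (capMemory - uLocal) * f
    return jCap, capMemoryNew


def advance_state(state: "TissueState", Evec, uLocal, dt: float, pulseOn: bool,
                  params: TissueParameters, t: float) -> "TissueState":
    """Commit all subsidiary variables after a converged field solve.

    ``Evec`` is the per-element field vector (n, 3) at the new time,
    ``uLocal`` the per-element mean potential driving the capacitive filter.
    No inner convergence loop is run for the subsidiary variables — they are
    explicit functions of the converged field.
    """
    Evec = np.atleast_2d(np.asarray(Evec, dtype=float))
    Emag = np.linalg.norm(Evec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Edir = np.where(Emag[:, None] > 0, Evec / np.where(Emag, Emag, 1.0)[:, None], 0.0)
    # when the field has collapsed (pulse fall) the membranes discharge along
    # the direction they were charged: fall back to the previous current axis
    dead = Emag == 0
    if np.any(dead):
        for prev in (state.jCond, state.jCap):
            prev = np.atleast_2d(prev)
            mag = np.linalg.norm(prev, axis=1)
            fix = dead & (mag > 0)
            if np.any(fix):
                Edir[fix] = prev[fix] / mag[fix, None]
                dead = dead & ~fix
    p = np.asarray(update_poration(state.p, Emag, dt, params))
    dP = np.asarray(update_damage(state.dP, Emag, dt, pulseOn, params.alphaP, params.tauRelax))
    dT = np.asarray(update_damage(state.dT, Emag, dt, pulseOn, params.alphaT, params.tauT))
    sigma = np.asarray(conductivity(p, dP, dT, params))
    jCap, capMemory = capacitive_current_density(uLocal, state.capMemory, dt, Edir, params)
    return TissueState(
        p=p, dP=dP, dT=dT, sigma=sigma, Emag=Emag,
        jCond=sigma[:, None] * Evec,
        jCap=np.atleast_2d(jCap),
        capMemory=np.asarray(capMemory, dtype=float),
        t=t,
    )


@dataclass
class TissueState:
    """Per-element state of the tissue at one instant of the simulation."""

    p: np.ndarray          # level of poration, [0, 1]
    dP: np.ndarray         # poration damage indicator, s
    dT: np.ndarray         # thermal damage indicator, s
    sigma: np.ndarray      # conductivity, S/m
    Emag: np.ndarray       # field magnitude, V/m
    jCond: np.ndarray      # conductive current density vector, A/m^2 (n, 3)
    jCap: np.ndarray       # capacitive current density vector, A/m^2 (n, 3)
    capMemory: np.ndarray  # filtered local potential, V
    t: float = 0.0         # simulation time, s

    @classmethod
    def virgin(cls, n_elements: int, params: TissueParameters, t: float = 0.0) -> "TissueState":
        """Unperturbed tissue: p = dP = dT = 0 and sigma = sigma0 everywhere."""
        z = np.zeros(n_elements)
        return cls(
            p=z.copy(), dP=z.copy(), dT=z.copy(),
            sigma=np.full(n_elements, params.sigma0),
            Emag=z.copy(),
            jCond=np.zeros((n_elements, 3)),
            jCap=np.zeros((n_elements, 3)),
            capMemory=z.copy(),
            t=t,
        )

    def copy(self) -> "TissueState":
        return TissueState(
            p=self.p.copy(), dP=self.dP.copy(), dT=self.dT.copy(),
            sigma=self.sigma.copy(), Emag=self.Emag.copy(),
            jCond=self.jCond.copy(), jCap=self.jCap.copy(),
            capMemory=self.capMemory.copy(), t=self.t,
        )

    def validate(self, params: TissueParameters) -> None:
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("p out of [0, 1]")
        if np.any(self.dP < 0) or np.any(self.dT < 0):
            raise ValueError("negative damage indicator")
        if np.any(self.sigma < params.sigma0 * (1 - 1e-12)):
            raise ValueError("sigma below baseline")
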