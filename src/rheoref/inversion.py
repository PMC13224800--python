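"""Forward model and inversion of the complex amplitude ratio.

The measured quantity of an oscillatory DWR experiment is the complex
amplitude ratio ``AR = (T0/theta0) e^{i phi}`` between the torque and
angular-displacement phasors.  With the probe equation of motion in the
frequency domain (time factor ``e^{+i omega t}``),

    AR = -I omega^2 + i omega (K_i + K_b),

where ``K_i`` and ``K_b`` are the interfacial and bulk drag torques per unit
probe angular velocity delivered by the flow solver.  The interface state is
encoded in the complex Boussinesq number ``Bo = eta_s*/(eta a)``, with
``G* = i omega eta_s*`` giving the storage and loss moduli.

The inversion recovers ``Bo`` from a measured ``AR`` by the flow-field-based
fixed point: freeze the flow at the current ``Bo``, solve the equation of
motion for the interfacial torque that would reproduce the measurement, and
rescale ``Bo`` accordingly (``K_i`` is exactly linear in ``Bo`` at frozen
flow, so convergence is fast and monotone over many decades).
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .flowfield import FlowEngine, get_engine
from .geometry import (
    WATER,
    DWRGeometry,
    FluidPhase,
    ProbeDynamics,
    inertia_limit,
)

__all__ = [
    "InterfaceState",
    "AmplitudeRatio",
    "InversionOptions",
    "ar_forward",
    "ar_highBo",
    "invert_ar",
    "calibrate_inertia",
    "state_from_moduli",
]


@dataclass
class InterfaceState:
    """Interfacial viscoelastic state at one frequency.

    ``eta_s`` is the complex interfacial shear viscosity (Pa s m); the moduli
    follow the ``G* = i omega eta_s*`` convention: ``G_loss = omega Re eta_s``
    and ``G_storage = -omega Im eta_s``.
    """

    omega: float
    Bo: complex
    eta_s: complex
    G_storage: float
    G_loss: float
    inertia_limited: bool = False
    n_iter: int = 0
    sigma_G: Optional[Tuple[float, float]] = None

    @property
    def G_complex(self) -> complex:
        return self.G_storage + 1j * self.G_loss


def state_from_moduli(
    G_storage: float,
    G_loss: float,
    omega: float,
    geom: DWRGeometry,
    subphase: FluidPhase = WATER,
) -> InterfaceState:
    """Build the interface state corresponding to given moduli at ``omega``."""
    if omega <= 0.0:
        raise ValueError("omega must be positive")
    G = G_storage + 1j * G_loss
    eta_s = G / (1j * omega)  # = (G_loss - i G_storage)/omega
    Bo = eta_s / (subphase.eta * geom.a)
    return InterfaceState(
        omega=omega,
        Bo=Bo,
        eta_s=eta_s,
        G_storage=G_storage,
        G_loss=G_loss,
    )


@dataclass
class AmplitudeRatio:
    """Torque/angle phasor ratio at one frequency (N m / rad).

    ``sigma_mod`` and ``sigma_phase`` are 1-sigma uncertainties of the modulus
    and of the phase; ``strain`` is the average interfacial strain at which
    the waveform was recorded; ``truth`` may carry the generating state of a
    synthetic measurement.
    """

    omega: float
    AR: complex
    sigma_mod: float = 0.0
    sigma_phase: float = 0.0
    strain: float = 0.0
    truth: Optional[InterfaceState] = None

    def __post_init__(self) -> None:
        if self.omega <= 0.0:
            raise ValueError("omega must be positive")
        if self.sigma_mod < 0.0 or self.sigma_phase < 0.0:
            raise ValueError("uncertainties must be non-negative")


@dataclass
class InversionOptions:
    """Tolerances and mesh resolution of the fixed-point inversion."""

    resolution: int = 16
    tol: float = 1e-6
    max_iter: int = 100
    bo_floor: float = 1e-6  # absolute Bo scale regarded as numerically zero
    two_phase: bool = False


def ar_forward(
    state: InterfaceState,
    dyn: ProbeDynamics,
    geom: DWRGeometry,
    phases: Tuple[FluidPhase, Optional[FluidPhase]] = (WATER, None),
    mesh_resolution: int = 16,
    two_phase: bool = False,
) -> complex:
    """Complex amplitude ratio predicted by the full flow model.

    ``AR = -I omega^2 + i omega (K_i + K_b)`` with the drags evaluated at the
    state's Boussinesq number.
    """
    eng = get_engine(geom, phases, mesh_resolution, two_phase)
    K_i, K_b, _ = eng.drags(state.Bo, state.omega)
    return -dyn.I * state.omega**2 + 1j * state.omega * (K_i + K_b)


def ar_highBo(state: InterfaceState, dyn: ProbeDynamics) -> complex:
    """Closed-form amplitude ratio in the interface-dominated limit.

    Bulk drag is neglected and the interfacial torque reduces to the
    geometric coefficient: ``AR = -I omega^2 + g1 G*``, so the modulus

    ``|AR| = sqrt((g1 G' - I omega^2)^2 + (g1 G'')^2)``

    has its minimum (resonance) at ``G' = I omega^2 / g1``.
    """
    return -dyn.I * state.omega**2 + dyn.g1 * state.G_complex


def _state_from_bo(
    Bo: complex,
    omega: float,
    geom: DWRGeometry,
    subphase: FluidPhase,
    dyn: ProbeDynamics,
    n_iter: int = 0,
) -> InterfaceState:
    eta_s = Bo * subphase.eta * geom.a
    G = 1j * omega * eta_s
    st = InterfaceState(
        omega=omega,
        Bo=Bo,
        eta_s=eta_s,
        G_storage=G.real,
        G_loss=G.imag,
        n_iter=n_iter,
    )
    st.inertia_limited = abs(G) < inertia_limit(dyn.I, omega, dyn.g1)
    return st


def invert_ar(
    meas: AmplitudeRatio,
    dyn: ProbeDynamics,
    geom: DWRGeometry,
    phases: Tuple[FluidPhase, Optional[FluidPhase]] = (WATER, None),
    opts: Optional[InversionOptions] = None,
) -> InterfaceState:
    """Invert a measured amplitude ratio into an interface state (FFBDA).

    Fixed-point iteration: with drags ``K_i(Bo_k)``, ``K_b(Bo_k)`` from the
    flow solve, the equation of motion gives the interfacial torque required
    by the measurement, and since ``K_i = Bo eta a J(Bo)`` with ``J`` the
    contact-line stress functional (slowly varying in ``Bo``),

        Bo_{k+1} = (AR + I omega^2 - i omega K_b(Bo_k)) / (i omega eta a J(Bo_k)).

    Seeded from the high-Bo closed form.  Converged when the Bo update is
    below ``tol`` relative (with an absolute floor so clean interfaces, where
    Bo -> 0, terminate); measurement uncertainties are propagated to the
    moduli by first-order rules.
    """
    opts = opts or InversionOptions()
    omega = meas.omega
    sub = phases[0]
    eng = get_engine(geom, phases, opts.resolution, opts.two_phase)
    eta_a = sub.eta * geom.a

    # high-Bo seed: AR = -I w^2 + g1 G*, G* = i w eta_s, eta_s = Bo eta a
    G_seed = (meas.AR + dyn.I * omega**2) / dyn.g1
    Bo = G_seed / (1j * omega * eta_a)
    if not np.isfinite(Bo) or abs(Bo) < opts.bo_floor:
        Bo = complex(opts.bo_floor)

    trace = [Bo]
    for k in range(1, opts.max_iter + 1):
        _, K_b, J = eng.drags(Bo, omega)
        denom = 1j * omega * eta_a * J
        if denom == 0:
            raise RuntimeError("degenerate interfacial drag functional (J = 0)")
        Bo_next = (meas.AR + dyn.I * omega**2 - 1j * omega * K_b) / denom
        trace.append(Bo_next)
        if abs(Bo_next - Bo) <= opts.tol * abs(Bo) or (
            abs(Bo_next) < opts.bo_floor and abs(Bo) < opts.bo_floor
        ):
            Bo = Bo_next
            break
        Bo = Bo_next
    else:
        raise RuntimeError(
            "FFBDA fixed point did not converge in "
            f"{opts.max_iter} iterations; |Bo| trace tail: "
            f"{[abs(b) for b in trace[-5:]]}"
        )

    st = _state_from_bo(Bo, omega, geom, sub, dyn, n_iter=k)
    # first-order uncertainty propagation: dG* ~ (i w eta a J)^{-1} g1-like
    # mapping of dAR; modulus/phase sigmas are mapped through |dG/dAR|
    if meas.sigma_mod > 0.0 or meas.sigma_phase > 0.0:
        _, K_b, J = eng.drags(Bo, omega)
        # |dBo/dAR| = 1/|i w eta a J| and |dG*/dBo| = w eta a, so
        # |dG*/dAR| = 1/|J|
        scale = 1.0 / abs(J)
        s_re = meas.sigma_mod
        s_im = abs(meas.AR) * meas.sigma_phase
        sigma_AR = float(np.hypot(s_re, s_im))
        st.sigma_G = (scale * sigma_AR, scale * sigma_AR)
    if st.G_loss < 0.0 and st.sigma_G is not None:
        if st.G_loss < -3.0 * st.sigma_G[1]:
            st.inertia_limited = True  # unphysical beyond noise; flag
    return st


def calibrate_inertia(
    clean_sweep: Sequence[AmplitudeRatio],
    geom: DWRGeometry,
    phases: Tuple[FluidPhase, Optional[FluidPhase]] = (WATER, None),
    resolution: int = 16,
) -> Tuple[float, dict]:
    """Least-squares rotor+probe inertia from a clean-interface sweep.

    Fits ``AR(omega) = -I omega^2 + i omega K_b(omega)`` (with ``K_b`` from
    the clean-interface flow solve, Bo = 0) for the single real parameter
    ``I``.  Returns the estimate and residual diagnostics; a large relative
    residual indicates the sweep was not a clean interface (e.g. residual
    interfacial drag biasing I upward).
    """
    if len(clean_sweep) < 3:
        raise ValueError("need at least 3 frequencies to calibrate inertia")
    omegas = np.array([m.omega for m in clean_sweep])
    if omegas.max() / omegas.min() < 1.5:
        raise ValueError("frequency range too narrow for a conditioned fit")
    eng = get_engine(geom, phases, resolution)
    ar = np.array([m.AR for m in clean_sweep])
    kb = np.array([eng.drags(0.0, w)[1] for w in omegas])
    resid_vec = ar - 1j * omegas * kb  # should equal -I w^2
    # least squares over real I: minimise |resid_vec + I w^2|^2
    I_est = -np.sum(resid_vec.real * omegas**2) / np.sum(omegas**4)
    model = -I_est * omegas**2 + 1j * omegas * kb
    resid = ar - model
    diag = {
        "residuals": resid,
        "rel_residual": float(
            np.linalg.norm(resid) / max(np.linalg.norm(ar), 1e-300)
        ),
        "omegas": omegas,
    }
    if I_est <= 0.0:
        raise RuntimeError("inertia fit produced a non-positive estimate")
    return float(I_est), diag
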