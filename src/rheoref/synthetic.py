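"""Forward simulation of the oscillatory DWR experiment.

Generates raw multi-channel records (and noiseless amplitude-ratio sweeps)
with known interfacial ground truth, so the whole analysis chain -- trigger
splitting, DFT demodulation, dual-gain merging and the flow-field inversion
-- can be validated without an instrument.  The probe dynamics follow the
second-order torque balance (inertia + interfacial + bulk drag); strain
control is idealised: the commanded angular amplitude is computed exactly
from the target average strain, rather than emulating the rheometer's
feedback loop.  Channel noise is white Gaussian per channel, and all
channels are quantised to the ADC grid (16 bit over +-10 V by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import WATER, DWRGeometry, FluidPhase, ProbeDynamics, average_strain
from .inversion import AmplitudeRatio, InterfaceState, ar_forward, ar_highBo, state_from_moduli
from .signals import ChannelCalibration, RawRecord

__all__ = [
    "SimulationSpec",
    "simulate_ar_sweep",
    "simulate_record",
    "resonance_curve",
]


@dataclass
class SimulationSpec:
    """Ground truth and acquisition settings for a synthetic run.

    ``G_storage``/``G_loss`` are either scalars (frequency-independent
    moduli, N/m) or sequences matching ``f_list``.  ``noise_sd`` is the
    per-channel white-noise standard deviation in volts.
    """

    G_storage: float | Sequence[float] = 0.0
    G_loss: float | Sequence[float] = 0.0
    f_list: Sequence[float] = (0.5,)
    strain_target: float = 0.03
    n_periods: int = 10
    fs: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0
    lead_in_periods: float = 3.0  # pre-trigger-analysis transient kept in each block
    geom: DWRGeometry = field(default_factory=DWRGeometry)
    I: float = 1.0e-5
    subphase: FluidPhase = WATER
    calib: ChannelCalibration = field(default_factory=ChannelCalibration)
    mesh_resolution: int = 16

    def __post_init__(self) -> None:
        if len(self.f_list) == 0:
            raise ValueError("f_list must not be empty")
        if self.fs <= 10.0 * max(self.f_list):
            raise ValueError("fs must exceed 10x the largest frequency")
        if self.n_periods < 4:
            raise ValueError("need at least 4 periods per measurement")

    def moduli_at(self, idx: int) -> Tuple[float, float]:
        gs = self.G_storage
        gl = self.G_loss
        g1 = gs[idx] if np.ndim(gs) else float(gs)
        g2 = gl[idx] if np.ndim(gl) else float(gl)
        return float(g1), float(g2)

    @property
    def dynamics(self) -> ProbeDynamics:
        return ProbeDynamics.from_geometry(self.I, self.geom)


def simulate_ar_sweep(spec: SimulationSpec) -> List[AmplitudeRatio]:
    """Noiseless amplitude-ratio sweep from the full flow-field model.

    Each returned measurement carries its generating interface state in
    ``truth``.
    """
    dyn = spec.dynamics
    out = []
    for idx, f in enumerate(spec.f_list):
        omega = 2.0 * np.pi * f
        gp, gpp = spec.moduli_at(idx)
        state = state_from_moduli(gp, gpp, omega, spec.geom, spec.subphase)
        AR = ar_forward(
            state,
            dyn,
            spec.geom,
            (spec.subphase, None),
            mesh_resolution=spec.mesh_resolution,
        )
        out.append(
            AmplitudeRatio(
                omega=omega, AR=AR, strain=spec.strain_target, truth=state
            )
        )
    return out


def _quantize(v: np.ndarray, calib: ChannelCalibration) -> np.ndarray:
    lsb = calib.lsb
    q = np.round(v / lsb) * lsb
    return np.clip(q, -calib.v_range, calib.v_range - lsb)


def simulate_record(spec: SimulationSpec) -> Tuple[RawRecord, List[AmplitudeRatio]]:
    """Synthesize the four-channel DAQ record for the spec's frequency list.

    One measurement block per frequency: the trigger rises at the block
    start, the commanded angle is ``theta(t) = theta0 cos(omega t)`` with
    ``theta0`` set by the target average strain, and the torque channel
    follows ``|AR| theta0 cos(omega t + arg AR)``.  Gaussian noise is added
    per channel and everything is quantised to the ADC grid.  Returns the
    record plus the noiseless ground-truth amplitude ratios.
    """
    rng = np.random.default_rng(spec.seed)
    truth = simulate_ar_sweep(spec)
    cal = spec.calib
    gamma_per_rad = average_strain(1.0, spec.geom)
    theta0 = spec.strain_target / gamma_per_rad

    t_parts, th_parts, lo_parts, hi_parts, tr_parts = [], [], [], [], []
    t_cursor = 0.0
    for meas in truth:
        omega = meas.omega
        f = omega / (2.0 * np.pi)
        n_samp = int(round((spec.n_periods + spec.lead_in_periods) * spec.fs / f))
        tt = t_cursor + np.arange(n_samp) / spec.fs
        tau = tt - t_cursor
        theta = theta0 * np.cos(omega * tau)
        torque = abs(meas.AR) * theta0 * np.cos(omega * tau + np.angle(meas.AR))
        v_th = cal.gain_theta * theta
        v_lo = cal.gain_torque_lo * torque
        v_hi = cal.gain_torque_hi * torque
        for name, v in (("theta", v_th), ("torque_lo", v_lo)):
            if np.max(np.abs(v)) > cal.v_range:
                raise ValueError(
                    f"channel {name} exceeds +-{cal.v_range} V; lower the gain"
                )
        trig = np.where(tau < 0.5 * n_samp / spec.fs, 5.0, 0.0)
        if spec.noise_sd > 0.0:
            v_th = v_th + rng.normal(0.0, spec.noise_sd, n_samp)
            v_lo = v_lo + rng.normal(0.0, spec.noise_sd, n_samp)
            v_hi = v_hi + rng.normal(0.0, spec.noise_sd, n_samp)
        t_parts.append(tt)
        th_parts.append(_quantize(v_th, cal))
        lo_parts.append(_quantize(v_lo, cal))
        hi_parts.append(_quantize(v_hi, cal))
        tr_parts.append(trig)
        t_cursor += n_samp / spec.fs

    rec = RawRecord(
        t=np.concatenate(t_parts),
        v_theta=np.concatenate(th_parts),
        v_torque_lo=np.concatenate(lo_parts),
        v_torque_hi=np.concatenate(hi_parts),
        v_trigger=np.concatenate(tr_parts),
        fs=spec.fs,
        calib=cal,
    )
    return rec, truth


def resonance_curve(
    dyn: ProbeDynamics,
    omega: float,
    G_loss: float,
    G_storage_grid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """``|AR|`` versus storage modulus in the interface-dominated limit.

    ``|AR|^2 = (g1 G' - I omega^2)^2 + (g1 G'')^2`` -- the torque needed to
    drive the probe has a minimum (resonance) at ``G' = I omega^2 / g1``,
    where the elastic interfacial torque cancels the inertia.  Returns
    ``(G' grid, |AR| values, analytic minimiser)``.
    """
    if omega <= 0.0:
        raise ValueError("omega must be positive")
    g_res = dyn.I * omega**2 / dyn.g1
    if G_storage_grid is None:
        G_storage_grid = np.linspace(0.0, 3.0 * g_res, 301)
    ar = np.sqrt(
        (dyn.g1 * G_storage_grid - dyn.I * omega**2) ** 2
        + (dyn.g1 * G_loss) ** 2
    )
    return G_storage_grid, ar, g_res
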