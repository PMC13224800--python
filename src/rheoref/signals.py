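"""Raw DAQ records to complex amplitude ratios.

A measurement session produces four simultaneously sampled voltage channels:
angular displacement, two torque channels read through amplifiers of
different gain (so that both small and large torques stay within the ADC
range), and a trigger marking the start of each measurement interval.  The
pipeline is: split the record at trigger rising edges, keep a whole number of
oscillation periods after discarding the leading transient, take the DFT bin
at the drive frequency of each channel, merge the dual-gain torque pair, and
form ``AR = (T0/theta0) e^{i(phi_T - phi_theta)}`` with uncertainties
estimated from the off-harmonic noise floor of the same spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .inversion import AmplitudeRatio

__all__ = [
    "ChannelCalibration",
    "RawRecord",
    "Segment",
    "HarmonicComponent",
    "split_by_trigger",
    "select_periods",
    "dft_fundamental",
    "merge_dual_gain",
    "amplitude_ratio",
    "estimate_uncertainty",
]


@dataclass(frozen=True)
class ChannelCalibration:
    """Volts-per-physical-unit gains and ADC parameters.

    ``gain_theta`` in V/rad, ``gain_torque_lo``/``hi`` in V/(N m); the ADC
    digitises over ``+- v_range`` volts with ``adc_bits`` bits.
    """

    gain_theta: float = 600.0
    gain_torque_lo: float = 1.0e4
    gain_torque_hi: float = 1.0e6
    adc_bits: int = 16
    v_range: float = 10.0

    @property
    def lsb(self) -> float:
        return 2.0 * self.v_range / 2**self.adc_bits


@dataclass
class RawRecord:
    """Uniformly sampled multi-channel record."""

    t: np.ndarray
    v_theta: np.ndarray
    v_torque_lo: np.ndarray
    v_torque_hi: np.ndarray
    v_trigger: np.ndarray
    fs: float
    calib: ChannelCalibration = field(default_factory=ChannelCalibration)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("v_theta", "v_torque_lo", "v_torque_hi", "v_trigger"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, rtol=1e-6):
                raise ValueError("t must increase uniformly at 1/fs")


@dataclass
class Segment:
    """One waveform (one measurement interval) cut from a record."""

    t0: float
    fs: float
    v_theta: np.ndarray
    v_torque_lo: np.ndarray
    v_torque_hi: np.ndarray
    calib: ChannelCalibration

    def __len__(self) -> int:
        return len(self.v_theta)


@dataclass
class HarmonicComponent:
    """Amplitude/phase of the fundamental of one channel, physical units."""

    f: float
    amplitude: float
    phase: float
    n_periods: int
    noise_floor: float = 0.0
    sigma_amplitude: float = 0.0
    sigma_phase: float = 0.0
    source: str = ""
    below_noise: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0.0 or self.n_periods < 1:
            raise ValueError("require amplitude >= 0 and n_periods >= 1")


def split_by_trigger(rec: RawRecord, threshold: float = 2.5) -> List[Segment]:
    """Cut the record at rising edges of the trigger channel.

    Each segment starts at a rising edge and ends one sample before the next
    edge (or at the record end).
    """
    trig = rec.v_trigger
    above = trig >= threshold
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    if len(edges) == 0:
        raise ValueError("no trigger rising edges found")
    bounds = list(edges) + [len(trig)]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append(
            Segment(
                t0=float(rec.t[a]),
                fs=rec.fs,
                v_theta=rec.v_theta[a:b],
                v_torque_lo=rec.v_torque_lo[a:b],
                v_torque_hi=rec.v_torque_hi[a:b],
                calib=rec.calib,
            )
        )
    return segs


def select_periods(
    seg: Segment, f: float, discard_fraction: float = 0.2
) -> Tuple[Segment, int]:
    """Trim a segment to a whole number of periods of frequency ``f``.

    The leading ``discard_fraction`` of the segment (start-up transient) is
    dropped, then the longest suffix holding an integer number of periods is
    kept, so the trimmed data always ends where the raw waveform ends.
    Returns the trimmed segment and the period count.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n = len(seg)
    n_keep = n - int(np.floor(discard_fraction * n))
    spp = seg.fs / f  # samples per period
    n_periods = int(np.floor(n_keep / spp))
    if n_periods < 1:
        raise ValueError(
            f"segment holds {n_keep / spp:.2f} periods after transient "
            "discard; need at least 1"
        )
    n_samples = int(round(n_periods * spp))
    start = n - n_samples
    trimmed = Segment(
        t0=seg.t0 + start / seg.fs,
        fs=seg.fs,
        v_theta=seg.v_theta[start:],
        v_torque_lo=seg.v_torque_lo[start:],
        v_torque_hi=seg.v_torque_hi[start:],
        calib=seg.calib,
    )
    return trimmed, n_periods


def _dft_bin(x: np.ndarray, k: int) -> complex:
    n = len(x)
    ph = np.exp(-2j * np.pi * k * np.arange(n) / n)
    return complex(np.dot(x, ph))


def dft_fundamental(
    x: np.ndarray,
    fs: float,
    f: float,
    gain: float,
    n_periods: int,
    source: str = "",
) -> HarmonicComponent:
    """Amplitude and phase of the drive-frequency bin, in physical units.

    For ``x = A cos(2 pi f t + phi)`` sampled over exactly ``n_periods``
    periods, the bin at ``k = n_periods`` returns ``A`` and ``phi`` to
    machine precision.  ``gain`` converts volts to physical units.
    """
    n = len(x)
    if fs < 4.0 * f:
        raise ValueError("fewer than 4 samples per period; f not resolvable")
    k = n_periods
    if k <= 0 or k >= n // 2:
        raise ValueError("period count outside the resolvable DFT range")
    X = _dft_bin(np.asarray(x, dtype=float), k)
    amp = 2.0 * abs(X) / n / gain
    phase = float(np.angle(X))
    if phase <= -np.pi:
        phase += 2.0 * np.pi
    return HarmonicComponent(
        f=f,
        amplitude=amp,
        phase=phase,
        n_periods=n_periods,
        source=source,
    )


def estimate_uncertainty(
    x: np.ndarray,
    gain: float,
    comp: HarmonicComponent,
    n_harmonics_excluded: int = 3,
) -> Tuple[float, float]:
    """Amplitude/phase 1-sigma of a harmonic estimate from the noise floor.

    The per-sample noise power is estimated from the periodogram with the
    fundamental and its first ``n_harmonics_excluded`` harmonics (and DC)
    removed; for white noise of variance ``sigma^2`` each DFT bin carries
    ``E|X_k|^2 = N sigma^2``, giving ``sigma_amplitude = sigma sqrt(2/N)``
    and ``sigma_phase = sigma_amplitude / amplitude``.  Results are stored on
    ``comp`` and returned; an amplitude below 3 sigma sets ``below_noise``.
    """
    xv = np.asarray(x, dtype=float) / gain
    n = len(xv)
    X = np.fft.rfft(xv)
    power = np.abs(X) ** 2
    k0 = comp.n_periods
    exclude = {0}
    for h in range(1, n_harmonics_excluded + 2):
        for dk in (-1, 0, 1):  # guard bins against leakage of the line
            exclude.add(h * k0 + dk)
    keep = np.array(
        [k for k in range(len(power)) if k not in exclude], dtype=int
    )
    if len(keep) == 0:
        raise ValueError("no noise bins left to estimate the floor")
    sigma2 = float(np.mean(power[keep])) / n  # per-sample noise variance
    sigma_amp = float(np.sqrt(2.0 * sigma2 / n))
    sigma_phase = sigma_amp / comp.amplitude if comp.amplitude > 0 else np.inf
    comp.noise_floor = float(np.sqrt(sigma2))
    comp.sigma_amplitude = sigma_amp
    comp.sigma_phase = sigma_phase
    comp.below_noise = comp.amplitude < 3.0 * sigma_amp
    return sigma_amp, sigma_phase


def merge_dual_gain(
    lo: HarmonicComponent,
    hi: HarmonicComponent,
    lo_raw_peak: float,
    hi_raw_peak: float,
    v_range: float,
    saturation_fraction: float = 0.95,
) -> HarmonicComponent:
    """Select the torque channel: high gain unless it saturates the ADC."""
    if lo.f != hi.f:
        raise ValueError("dual-gain components must share the frequency")
    limit = saturation_fraction * v_range
    if hi_raw_peak <= limit:
        return replace(hi, source=hi.source or "hi")
    if lo_raw_peak <= limit:
        return replace(lo, source=lo.source or "lo")
    raise ValueError("both torque channels saturated")


def amplitude_ratio(
    torque: HarmonicComponent,
    angle: HarmonicComponent,
    strain: float = 0.0,
) -> AmplitudeRatio:
    """Complex amplitude ratio ``(T0/theta0) e^{i(phi_T - phi_theta)}``.

    A common time shift of both channels cancels in the phase difference.
    First-order uncertainty propagation:
    ``(sigma_|AR|/|AR|)^2 = (sigma_T/T0)^2 + (sigma_theta/theta0)^2`` and
    ``sigma_phi^2 = sigma_phiT^2 + sigma_phitheta^2``.
    """
    if torque.f != angle.f:
        raise ValueError("torque and angle components must share the frequency")
    if angle.amplitude == 0.0:
        raise ValueError("zero angular amplitude")
    mod = torque.amplitude / angle.amplitude
    ph = torque.phase - angle.phase
    ph = float(np.angle(np.exp(1j * ph)))
    rel = np.hypot(
        torque.sigma_amplitude / torque.amplitude if torque.amplitude else 0.0,
        angle.sigma_amplitude / angle.amplitude,
    )
    sigma_phase = float(np.hypot(torque.sigma_phase, angle.sigma_phase))
    if not np.isfinite(sigma_phase):
        sigma_phase = 0.0
    return AmplitudeRatio(
        omega=2.0 * np.pi * torque.f,
        AR=mod * np.exp(1j * ph),
        sigma_mod=float(mod * rel),
        sigma_phase=sigma_phase,
        strain=strain,
    )


def process_segment(
    seg: Segment,
    f: float,
    discard_fraction: float = 0.2,
    strain: float = 0.0,
) -> AmplitudeRatio:
    """Full per-segment pipeline: trim, DFT, merge gains, form AR."""
    trimmed, n_p = select_periods(seg, f, discard_fraction)
    cal = seg.calib
    ang = dft_fundamental(
        trimmed.v_theta, trimmed.fs, f, cal.gain_theta, n_p, source="theta"
    )
    estimate_uncertainty(trimmed.v_theta, cal.gain_theta, ang)
    lo = dft_fundamental(
        trimmed.v_torque_lo, trimmed.fs, f, cal.gain_torque_lo, n_p, source="lo"
    )
    estimate_uncertainty(trimmed.v_torque_lo, cal.gain_torque_lo, lo)
    hi = dft_fundamental(
        trimmed.v_torque_hi, trimmed.fs, f, cal.gain_torque_hi, n_p, source="hi"
    )
    estimate_uncertainty(trimmed.v_torque_hi, cal.gain_torque_hi, hi)
    torque = merge_dual_gain(
        lo,
        hi,
        float(np.max(np.abs(trimmed.v_torque_lo))),
        float(np.max(np.abs(trimmed.v_torque_hi))),
        cal.v_range,
    )
    return amplitude_ratio(torque, ang, strain=strain)
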