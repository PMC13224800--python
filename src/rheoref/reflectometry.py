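"""Specular neutron reflectivity of a lipid monolayer at the air/water interface.

Forward model: transfer-matrix (Abeles) reflectivity of a slab stack with
Nevot-Croce Gaussian-roughness factors and constant-dQ/Q Gaussian resolution
smearing.  The monolayer is parameterised molecularly as two layers -- acyl
tails against air and hydrated headgroups against water -- tied together by
the area per molecule ``A_mol`` shared by both layers:

* tail thickness ``d_AC = V_AC / A_mol`` (full tail occupancy, no solvent),
* headgroup solvent fraction ``phi = 1 - V_head / (A_mol d_head)``.

The same structural parameters describe every isotopic contrast (e.g. D2O
and air-contrast-matched water, ACMW); only the subphase SLD and background
differ, which is what makes multi-contrast co-refinement well-posed.

SLD values are expressed in the customary 1e-6 Angstrom^-2 units (so D2O is
6.36); thicknesses and roughnesses in Angstroms; Qz in inverse Angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Slab",
    "LipidMonolayerModel",
    "ReflectivityCurve",
    "FitResult",
    "qz_from_angle",
    "lipid_to_slabs",
    "abeles_reflectivity",
    "smear_resolution",
    "reflectivity_model",
    "corefine",
    "volume_fraction_profile",
    "sld_profile",
    "acmw_fraction",
    "simulate_curves",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer: thickness (A), SLD (1e-6 A^-2), roughness of
    the interface to the layer above (A), solvent volume fraction."""

    thickness: float
    sld: complex
    roughness: float = 0.0
    solvent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness < 0.0:
            raise ValueError("thickness must be non-negative")
        if self.roughness < 0.0:
            raise ValueError("roughness must be non-negative")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError("solvent_fraction must be in [0, 1]")


@dataclass
class LipidMonolayerModel:
    """Molecularly constrained two-layer lipid monolayer.

    Defaults describe a chain-deuterated DPPC monolayer in its condensed
    phase: tail volume 759 A^3, phosphatidylcholine head volume 344 A^3 and
    head thickness 9 A (literature values), with component SLDs of 8.08
    (deuterated tails) and 1.74 (heads).  ``sld_subphase`` and ``background``
    are per-contrast dictionaries.
    """

    A_mol: float = 46.66  # area per molecule, A^2
    V_AC: float = 759.0  # acyl-chain (tail) volume, A^3
    V_head: float = 344.0  # headgroup volume, A^3
    d_head: float = 9.0  # headgroup thickness, A
    sld_AC: float = 8.08
    sld_head: float = 1.74
    sigma: float = 3.45  # capillary-wave roughness, A, all interfaces
    sld_subphase: Dict[str, float] = field(
        default_factory=lambda: {"d2o": 6.36, "acmw": 0.0}
    )
    background: Dict[str, float] = field(
        default_factory=lambda: {"d2o": 5e-7, "acmw": 5e-6}
    )

    @property
    def d_AC(self) -> float:
        """Tail-layer thickness from the full-occupancy constraint (A)."""
        return self.V_AC / self.A_mol

    @property
    def head_solvent_fraction(self) -> float:
        """Solvent (hydration) volume fraction of the headgroup layer."""
        phi = 1.0 - self.V_head / (self.A_mol * self.d_head)
        return phi

    def validate(self) -> None:
        if min(self.A_mol, self.V_AC, self.V_head, self.d_head) <= 0.0:
            raise ValueError("molecular parameters must be positive")
        phi = self.head_solvent_fraction
        if not 0.0 <= phi <= 1.0:
            raise ValueError(
                f"head solvent fraction {phi:.3f} outside [0, 1]: "
                "over-packed headgroups (A_mol too small)"
            )


@dataclass
class ReflectivityCurve:
    """Measured or synthetic R(Qz) for one isotopic contrast.

    ``dq`` holds 1-sigma Qz resolution widths (may be None for unsmeared or
    constant-dQ/Q treatment).
    """

    qz: np.ndarray
    R: np.ndarray
    dR: np.ndarray
    contrast: str
    dq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.qz = np.asarray(self.qz, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.dR = np.asarray(self.dR, dtype=float)
        if not (len(self.qz) == len(self.R) == len(self.dR)):
            raise ValueError("qz, R, dR must have equal length")
        if np.any(self.qz <= 0) or np.any(np.diff(self.qz) <= 0):
            raise ValueError("qz must be positive and strictly increasing")
        if np.any(self.dR < 0):
            raise ValueError("dR must be non-negative")


def qz_from_angle(theta_deg: float, lam: float) -> float:
    """Specular momentum transfer ``Qz = 4 pi sin(theta) / lambda`` (A^-1)."""
    if lam <= 0.0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi * math.sin(math.radians(theta_deg)) / lam


def lipid_to_slabs(model: LipidMonolayerModel, contrast: str) -> List[Slab]:
    """Emit the air | tails | heads | subphase stack for one contrast.

    The head-layer SLD is the volume-weighted mix of headgroup material and
    subphase solvent; the single capillary roughness applies to all three
    interfaces.
    """
    model.validate()
    if contrast not in model.sld_subphase:
        raise KeyError(f"unknown contrast {contrast!r}")
    sld_sub = model.sld_subphase[contrast]
    phi = model.head_solvent_fraction
    sld_head_eff = (1.0 - phi) * model.sld_head + phi * sld_sub
    return [
        Slab(0.0, 0.0, 0.0),  # incident medium: air
        Slab(model.d_AC, model.sld_AC, model.sigma, 0.0),
        Slab(model.d_head, sld_head_eff, model.sigma, phi),
        Slab(0.0, sld_sub, model.sigma),  # semi-infinite subphase
    ]


def abeles_reflectivity(stack: Sequence[Slab], qz: np.ndarray) -> np.ndarray:
    """Transfer-matrix specular reflectivity with Nevot-Croce roughness.

    ``stack[0]`` is the incident medium, ``stack[-1]`` the semi-infinite
    substrate; intermediate thicknesses must be finite.
    """
    qz = np.atleast_1d(np.asarray(qz, dtype=float))
    if np.any(qz <= 0):
        raise ValueError("qz must be positive")
    n = len(stack)
    if n < 2:
        raise ValueError("need at least incident medium and substrate")
    sld0 = stack[0].sld
    k0 = qz / 2.0
    kz = np.empty((n, len(qz)), dtype=complex)
    for m, slab in enumerate(stack):
        kz[m] = np.sqrt(k0**2 - 4.0e-6 * np.pi * (slab.sld - sld0) + 0j)

    # accumulate the characteristic matrix
    M00 = np.ones(len(qz), dtype=complex)
    M01 = np.zeros(len(qz), dtype=complex)
    M10 = np.zeros(len(qz), dtype=complex)
    M11 = np.ones(len(qz), dtype=complex)
    for m in range(n - 1):
        ka, kb = kz[m], kz[m + 1]
        denom = ka + kb
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom != 0, (ka - kb) / denom, 0.0)
        sig = stack[m + 1].roughness
        if sig > 0.0:
            r = r * np.exp(-2.0 * ka * kb * sig**2)
        beta = 1j * ka * stack[m].thickness if m > 0 else 0.0
        ep, em = np.exp(beta), np.exp(-beta)
        a00, a01 = ep, r * ep
        a10, a11 = r * em, em
        M00, M01, M10, M11 = (
            M00 * a00 + M10 * a01,
            M01 * a00 + M11 * a01,
            M00 * a10 + M10 * a11,
            M01 * a10 + M11 * a11,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(M00 != 0, np.abs(M10 / M00) ** 2, 1.0)
    return np.clip(refl.real, 0.0, 1.0)


def smear_resolution(
    reflectivity_fn: Callable[[np.ndarray], np.ndarray],
    qz: np.ndarray,
    dq_over_q: float,
    n_gauss: int = 17,
    width: float = 3.5,
) -> np.ndarray:
    """Constant relative resolution smearing, FWHM = ``dq_over_q * Qz``.

    Convolves the model with a Gaussian of width proportional to Qz by
    fixed-order Gauss-Legendre quadrature over ``+- width`` sigma;
    ``dq_over_q = 0`` returns the unsmeared model.
    """
    qz = np.atleast_1d(np.asarray(qz, dtype=float))
    if dq_over_q < 0.0:
        raise ValueError("dq_over_q must be non-negative")
    if dq_over_q == 0.0:
        return reflectivity_fn(qz)
    x, wq = np.polynomial.legendre.leggauss(n_gauss)
    x = x * width  # nodes in sigma units
    gauss = np.exp(-0.5 * x**2)
    wts = wq * gauss
    wts = wts / np.sum(wts)
    sigma = dq_over_q * qz / _FWHM
    out = np.zeros_like(qz)
    for xi, wi in zip(x, wts):
        q_shift = np.maximum(qz + xi * sigma, 1e-8)
        out += wi * reflectivity_fn(q_shift)
    return out


def reflectivity_model(
    model: LipidMonolayerModel,
    contrast: str,
    qz: np.ndarray,
    dq_over_q: float = 0.07,
) -> np.ndarray:
    """Smeared model reflectivity plus constant background for one contrast."""
    stack = lipid_to_slabs(model, contrast)
    bkg = model.background.get(contrast, 0.0)
    return (
        smear_resolution(lambda q: abeles_reflectivity(stack, q), qz, dq_over_q)
        + bkg
    )


@dataclass
class FitResult:
    """Co-refinement output: fitted model, uncertainties and diagnostics."""

    model: LipidMonolayerModel
    params: Dict[str, float]
    sigmas: Dict[str, float]
    chi2_per_curve: Dict[str, float]
    chi2: float
    n_points: int
    success: bool


def _get_param(model: LipidMonolayerModel, name: str) -> float:
    if ":" in name:
        base, contrast = name.split(":", 1)
        return getattr(model, base)[contrast]
    return getattr(model, name)


def _set_param(model: LipidMonolayerModel, name: str, value: float) -> None:
    if ":" in name:
        base, contrast = name.split(":", 1)
        getattr(model, base)[contrast] = value
    else:
        setattr(model, name, value)


_DEFAULT_BOUNDS = {
    "A_mol": (30.0, 120.0),
    "sigma": (0.5, 12.0),
    "d_head": (5.0, 15.0),
    "sld_subphase": (-0.6, 6.5),
    "background": (0.0, 1e-4),
}


def corefine(
    curves: Sequence[ReflectivityCurve],
    model: LipidMonolayerModel,
    vary: Optional[Sequence[str]] = None,
    dq_over_q: float = 0.07,
    n_starts: int = 3,
) -> FitResult:
    """Co-refine one structural model against all contrasts simultaneously.

    ``vary`` lists free parameter names (``"A_mol"``, ``"sigma"``,
    ``"sld_subphase:<contrast>"``, ``"background:<contrast>"`` ...).  By
    default the area per molecule and the subphase SLD of every
    non-contrast-matched subphase are free, everything else (literature
    molecular volumes, capillary roughness, backgrounds) stays fixed.
    Weighted least squares with a small multi-start over A_mol to dodge
    fringe-aliasing local minima; 1-sigma uncertainties from the local
    quadratic (J^T J) approximation at the optimum.
    """
    if len(curves) == 0:
        raise ValueError("need at least one reflectivity curve")
    if vary is None:
        vary = ["A_mol"] + [
            f"sld_subphase:{c.contrast}"
            for c in curves
            if abs(model.sld_subphase.get(c.contrast, 0.0)) > 0.5
        ]
    vary = list(vary)

    def make_model(x: np.ndarray) -> LipidMonolayerModel:
        m = replace(
            model,
            sld_subphase=dict(model.sld_subphase),
            background=dict(model.background),
        )
        for name, val in zip(vary, x):
            _set_param(m, name, float(val))
        return m

    def residuals(x: np.ndarray) -> np.ndarray:
        m = make_model(x)
        out = []
        for c in curves:
            Rm = reflectivity_model(m, c.contrast, c.qz, dq_over_q)
            w = np.where(c.dR > 0, c.dR, np.maximum(1e-3 * np.abs(c.R), 1e-12))
            out.append((Rm - c.R) / w)
        return np.concatenate(out)

    x0 = np.array([_get_param(model, n) for n in vary], dtype=float)
    lo = np.array([_DEFAULT_BOUNDS.get(n.split(":")[0], (-np.inf, np.inf))[0] for n in vary])
    hi = np.array([_DEFAULT_BOUNDS.get(n.split(":")[0], (-np.inf, np.inf))[1] for n in vary])
    x0 = np.clip(x0, lo, hi)

    best = None
    factors = [1.0, 0.9, 1.1][: max(1, n_starts)]
    for fac in factors:
        xs = x0.copy()
        for i, name in enumerate(vary):
            if name == "A_mol":
                xs[i] = np.clip(x0[i] * fac, lo[i], hi[i])
        try:
            res = least_squares(residuals, xs, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("co-refinement failed from every start")

    m_fit = make_model(best.x)
    # parameter sigmas from the quadratic approximation
    J = best.jac
    dof = max(len(best.fun) - len(vary), 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        sig = np.full(len(vary), np.nan)

    chi2_per_curve = {}
    pos = 0
    for c in curves:
        k = len(c.qz)
        chi2_per_curve[c.contrast] = float(
            np.sum(best.fun[pos : pos + k] ** 2)
        )
        pos += k
    return FitResult(
        model=m_fit,
        params={n: float(v) for n, v in zip(vary, best.x)},
        sigmas={n: float(s) for n, s in zip(vary, sig)},
        chi2_per_curve=chi2_per_curve,
        chi2=float(2.0 * best.cost),
        n_points=len(best.fun),
        success=bool(best.success),
    )


def _slab_indicator(
    z: np.ndarray, z_top: float, z_bot: float, sigma: float
) -> np.ndarray:
    """Error-function-broadened indicator of the region z_top < z < z_bot
    (z increases downward into the subphase)."""
    from scipy.special import erf

    s = max(sigma, 1e-12) * math.sqrt(2.0)
    return 0.5 * (erf((z - z_top) / s) - erf((z - z_bot) / s))


def volume_fraction_profile(
    model: LipidMonolayerModel,
    contrast: str,
    z: np.ndarray,
) -> Dict[str, np.ndarray]:
    """Roughness-broadened component volume fractions versus depth.

    ``z`` is measured from the air-tails dividing surface, positive into the
    subphase.  Components: air, tails, heads (lipid material only) and water
    (head-layer solvent plus subphase).  Fractions sum to one at every z.
    """
    model.validate()
    z = np.asarray(z, dtype=float)
    d1 = model.d_AC
    d2 = d1 + model.d_head
    phi = model.head_solvent_fraction
    s = model.sigma
    from scipy.special import erf

    sq = max(s, 1e-12) * math.sqrt(2.0)
    f_air = 0.5 * (1.0 - erf(z / sq))
    f_tail_slab = _slab_indicator(z, 0.0, d1, s)
    f_head_slab = _slab_indicator(z, d1, d2, s)
    f_sub = 0.5 * (1.0 + erf((z - d2) / sq))
    return {
        "air": f_air,
        "tails": f_tail_slab,
        "heads": (1.0 - phi) * f_head_slab,
        "water": phi * f_head_slab + f_sub,
    }


def sld_profile(
    model: LipidMonolayerModel,
    contrast: str,
    z: np.ndarray,
) -> np.ndarray:
    """Roughness-broadened SLD depth profile of the slab stack (1e-6 A^-2)."""
    fr = volume_fraction_profile(model, contrast, z)
    sld_sub = model.sld_subphase[contrast]
    return (
        fr["tails"] * model.sld_AC
        + fr["heads"] * model.sld_head
        + fr["water"] * sld_sub
    )


def acmw_fraction(sld_d2o: float = 6.36, sld_h2o: float = -0.56) -> float:
    """D2O volume fraction of air-contrast-matched water (zero net SLD).

    Solves ``x sld_d2o + (1 - x) sld_h2o = 0``; with the standard SLDs the
    mixture is ~8.1% D2O by volume, consistent with the usual ~8% recipes to
    within the convention (volume vs mass) used to quote them.
    """
    if not (sld_d2o > 0.0 > sld_h2o):
        raise ValueError("require sld_d2o > 0 > sld_h2o")
    return -sld_h2o / (sld_d2o - sld_h2o)


def acmw_mass_fraction(sld_d2o: float = 6.36, sld_h2o: float = -0.56) -> float:
    """D2O mass fraction of ACMW (volume fraction times the density ratio)."""
    x = acmw_fraction(sld_d2o, sld_h2o)
    rho_d2o, rho_h2o = 1.107, 0.998  # g/cm^3 near room temperature
    return x * rho_d2o / (x * rho_d2o + (1.0 - x) * rho_h2o)


def simulate_curves(
    model: LipidMonolayerModel,
    contrasts: Sequence[str] = ("acmw", "d2o"),
    qmin: float = 0.01,
    qmax: float = 0.35,
    n_points: int = 120,
    noise: float = 0.05,
    dq_over_q: float = 0.07,
    seed: int = 0,
) -> List[ReflectivityCurve]:
    """Synthetic multi-contrast reflectivity with relative Gaussian noise.

    Log-spaced Qz grid over a typical time-of-flight span; ``noise`` is the
    relative 1-sigma counting uncertainty applied to the smeared model.
    """
    rng = np.random.default_rng(seed)
    qz = np.geomspace(qmin, qmax, n_points)
    out = []
    for c in contrasts:
        R_true = reflectivity_model(model, c, qz, dq_over_q)
        dR = noise * R_true
        R_obs = R_true + rng.normal(0.0, 1.0, n_points) * dR
        out.append(
            ReflectivityCurve(
                qz=qz, R=R_obs, dR=dR, contrast=c,
                dq=dq_over_q * qz / _FWHM,
            )
        )
    return out
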