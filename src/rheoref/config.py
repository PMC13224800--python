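"""Run configuration, file formats and provenance headers.

A run is described by one YAML or JSON document with blocks for the cell
geometry, probe dynamics, fluid phases, signal calibration, inversion
tolerances, the synthetic-instrument settings and the monolayer model.
Unknown keys are rejected so silent typos cannot change a run, and every
output file carries the configuration hash, package version and seed, making
reruns byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import AIR, WATER, DWRGeometry, FluidPhase, ProbeDynamics, g1_coefficient
from .inversion import AmplitudeRatio, InterfaceState, InversionOptions
from .reflectometry import LipidMonolayerModel, ReflectivityCurve
from .signals import ChannelCalibration, RawRecord
from .synthetic import SimulationSpec

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_record",
    "read_record",
    "write_ort",
    "read_ort",
    "results_table",
]

_ALLOWED = {
    "geometry": {"R_i", "R4", "R5", "R_o", "diagonal", "depth", "a"},
    "dynamics": {"I", "g1"},
    "fluids": {
        "eta_sub",
        "rho_sub",
        "eta_top",
        "rho_top",
        "surface_tension",
        "two_phase",
    },
    "signals": {
        "gain_theta",
        "gain_torque_lo",
        "gain_torque_hi",
        "adc_bits",
        "v_range",
        "trigger_threshold",
        "discard_fraction",
    },
    "inversion": {"resolution", "tol", "max_iter"},
    "simulation": {
        "f_list",
        "G_storage",
        "G_loss",
        "strain_target",
        "n_periods",
        "fs",
        "noise_sd",
    },
    "reflectometry": {
        "A_mol",
        "V_AC",
        "V_head",
        "d_head",
        "sld_AC",
        "sld_head",
        "sigma",
        "sld_subphase",
        "background",
        "dq_over_q",
        "vary",
        "noise",
    },
}
_TOP = set(_ALLOWED) | {"seed", "output_dir"}


@dataclass
class RunConfig:
    """Validated, resolved configuration for one analysis run."""

    raw: Dict[str, Any]
    seed: int = 0
    output_dir: str = "."

    @property
    def geometry(self) -> DWRGeometry:
        g = self.raw.get("geometry", {})
        return DWRGeometry(
            R_i=g.get("R_i", 20.0e-3),
            R4=g.get("R4", 23.0e-3),
            R5=g.get("R5", 24.0e-3),
            R_o=g.get("R_o", 28.79e-3),
            diagonal=g.get("diagonal", 1.0e-3),
            depth=g.get("depth", 5.0e-3),
            a=g.get("a"),
        )

    @property
    def dynamics(self) -> ProbeDynamics:
        d = self.raw.get("dynamics", {})
        I = d.get("I", 1.0e-5)
        g1 = d.get("g1") or g1_coefficient(self.geometry)
        return ProbeDynamics(I=I, g1=g1)

    @property
    def subphase(self) -> FluidPhase:
        f = self.raw.get("fluids", {})
        return FluidPhase(
            eta=f.get("eta_sub", WATER.eta),
            rho=f.get("rho_sub", WATER.rho),
            surface_tension=f.get("surface_tension", WATER.surface_tension),
        )

    @property
    def top_phase(self) -> Optional[FluidPhase]:
        f = self.raw.get("fluids", {})
        if not f.get("two_phase", False):
            return None
        return FluidPhase(eta=f.get("eta_top", AIR.eta), rho=f.get("rho_top", AIR.rho))

    @property
    def calibration(self) -> ChannelCalibration:
        s = self.raw.get("signals", {})
        return ChannelCalibration(
            gain_theta=s.get("gain_theta", 600.0),
            gain_torque_lo=s.get("gain_torque_lo", 1.0e4),
            gain_torque_hi=s.get("gain_torque_hi", 1.0e6),
            adc_bits=s.get("adc_bits", 16),
            v_range=s.get("v_range", 10.0),
        )

    @property
    def trigger_threshold(self) -> float:
        return self.raw.get("signals", {}).get("trigger_threshold", 2.5)

    @property
    def discard_fraction(self) -> float:
        return self.raw.get("signals", {}).get("discard_fraction", 0.2)

    @property
    def inversion_options(self) -> InversionOptions:
        i = self.raw.get("inversion", {})
        return InversionOptions(
            resolution=i.get("resolution", 16),
            tol=i.get("tol", 1e-6),
            max_iter=i.get("max_iter", 100),
            two_phase=self.raw.get("fluids", {}).get("two_phase", False),
        )

    def simulation_spec(self) -> SimulationSpec:
        s = self.raw.get("simulation", {})
        return SimulationSpec(
            G_storage=s.get("G_storage", 0.0),
            G_loss=s.get("G_loss", 5.0e-4),
            f_list=s.get("f_list", [0.5]),
            strain_target=s.get("strain_target", 0.03),
            n_periods=s.get("n_periods", 10),
            fs=s.get("fs", 100.0),
            noise_sd=s.get("noise_sd", 0.0),
            seed=self.seed,
            geom=self.geometry,
            I=self.raw.get("dynamics", {}).get("I", 1.0e-5),
            subphase=self.subphase,
            calib=self.calibration,
            mesh_resolution=self.inversion_options.resolution,
        )

    def monolayer_model(self) -> LipidMonolayerModel:
        r = self.raw.get("reflectometry", {})
        m = LipidMonolayerModel()
        for key in (
            "A_mol", "V_AC", "V_head", "d_head", "sld_AC", "sld_head", "sigma",
        ):
            if key in r:
                setattr(m, key, r[key])
        if "sld_subphase" in r:
            m.sld_subphase = dict(r["sld_subphase"])
        if "background" in r:
            m.background = dict(r["background"])
        return m

    @property
    def dq_over_q(self) -> float:
        return self.raw.get("reflectometry", {}).get("dq_over_q", 0.07)


def _validate(doc: Dict[str, Any]) -> None:
    for key, val in doc.items():
        if key not in _TOP:
            raise ValueError(f"unknown configuration key {key!r}")
        if key in _ALLOWED:
            if not isinstance(val, dict):
                raise ValueError(f"block {key!r} must be a mapping")
            bad = set(val) - _ALLOWED[key]
            if bad:
                raise ValueError(
                    f"unknown key(s) {sorted(bad)} in block {key!r}"
                )


def load_config(path: Optional[str | Path] = None, doc: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML/JSON config file (or an in-memory mapping)."""
    if doc is None:
        if path is None:
            doc = {}
        else:
            text = Path(path).read_text()
            doc = yaml.safe_load(text) or {}
    _validate(doc)
    return RunConfig(
        raw=doc,
        seed=int(doc.get("seed", 0)),
        output_dir=doc.get("output_dir", "."),
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(cfg: Optional[RunConfig], extra: Dict[str, Any]) -> List[str]:
    lines = [f"# rheoref {__version__}"]
    if cfg is not None:
        lines.append(f"# config_hash: {config_hash(cfg)}")
        lines.append(f"# seed: {cfg.seed}")
    for k, v in extra.items():
        lines.append(f"# {k}: {v}")
    return lines


def write_record(
    path: str | Path,
    rec: RawRecord,
    cfg: Optional[RunConfig] = None,
    truth: Optional[Sequence[AmplitudeRatio]] = None,
) -> None:
    """Write a raw record as a TSV with provenance header; ground truth (if
    given) goes to a JSON sidecar next to it."""
    path = Path(path)
    cal = rec.calib
    extra = {
        "fs_Hz": rec.fs,
        "gain_theta_V_per_rad": cal.gain_theta,
        "gain_torque_lo_V_per_Nm": cal.gain_torque_lo,
        "gain_torque_hi_V_per_Nm": cal.gain_torque_hi,
        "adc_bits": cal.adc_bits,
        "v_range_V": cal.v_range,
        "columns": "t v_theta v_torque_lo v_torque_hi v_trigger",
    }
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(cfg, extra)) + "\n")
        data = np.column_stack(
            [rec.t, rec.v_theta, rec.v_torque_lo, rec.v_torque_hi, rec.v_trigger]
        )
        np.savetxt(fh, data, fmt="%.10g", delimiter="\t")
    if truth is not None:
        side = {
            "measurements": [
                {
                    "f_Hz": m.omega / (2.0 * np.pi),
                    "Re_AR": m.AR.real,
                    "Im_AR": m.AR.imag,
                    "strain": m.strain,
                    "G_storage": m.truth.G_storage if m.truth else None,
                    "G_loss": m.truth.G_loss if m.truth else None,
                }
                for m in truth
            ]
        }
        Path(str(path) + ".truth.json").write_text(json.dumps(side, indent=1))


def read_record(path: str | Path) -> RawRecord:
    """Read a TSV raw record written by :func:`write_record`."""
    path = Path(path)
    meta: Dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if line.strip():
                rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    if arr.shape[1] != 5:
        raise ValueError(
            f"{path}: expected 5 columns (t, v_theta, v_torque_lo, "
            f"v_torque_hi, v_trigger), found {arr.shape[1]}"
        )
    cal = ChannelCalibration(
        gain_theta=float(meta.get("gain_theta_V_per_rad", 600.0)),
        gain_torque_lo=float(meta.get("gain_torque_lo_V_per_Nm", 1.0e4)),
        gain_torque_hi=float(meta.get("gain_torque_hi_V_per_Nm", 1.0e6)),
        adc_bits=int(float(meta.get("adc_bits", 16))),
        v_range=float(meta.get("v_range_V", 10.0)),
    )
    return RawRecord(
        t=arr[:, 0],
        v_theta=arr[:, 1],
        v_torque_lo=arr[:, 2],
        v_torque_hi=arr[:, 3],
        v_trigger=arr[:, 4],
        fs=float(meta.get("fs_Hz", 1.0 / np.median(np.diff(arr[:, 0])))),
        calib=cal,
    )


def write_ort(
    path: str | Path,
    curve: ReflectivityCurve,
    cfg: Optional[RunConfig] = None,
) -> None:
    """Write a reflectivity curve as ORSO-style ASCII (Qz, R, dR[, dQz])."""
    cols = [curve.qz, curve.R, curve.dR]
    names = "Qz_1/A R dR"
    if curve.dq is not None:
        cols.append(curve.dq)
        names += " dQz_1/A"
    extra = {"contrast": curve.contrast, "columns": names}
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(cfg, extra)) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.8g")


def read_ort(path: str | Path, contrast: Optional[str] = None) -> ReflectivityCurve:
    """Read an ORSO-style ASCII reflectivity file (3 or 4 columns)."""
    path = Path(path)
    meta: Dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{ln}: need at least 3 columns (Qz, R, dR)"
                )
            rows.append([float(x) for x in parts[:4]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.asarray([r[:ncol] for r in rows])
    return ReflectivityCurve(
        qz=arr[:, 0],
        R=arr[:, 1],
        dR=arr[:, 2],
        dq=arr[:, 3] if ncol >= 4 else None,
        contrast=contrast or meta.get("contrast", Path(path).stem),
    )


def results_table(
    states: Sequence[InterfaceState],
    measurements: Sequence[AmplitudeRatio],
) -> pd.DataFrame:
    """Tabulate inverted interface states alongside their measurements."""
    rows = []
    for st, m in zip(states, measurements):
        rows.append(
            {
                "f_Hz": st.omega / (2.0 * np.pi),
                "strain": m.strain,
                "Re_AR": m.AR.real,
                "Im_AR": m.AR.imag,
                "Bo_re": st.Bo.real,
                "Bo_im": st.Bo.imag,
                "G_prime": st.G_storage,
                "G_loss": st.G_loss,
                "sigma_G_prime": st.sigma_G[0] if st.sigma_G else 0.0,
                "sigma_G_loss": st.sigma_G[1] if st.sigma_G else 0.0,
                "inertia_limited": st.inertia_limited,
                "n_iter": st.n_iter,
            }
        )
    return pd.DataFrame(rows)
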