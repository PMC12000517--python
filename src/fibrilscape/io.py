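"""Plain-text readers and writers for the pipeline's file dialects.

* SAXS profiles: whitespace-separated columns q, I, [sigma]; ``#``
  comment/header lines; q in nm^-1 (a flag converts from inverse
  Angstrom on read).
* TEM widths: CSV with columns condition, width_nm [, fibril_id].
* Kinetics: CSV with columns time_h, well, condition, signal.
* 1D spectra: two whitespace-separated columns ppm, intensity with
  ``#`` comments.

Writers emit exactly the dialects the readers consume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ThTCurve
from .saxs_model import SAXSProfile
from .ssnmr import NMRSpectrum1D
from .tem import WidthSample

__all__ = [
    "read_saxs_profile", "write_saxs_profile",
    "read_width_samples", "write_width_samples",
    "read_tht_curves", "write_tht_curves",
    "read_nmr_spectrum", "write_nmr_spectrum",
]


def read_saxs_profile(path, label: str = "",
                      q_unit: str = "nm^-1") -> SAXSProfile:
    """Read a 3-column (q, I, [sigma]) text profile.

    ``q_unit="A^-1"`` converts inverse-Angstrom grids to nm^-1 (x10).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    q = data[:, 0]
    if q_unit == "A^-1":
        q = q * 10.0
    elif q_unit != "nm^-1":
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSProfile(q, data[:, 1], sigma, label=label or Path(path).stem)


def write_saxs_profile(path, profile: SAXSProfile) -> None:
    cols = [profile.q, profile.intensity]
    header = "q[nm^-1] I[a.u.]"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma[a.u.]"
    if profile.label:
        header = f"{profile.label}\n{header}"
    np.savetxt(path, np.column_stack(cols), header=header)


def read_width_samples(path) -> dict[str, WidthSample]:
    """Read a width CSV into one WidthSample per condition."""
    df = pd.read_csv(path)
    required = {"condition", "width_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: width CSV needs columns {sorted(required)}")
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        ids = grp["fibril_id"].to_numpy() if "fibril_id" in df.columns else None
        out[str(cond)] = WidthSample(condition=str(cond),
                                     widths=grp["width_nm"].to_numpy(),
                                     fibril_ids=ids)
    return out


def write_width_samples(path, samples: list[WidthSample]) -> None:
    frames = []
    for s in samples:
        d = {"condition": s.condition, "width_nm": s.widths}
        if s.fibril_ids is not None:
            d["fibril_id"] = s.fibril_ids
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tht_curves(path) -> list[ThTCurve]:
    """Read a kinetics CSV into one curve per (well, condition)."""
    df = pd.read_csv(path)
    required = {"time_h", "well", "condition", "signal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: kinetics CSV needs columns {sorted(required)}")
    curves = []
    for (well, cond), grp in df.groupby(["well", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(ThTCurve(grp["time_h"].to_numpy(),
                               grp["signal"].to_numpy(),
                               replicate_id=str(well), condition=str(cond)))
    return curves


def write_tht_curves(path, curves: list[ThTCurve]) -> None:
    frames = [pd.DataFrame({"time_h": c.time_h, "well": c.replicate_id,
                            "condition": c.condition, "signal": c.signal})
              for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_nmr_spectrum(path, label: str = "") -> NMRSpectrum1D:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (ppm, intensity)")
    return NMRSpectrum1D(data[:, 0], data[:, 1],
                         label=label or Path(path).stem)


def write_nmr_spectrum(path, spec: NMRSpectrum1D) -> None:
    header = "ppm intensity[a.u.]"
    if spec.label:
        header = f"{spec.label}\n{header}"
    np.savetxt(path, np.column_stack([spec.ppm, spec.intensity]), header=header)
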