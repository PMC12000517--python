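"""Window integration of 1D solid-state NMR spectra.

Cross-polarization (CP) 13C spectra of huntingtin exon-1 fibrils show
three diagnostic aliphatic regions: Pro C-alpha, Gln C-alpha and Pro
C-delta.  Integrating each window and normalizing by the maximum
intensity of the Gln C-alpha peak gives a Q/P ratio that reports the
rigidity of the proline-rich flanking domain relative to the
polyglutamine core: a drop in Q/P means relatively more CP signal from
prolines, i.e. a more rigid fuzzy coat.

Two window schemes are shipped, matching the integration bounds used
for the two independently prepared fibril batches (referencing differs
slightly between them):

* batch 1: PCa 68.31-60.68, QCa 60.68-53.40, PCd 53.40-47.78 ppm
* batch 2: PCa 66.70-58.99, QCa 58.99-51.79, PCd 51.79-46.01 ppm

Integration is trapezoidal on the native ppm grid, with no resampling
and no baseline correction by default (an optional linear baseline can
be subtracted).  Error bars derive from the noise level of a
signal-free region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMRSpectrum1D", "IntegrationWindow", "BATCH1_SCHEME",
           "BATCH2_SCHEME", "SCHEMES", "integrate_window", "qp_ratios",
           "noise_error"]


@dataclass
class NMRSpectrum1D:
    """A ppm-indexed 1D intensity trace.

    The axis may be stored ascending or descending; it is normalized
    internally to descending ppm (the plotting convention).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1D arrays")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending: flip to descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def ppm_range(self) -> tuple[float, float]:
        """(low, high) ppm extent."""
        return float(self.ppm[-1]), float(self.ppm[0])

    def slice(self, ppm_lo: float, ppm_hi: float) -> "NMRSpectrum1D":
        m = (self.ppm >= ppm_lo) & (self.ppm <= ppm_hi)
        if m.sum() < 2:
            raise ValueError(f"fewer than 2 points in [{ppm_lo}, {ppm_hi}] ppm")
        return NMRSpectrum1D(self.ppm[m], self.intensity[m], self.label)


@dataclass(frozen=True)
class IntegrationWindow:
    """A named ppm range, bounds given high-field to low-field."""

    name: str
    ppm_hi: float
    ppm_lo: float

    def __post_init__(self) -> None:
        if self.ppm_hi <= self.ppm_lo:
            raise ValueError("ppm_hi must exceed ppm_lo")


# integration bounds for the two fibril batches (ppm)
BATCH1_SCHEME = (
    IntegrationWindow("PCa", 68.31, 60.68),
    IntegrationWindow("QCa", 60.68, 53.40),
    IntegrationWindow("PCd", 53.40, 47.78),
)
BATCH2_SCHEME = (
    IntegrationWindow("PCa", 66.70, 58.99),
    IntegrationWindow("QCa", 58.99, 51.79),
    IntegrationWindow("PCd", 51.79, 46.01),
)
SCHEMES = {"batch1": BATCH1_SCHEME, "batch2": BATCH2_SCHEME}


def _check_scheme(scheme) -> dict[str, IntegrationWindow]:
    by_name = {w.name: w for w in scheme}
    missing = {"PCa", "QCa", "PCd"} - set(by_name)
    if missing:
        raise ValueError(f"scheme is missing windows: {sorted(missing)}")
    return by_name


def integrate_window(spec: NMRSpectrum1D, w: IntegrationWindow,
                     baseline: bool = False) -> float:
    """Trapezoidal integral of intensity over the window, a.u. * ppm.

    With ``baseline=True`` a straight line through the window's two end
    points is subtracted first.
    """
    lo, hi = spec.ppm_range
    if w.ppm_lo < lo or w.ppm_hi > hi:
        raise ValueError(
            f"window {w.name} [{w.ppm_lo}, {w.ppm_hi}] outside spectral "
            f"range [{lo:.2f}, {hi:.2f}] ppm")
    sub = spec.slice(w.ppm_lo, w.ppm_hi)
    x = sub.ppm[::-1]  # ascending for integration
    y = sub.intensity[::-1]
    if baseline:
        y = y - np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    return float(np.trapezoid(y, x))


def qp_ratios(spec: NMRSpectrum1D, scheme=BATCH1_SCHEME,
              noise_floor: float = 0.0) -> dict[str, float]:
    """Normalized window areas and Gln/Pro area ratios.

    Each window's area is divided by the maximum point intensity inside
    the QCa window (the tallest polyQ core signal).  The returned dict
    also carries the area ratios ``QCa:PCa`` and ``QCa:PCd`` — the Q/P
    ratios whose decrease signals a rigidified proline-rich domain.
    """
    by_name = _check_scheme(scheme)
    qca = by_name["QCa"]
    sub = spec.slice(qca.ppm_lo, qca.ppm_hi)
    qca_max = float(sub.intensity.max())
    if qca_max <= noise_floor:
        raise ValueError("QCa maximum does not rise above the noise floor")
    areas = {name: integrate_window(spec, w) for name, w in by_name.items()}
    out = {f"{name}_norm": area / qca_max for name, area in areas.items()}
    out["QCa:PCa"] = areas["QCa"] / areas["PCa"]
    out["QCa:PCd"] = areas["QCa"] / areas["PCd"]
    out["QCa_max"] = qca_max
    return out


def noise_error(spec: NMRSpectrum1D, signal_free_region: tuple[float, float],
                scheme=BATCH1_SCHEME) -> dict[str, float]:
    """Window-area uncertainties from the noise of a signal-free region.

    The noise sd is the sample standard deviation over
    ``signal_free_region`` (ppm_lo, ppm_hi), which must not overlap any
    integration window.  For white noise the trapezoidal area over n
    points of spacing dppm has sd  noise_sd * dppm * sqrt(n).
    """
    lo, hi = sorted(signal_free_region)
    by_name = _check_scheme(scheme)
    for w in by_name.values():
        if lo < w.ppm_hi and hi > w.ppm_lo:
            raise ValueError(
                f"signal-free region [{lo}, {hi}] overlaps window {w.name}")
    region = spec.slice(lo, hi)
    sd = float(np.std(region.intensity, ddof=1))
    step = float(np.median(np.abs(np.diff(spec.ppm))))
    out = {}
    for name, w in by_name.items():
        n_pts = int(np.sum((spec.ppm >= w.ppm_lo) & (spec.ppm <= w.ppm_hi)))
        out[name] = sd * step * np.sqrt(n_pts)
    out["noise_sd"] = sd
    return out
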