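"""Seeded generators emulating each instrument input of the pipeline.

Every generator is a pure function of its parameters and a seed: the
same call yields bit-identical output.  The generators reproduce the
statistical structure each analysis stage assumes —

* SAXS: forward simulation of the full bundle model with multiplicative
  (counting-like) or additive noise; default 2% multiplicative.
* TEM: per-condition fibril-width samples, truncated normal (0.5 nm
  floor) around a condition mean, e.g. ~10 nm without inhibitor vs
  ~4 nm with.
* ThT kinetics: logistic time courses with independent lag, growth rate
  and plateau, sampled every 0.25 h as a plate reader would.
* ssNMR: 1D spectra as sums of Gaussian/Lorentzian peaks at Gln/Pro
  carbon positions plus baseline noise.

Real instrument noise (detector counting statistics, plate-reader
drift) is richer than these stand-ins; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ThTCurve
from .saxs_model import SAXSModelParams, SAXSProfile, model_intensity
from .ssnmr import NMRSpectrum1D
from .tem import WidthSample

__all__ = [
    "NoiseSpec",
    "ThTGeneratorParams",
    "NMRPeakSpec",
    "gen_saxs_curve",
    "gen_tem_widths",
    "gen_tht_curve",
    "gen_nmr_spectrum",
]


@dataclass(frozen=True)
class NoiseSpec:
    """How to perturb a clean signal.

    kind : "none", "multiplicative-gaussian" (level = fractional sd) or
        "additive-gaussian" (level = absolute sd, a.u.)
    """

    kind: str = "multiplicative-gaussian"
    level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")

    def apply(self, clean: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (noisy signal, per-point sd or None for noiseless)."""
        if self.kind == "none" or self.level == 0:
            return clean.copy(), None
        rng = np.random.default_rng(self.seed)
        g = rng.standard_normal(clean.shape)
        if self.kind == "multiplicative-gaussian":
            sigma = self.level * np.abs(clean)
        else:
            sigma = np.full(clean.shape, self.level)
        return clean + sigma * g, sigma


@dataclass(frozen=True)
class ThTGeneratorParams:
    """Shape of a synthetic aggregation time course.

    The expectation is a logistic centred at ``lag_h + 2/rate`` rising
    from ``baseline`` to ``plateau``; the tangent at the midpoint then
    intercepts the baseline exactly at ``lag_h``, so lag extraction can
    be validated by round trip.  Sampling every 0.25 h mirrors a plate
    reader recording every 15 minutes.
    """

    lag_h: float = 5.0
    rate: float = 1.5  # 1/h, logistic steepness
    plateau: float = 1.0
    baseline: float = 0.0
    sampling_interval_h: float = 0.25

    def __post_init__(self) -> None:
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.plateau <= 0:
            raise ValueError("plateau must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.plateau <= self.baseline:
            raise ValueError("plateau must exceed baseline")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be > 0")

    def expectation(self, t: np.ndarray) -> np.ndarray:
        t0 = self.lag_h + 2.0 / self.rate
        span = self.plateau - self.baseline
        return self.baseline + span / (1.0 + np.exp(-self.rate * (t - t0)))


@dataclass(frozen=True)
class NMRPeakSpec:
    """One resonance line of a synthetic 1D spectrum."""

    center_ppm: float
    width_ppm: float  # sd for gaussian, HWHM for lorentzian
    amplitude: float = 1.0  # peak height, a.u.
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width_ppm <= 0:
            raise ValueError("width_ppm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def evaluate(self, ppm: np.ndarray) -> np.ndarray:
        x = ppm - self.center_ppm
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (x / self.width_ppm) ** 2)
        return self.amplitude / (1.0 + (x / self.width_ppm) ** 2)


# ---------------------------------------------------------------------------
# generators


def gen_saxs_curve(params: SAXSModelParams, q_grid,
                   noise: NoiseSpec = NoiseSpec(kind="none"),
                   label: str = "") -> SAXSProfile:
    """Forward-simulate a 1D scattering curve of the full bundle model.

    Noiseless output is identical to :func:`model_intensity` on the same
    grid; with noise, the sigma column records the per-point noise sd.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or np.any(q <= 0):
        raise ValueError("q_grid must be 1D and strictly positive")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be strictly increasing")
    clean = model_intensity(q, params)
    noisy, sigma = noise.apply(clean)
    return SAXSProfile(q, noisy, sigma, label=label)


def gen_tem_widths(mean_nm: float, sd_nm: float, n: int, seed: int,
                   condition: str = "", floor_nm: float = 0.5) -> WidthSample:
    """Draw ``n`` fibril-width measurements, normal truncated at a
    physical floor (default 0.5 nm)."""
    if mean_nm <= 0:
        raise ValueError("mean_nm must be > 0")
    if sd_nm < 0:
        raise ValueError("sd_nm must be >= 0")
    if n < 1:
        raise ValueError("need n >= 1 measurements")
    rng = np.random.default_rng(seed)
    if sd_nm == 0:
        widths = np.full(n, float(mean_nm))
    else:
        widths = np.empty(0)
        while widths.size < n:  # rejection sampling against the floor
            draw = rng.normal(mean_nm, sd_nm, size=2 * n)
            widths = np.concatenate([widths, draw[draw >= floor_nm]])
        widths = widths[:n]
    return WidthSample(condition=condition or f"mean {mean_nm} nm",
                       widths=widths)


def gen_tht_curve(gp: ThTGeneratorParams, duration_h: float,
                  noise: NoiseSpec = NoiseSpec(kind="none"),
                  replicate_id: str = "w1", condition: str = "") -> ThTCurve:
    """Simulate one well of a fluorescence aggregation assay."""
    if duration_h <= gp.lag_h:
        raise ValueError("duration_h must exceed the lag time")
    t = np.arange(0.0, duration_h + 0.5 * gp.sampling_interval_h,
                  gp.sampling_interval_h)
    clean = gp.expectation(t)
    noisy, _ = noise.apply(clean)
    return ThTCurve(time_h=t, signal=noisy, replicate_id=replicate_id,
                    condition=condition)


def gen_nmr_spectrum(peaks: list[NMRPeakSpec], ppm_grid,
                     noise: NoiseSpec = NoiseSpec(kind="none"),
                     label: str = "") -> NMRSpectrum1D:
    """Simulate a 1D spectrum as a sum of analytic peaks plus noise."""
    ppm = np.asarray(ppm_grid, dtype=float)
    if ppm.ndim != 1 or ppm.size < 2:
        raise ValueError("ppm_grid must be a 1D array with >= 2 points")
    d = np.diff(ppm)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm_grid must be monotone")
    clean = np.zeros_like(ppm)
    for pk in peaks:
        clean += pk.evaluate(ppm)
    if noise.kind == "multiplicative-gaussian" and noise.level > 0:
        # multiplicative noise on a near-zero baseline is degenerate;
        # spectra use additive noise scaled to the tallest peak instead
        scale = float(clean.max()) if clean.max() > 0 else 1.0
        noise = NoiseSpec("additive-gaussian", noise.level * scale, noise.seed)
    noisy, _ = noise.apply(clean)
    return NMRSpectrum1D(ppm=ppm, intensity=noisy, label=label)
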