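"""Least-squares fitting of the fibril-bundle scattering model.

Fits minimize log-space residuals, sum[(log I_obs - log I_model)/w]^2:
SAXS intensities span several decades and linear residuals would weight
only the low-q plateau.  Weights come from the profile's sigma column
when present (delta method: sigma_log ~ sigma/I), else unit.

A multi-start strategy (perturbed initial guesses, best-of selection)
guards against the correlated (A, r, sigma_r) and (nu, d) directions of
the objective.  The rod length L is never fitted.

The polydisperse form factor is evaluated during fitting through a
cached table (dense log-spaced radius grid, cubic spline in ln r) built
once per (q-grid, L); interpolation error is ~1e-4 relative, negligible
against measurement noise, and the exact quadrature path is used
everywhere outside the optimizer loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .saxs_model import (
    SAXSModelParams,
    SAXSProfile,
    _p_cylinder,
    default_radius_grid,
    lognormal_weights,
    prism_structure_factor,
)

__all__ = ["FitResult", "RegionBounds", "segment_regions", "fit_model",
           "compare_conditions", "DEFAULT_BOUNDS"]

#: free parameters of the model (L is always held fixed)
_PARAM_NAMES = ("A", "r", "sigma_r", "d", "nu", "B", "n_exp", "C")

#: default fit bounds.  nu is capped at 4 to keep the PRISM structure
#: factor positive (the kernel reaches -0.2172, so 1 + nu*W > 0 needs
#: nu < 4.60).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r": (1.0, 20.0),
    "sigma_r": (0.0, 0.5),
    "d": (5.0, 60.0),
    "nu": (0.0, 4.0),
    "n_exp": (0.0, 4.0),
}

# default region boundaries (nm^-1): low / intermediate / high q
DEFAULT_Q_STAR = 0.12
DEFAULT_Q_POROD = 0.3


@dataclass(frozen=True)
class RegionBounds:
    """Boundaries splitting a profile into low / intermediate / high q."""

    q_star: float  # low -> intermediate boundary (slope change), nm^-1
    q_porod: float  # intermediate -> high (Porod) boundary, nm^-1
    method: str  # "default" or "detected"


@dataclass
class FitResult:
    params: SAXSModelParams
    stderr: dict[str, float]
    chi2_reduced: float
    converged: bool
    region_bounds: RegionBounds
    n_points: int
    label: str = ""

    @property
    def cross_section(self) -> float:
        """Fitted fibril cross-section diameter 2r, nm."""
        return 2.0 * self.params.r


# ---------------------------------------------------------------------------
# region segmentation


def _sliding_slopes(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Centered w-point OLS slopes of y(x); length len(x) - w + 1."""
    n = x.size - w + 1
    out = np.empty(n)
    for k in range(n):
        out[k] = np.polyfit(x[k:k + w], y[k:k + w], 1)[0]
    return out


def segment_regions(profile: SAXSProfile, mode: str = "auto",
                    departure: float = 0.05, porod_slope: float = -2.0,
                    persist: int = 5) -> RegionBounds:
    """Split a profile into the three canonical q-regions.

    ``mode="default"`` returns the standard boundaries (0.12, 0.3) nm^-1.
    ``mode="auto"`` runs a slope-change detector built on piecewise
    linear fits in log-log space: a power law is fitted to the low-q
    edge, and q* is the first q where log I departs from that trend
    line by more than ``departure`` (log units) for at least
    ``persist`` consecutive points — the scale at which the profile
    leaves its rod-like q^-1 decay.  The Porod boundary is the first
    subsequent q whose sliding-window local slope drops below
    ``porod_slope``.  A pure power law never departs its own trend:
    the detector reports no breakpoint and the default bounds are
    returned (method tag "default").
    """
    if profile.q[-1] / profile.q[0] < 10.0:
        raise ValueError("profile must span at least one decade in q")
    if mode not in ("auto", "default"):
        raise ValueError(f"unknown mode {mode!r}")
    default = RegionBounds(DEFAULT_Q_STAR, DEFAULT_Q_POROD, "default")
    if mode == "default":
        return default

    x = np.log(profile.q)
    y = np.log(np.maximum(profile.intensity, 1e-300))
    n = x.size
    if n < 30:
        return default
    # fit the low-q trend over the first quarter of the grid (wide
    # enough that its extrapolated slope uncertainty stays well below
    # the departure threshold) and find the first persistent departure
    n_low = max(10, n // 4)
    c1, c0 = np.polyfit(x[:n_low], y[:n_low], 1)
    dev = np.abs(y - (c0 + c1 * x)) > departure
    dev[:n_low] = False
    run = np.convolve(dev.astype(int), np.ones(persist, int), mode="valid")
    hits = np.flatnonzero(run == persist)
    if hits.size == 0:
        return default
    k_star = int(hits[0])
    q_star = float(profile.q[k_star])

    w = max(7, n // 14) | 1
    slopes = _sliding_slopes(x, y, w)
    centers = profile.q[(w - 1) // 2: (w - 1) // 2 + slopes.size]
    after = np.flatnonzero((centers > q_star) & (slopes < porod_slope))
    q_porod = float(centers[after[0]]) if after.size else DEFAULT_Q_POROD
    return RegionBounds(q_star, q_porod, "detected")


# ---------------------------------------------------------------------------
# form-factor table


class _FormFactorTable:
    """Cylinder form factor P(q, r) tabulated on a dense log-r grid and
    interpolated by a cubic spline in ln r, for fast polydispersity sums
    with q and L fixed."""

    def __init__(self, q: np.ndarray, L: float, r_lo: float, r_hi: float,
                 n_r: int = 384):
        self.q = q
        self.L = L
        self.r_lo, self.r_hi = r_lo, r_hi
        self.radii = np.geomspace(r_lo, r_hi, n_r)
        table = _p_cylinder(q, self.radii, L, per_cycle=3.0)
        self._spline = CubicSpline(np.log(self.radii), table, axis=1)

    def polydisperse(self, r_median: float, sigma_r: float) -> np.ndarray:
        radii = default_radius_grid(r_median, sigma_r)
        w = lognormal_weights(r_median, sigma_r, radii)
        lr = np.log(np.clip(radii, self.r_lo, self.r_hi))
        return self._spline(lr) @ w


_TABLE_CACHE: dict[tuple, _FormFactorTable] = {}


def _get_table(q: np.ndarray, L: float, bounds: dict) -> _FormFactorTable:
    r_lo, r_hi = bounds["r"]
    s_hi = bounds["sigma_r"][1]
    lo = r_lo * np.exp(-4.0 * s_hi)
    hi = r_hi * np.exp(4.0 * s_hi)
    key = (hash(q.tobytes()), float(L), round(lo, 9), round(hi, 9))
    if key not in _TABLE_CACHE:
        if len(_TABLE_CACHE) > 8:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = _FormFactorTable(q, L, lo, hi)
    return _TABLE_CACHE[key]


# ---------------------------------------------------------------------------
# model fitting


def _model_from_table(q: np.ndarray, p: dict, table: _FormFactorTable) -> np.ndarray:
    poly = table.polydisperse(p["r"], p["sigma_r"])
    s = prism_structure_factor(q, p["d"], p["nu"]) if p["nu"] > 0 else 1.0
    return p["A"] * poly * s + p["B"] * q ** (-p["n_exp"]) + p["C"]


def _default_bounds(init: SAXSModelParams, intensity: np.ndarray) -> dict:
    b = dict(DEFAULT_BOUNDS)
    i_max = float(np.max(intensity))
    b.setdefault("A", (init.A * 1e-3, init.A * 1e3))
    b.setdefault("B", (0.0, 10.0 * i_max))
    b.setdefault("C", (0.0, i_max))
    return b


def fit_model(profile: SAXSProfile, init: SAXSModelParams,
              fixed: set[str] | frozenset[str] = frozenset(),
              bounds: dict[str, tuple[float, float]] | None = None,
              n_starts: int = 5, seed: int = 0) -> FitResult:
    """Fit the bundle model to a profile by multi-start weighted least
    squares on log-intensity residuals.

    Parameters
    ----------
    profile : measured or simulated curve (sigma column used as weights
        when present).
    init : initial parameter guess; must lie inside ``bounds``.
    fixed : names of parameters to hold at their ``init`` value.  ``L``
        is always fixed regardless.
    bounds : per-parameter (lo, hi) overrides of :data:`DEFAULT_BOUNDS`.
    n_starts : number of starts; the first uses ``init`` verbatim, the
        rest perturb each free parameter by a log-uniform factor within
        +/-30%.  Deterministic given ``seed``.

    Never raises on non-convergence: the best attempt is returned with
    ``converged=False``.
    """
    q, i_obs = profile.q, profile.intensity
    if np.any(i_obs <= 0):
        raise ValueError("profile intensities must be positive for log-space fitting")
    log_obs = np.log(i_obs)
    w = (profile.sigma / i_obs) if profile.sigma is not None else np.ones_like(q)

    all_bounds = _default_bounds(init, i_obs)
    if bounds:
        all_bounds.update(bounds)
    fixed = set(fixed) | {"L"}
    free = [p for p in _PARAM_NAMES if p not in fixed]
    if not free:
        raise ValueError("no free parameters")
    for name in free:
        lo, hi = all_bounds[name]
        val = getattr(init, name)
        if not (lo <= val <= hi):
            raise ValueError(f"init.{name}={val} outside bounds [{lo}, {hi}]")

    table = _get_table(q, init.L, all_bounds)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        p = {k: params[k].value for k in _PARAM_NAMES}
        model = _model_from_table(q, p, table)
        return (log_obs - np.log(np.maximum(model, 1e-300))) / w

    rng = np.random.default_rng(seed)
    starts = [init]
    for _ in range(max(0, n_starts - 1)):
        kw = {}
        for name in free:
            lo, hi = all_bounds[name]
            factor = np.exp(rng.uniform(np.log(1 / 1.3), np.log(1.3)))
            val = getattr(init, name)
            base = val if val > 0 else 0.05 * (hi - lo) + lo
            kw[name] = float(np.clip(base * factor, lo + 1e-12 * (hi - lo), hi))
        try:
            starts.append(init.replace(**kw))
        except ValueError:
            starts.append(init)  # perturbation broke an invariant; reuse init

    best = None
    for start in starts:
        pars = lmfit.Parameters()
        for name in _PARAM_NAMES:
            lo, hi = all_bounds.get(name, (-np.inf, np.inf))
            pars.add(name, value=getattr(start, name), vary=name in free,
                     min=lo, max=hi)
        try:
            res = lmfit.minimize(residual, pars, method="least_squares",
                                 x_scale="jac", max_nfev=400 * len(free))
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    regions = segment_regions(profile)
    if best is None:  # every start blew up; report the unfitted init
        return FitResult(params=init, stderr={}, chi2_reduced=np.inf,
                         converged=False, region_bounds=regions,
                         n_points=len(profile), label=profile.label)

    fitted = {k: float(best.params[k].value) for k in _PARAM_NAMES}
    fitted["L"] = init.L
    stderr = {k: float(best.params[k].stderr)
              for k in free
              if best.params[k].stderr is not None and np.isfinite(best.params[k].stderr)}
    dof = max(1, len(profile) - len(free))
    return FitResult(params=SAXSModelParams(**fitted), stderr=stderr,
                     chi2_reduced=float(best.chisqr) / dof,
                     converged=bool(best.success), region_bounds=regions,
                     n_points=len(profile), label=profile.label)


def compare_conditions(fit_a: FitResult, fit_b: FitResult) -> pd.DataFrame:
    """Per-parameter comparison of two fits (e.g. with/without inhibitor).

    Differences are ``a - b`` with joint standard errors propagated in
    quadrature; a parameter is flagged when it differs by more than two
    joint standard errors.  The table also carries the derived
    cross-section diameter 2r.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged for a comparison")
    rows = []
    names = list(_PARAM_NAMES) + ["cross_section"]
    for name in names:
        if name == "cross_section":
            va, vb = fit_a.cross_section, fit_b.cross_section
            sa = 2.0 * fit_a.stderr.get("r", np.nan)
            sb = 2.0 * fit_b.stderr.get("r", np.nan)
        else:
            va = getattr(fit_a.params, name)
            vb = getattr(fit_b.params, name)
            sa = fit_a.stderr.get(name, np.nan)
            sb = fit_b.stderr.get(name, np.nan)
        diff = va - vb
        joint = float(np.hypot(sa, sb)) if np.isfinite(sa) and np.isfinite(sb) else np.nan
        flagged = bool(np.isfinite(joint) and joint > 0 and abs(diff) > 2.0 * joint)
        rows.append({"parameter": name, "value_a": va, "value_b": vb,
                     "difference": diff, "stderr_joint": joint, "flagged": flagged})
    return pd.DataFrame(rows)
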