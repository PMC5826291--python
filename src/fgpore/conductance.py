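"""Density-based ionic-conductance model for protein-coated nanopores.

A bare cylindrical pore of height l and diameter d in solution of bulk
conductivity sigma_bare has

    G(d) = sigma_bare * [4 l / (pi d^2) + 1/d]^(-1)

(pore resistance in series with the access resistance of the two solution
hemispheres).  Grafted protein reduces the local conductivity in
proportion to the local protein density,

    sigma(r) = sigma_bare * max(0, 1 - rho(r)/rho_crit),

and radial integration gives effective pore and access conductivities:

    sigma_region = (4 / pi d^2) * int_0^{d/2} 2 pi r sigma(r) dr,

which enter the generalised series formula

    G(d) = [4 l / (pi d^2 sigma_pore) + 1/(d sigma_access)]^(-1).

With vanishing density this reduces exactly to the bare-pore law.  The
fitted defaults are sigma_bare = 2.2 nS/nm and rho_crit = 85 mg/ml.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .density_analysis import RadialProfile


@dataclass
class ConductivityModel:
    sigma_bare: float = 2.2      # nS/nm
    rho_crit: float = 85.0       # mg/ml
    height: float = 20.0         # nm
    sigma_bare_err: float = math.nan
    rho_crit_err: float = math.nan

    def __post_init__(self) -> None:
        if self.sigma_bare <= 0 or self.rho_crit <= 0:
            raise ValueError("sigma_bare and rho_crit must be positive")


@dataclass
class ConductanceCurve:
    diameters: np.ndarray
    G: np.ndarray                # nS
    provenance: str              # "bare" | "density" | "sigmoid"


@dataclass
class SigmoidFit:
    """4-parameter logistic fits of sigma_pore(d) and sigma_access(d)."""

    pore_params: np.ndarray      # (lo, hi, d0, width)
    access_params: np.ndarray
    pore_residual: float
    access_residual: float
    d_range: tuple[float, float]


def local_conductivity(rho, model: ConductivityModel):
    """sigma(rho) = sigma_bare * max(0, 1 - rho/rho_crit), in nS/nm."""
    rho = np.asarray(rho, float)
    out = model.sigma_bare * np.clip(1.0 - rho / model.rho_crit, 0.0, None)
    return float(out) if out.ndim == 0 else out


def region_conductivity(
    profile: RadialProfile, model: ConductivityModel, diameter: float
) -> float:
    """Radially integrated effective conductivity of a region (nS/nm).

    sigma = (4 / pi d^2) * int 2 pi r sigma(r) dr over 0 <= r <= d/2, by
    trapezoidal quadrature on the profile grid (exact for the piecewise-
    linear profiles used in tests).  The same operation serves the pore
    (|z| < 10 nm) and the access (10 < |z| < 40 nm) windows.
    """
    half_d = diameter / 2.0
    if profile.r.max() < half_d - 1e-9:
        raise ValueError(
            f"profile extends to r={profile.r.max():.2f} nm < d/2={half_d:.2f} nm"
        )
    # integrate on the profile's own grid (plus exact endpoints) so the
    # trapezoid rule is exact for piecewise-linear profiles
    inner = profile.r[(profile.r > 0.0) & (profile.r < half_d)]
    r = np.concatenate(([0.0], inner, [half_d]))
    rho = np.interp(r, profile.r, profile.rho)
    sig = local_conductivity(rho, model)
    integral = np.trapezoid(2.0 * math.pi * r * sig, r)
    return float(4.0 / (math.pi * diameter**2) * integral)


def total_conductance(
    sigma_pore: float, sigma_access: float, diameter: float, height: float = 20.0
) -> float:
    """Series pore + access conductance (nS)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if sigma_pore < 0 or sigma_access < 0:
        raise ValueError("conductivities must be >= 0")
    if sigma_pore == 0.0 or sigma_access == 0.0:
        return 0.0
    r_pore = 4.0 * height / (math.pi * diameter**2 * sigma_pore)
    r_access = 1.0 / (diameter * sigma_access)
    return 1.0 / (r_pore + r_access)


def bare_conductance(diameter, sigma_bare: float = 2.2, height: float = 20.0):
    """Bare-pore G(d); the zero-density limit of the density-based model."""
    d = np.asarray(diameter, float)
    out = sigma_bare / (4.0 * height / (math.pi * d**2) + 1.0 / d)
    return float(out) if out.ndim == 0 else out


def predict_conductance(
    pore_profile: RadialProfile,
    access_profile: RadialProfile | None,
    model: ConductivityModel,
    diameter: float,
) -> float:
    """Density-based G for one pore from its radial profiles (nS)."""
    s_pore = region_conductivity(pore_profile, model, diameter)
    if access_profile is None:
        s_access = model.sigma_bare
    else:
        s_access = region_conductivity(access_profile, model, diameter)
    return total_conductance(s_pore, s_access, diameter, model.height)


def fit_sigma_bare(
    diameters: np.ndarray, G: np.ndarray, height: float = 20.0
) -> tuple[float, float]:
    """Least-squares sigma_bare (and s.e.) from bare-pore G(d) data."""
    diameters = np.asarray(diameters, float)
    G = np.asarray(G, float)
    if len(np.unique(diameters)) < 2:
        raise ValueError("need bare-pore data at >= 2 distinct diameters")
    popt, pcov = curve_fit(
        lambda d, s: bare_conductance(d, s, height), diameters, G, p0=[2.0]
    )
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def fit_model(
    bare_data: tuple[np.ndarray, np.ndarray],
    coated_data: tuple[np.ndarray, np.ndarray] | None = None,
    profiles: dict | None = None,
    height: float = 20.0,
) -> ConductivityModel:
    """Fit sigma_bare from bare-pore data and rho_crit from coated data.

    ``profiles`` maps diameter -> (pore RadialProfile, access RadialProfile
    or None) for the coated pores.  rho_crit is found by 1D least squares
    on the coated conductances.
    """
    d_bare, g_bare = bare_data
    if len(np.unique(np.asarray(d_bare))) < 3:
        raise ValueError("need >= 3 distinct bare-pore diameters")
    s_bare, s_err = fit_sigma_bare(d_bare, g_bare, height)
    rho_crit, rho_err = 85.0, math.nan
    if coated_data is not None:
        if profiles is None:
            raise ValueError("coated data requires density profiles per diameter")
        d_c, g_c = np.asarray(coated_data[0], float), np.asarray(coated_data[1], float)

        def sse(rc: float) -> float:
            m = ConductivityModel(s_bare, rc, height)
            pred = np.array([
                predict_conductance(profiles[d][0], profiles[d][1], m, d) for d in d_c
            ])
            return float(np.sum((pred - g_c) ** 2))

        res = minimize_scalar(sse, bounds=(10.0, 500.0), method="bounded")
        rho_crit = float(res.x)
        # curvature-based standard error
        h = 1.0
        d2 = (sse(rho_crit + h) - 2 * sse(rho_crit) + sse(rho_crit - h)) / h**2
        dof = max(len(d_c) - 1, 1)
        if d2 > 0:
            rho_err = float(math.sqrt(2.0 * sse(rho_crit) / dof / d2))
    return ConductivityModel(s_bare, rho_crit, height, s_err, rho_err)


def _logistic(d, lo, hi, d0, w):
    return lo + (hi - lo) / (1.0 + np.exp(-(d - d0) / w))


def fit_sigmoids(
    diameters: np.ndarray,
    sigma_pore: np.ndarray,
    sigma_access: np.ndarray,
    sigma_bare: float = 2.2,
) -> SigmoidFit:
    """Fit smooth 4-parameter logistic curves to per-diameter conductivities."""
    d = np.asarray(diameters, float)

    def fit_one(y):
        y = np.asarray(y, float)
        p0 = [max(y.min(), 0.0), min(y.max(), sigma_bare), np.median(d), 5.0]
        popt, _ = curve_fit(
            _logistic, d, y, p0=p0,
            bounds=([0, 0, 0, 0.1], [sigma_bare, sigma_bare, 200, 100]),
            maxfev=20000,
        )
        return popt, float(np.sqrt(np.mean((_logistic(d, *popt) - y) ** 2)))

    pp, pr = fit_one(sigma_pore)
    ap, ar = fit_one(sigma_access)
    return SigmoidFit(pp, ap, pr, ar, (float(d.min()), float(d.max())))


def closed_form_curve(
    fit: SigmoidFit,
    diameters: np.ndarray,
    height: float = 20.0,
    allow_extrapolation: bool = False,
) -> ConductanceCurve:
    """Continuous G(d) from the sigmoid conductivity fits."""
    d = np.asarray(diameters, float)
    lo, hi = fit.d_range
    if not allow_extrapolation and (d.min() < lo - 1e-9 or d.max() > hi + 1e-9):
        raise ValueError(
            f"diameters outside fitted range [{lo}, {hi}] nm; "
            "pass allow_extrapolation=True to extrapolate"
        )
    g = np.array([
        total_conductance(
            float(_logistic(x, *fit.pore_params)),
            float(_logistic(x, *fit.access_params)),
            float(x), height,
        )
        for x in d
    ])
    return ConductanceCurve(diameters=d, G=g, provenance="sigmoid")


def threshold_diameter(curve: ConductanceCurve, g_threshold: float = 4.0) -> float:
    """Smallest diameter at which G crosses the threshold (nS)."""
    above = curve.G >= g_threshold
    if not above.any():
        return math.inf
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.diameters[0])
    d0, d1 = curve.diameters[i - 1], curve.diameters[i]
    g0, g1 = curve.G[i - 1], curve.G[i]
    return float(d0 + (g_threshold - g0) * (d1 - d0) / (g1 - g0))


def read_gd_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Delimited text with columns diameter_nm, conductance_nS."""
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]
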