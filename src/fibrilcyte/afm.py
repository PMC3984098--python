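"""Force-curve analysis: calibration, contact point, Hertz-cone fits, maps.

The raw photodiode signal is converted to force through the calibrated
sensitivity and spring constant, the contact point is located by a
piecewise (flat baseline + quadratic onset) breakpoint search, and the
Young's modulus is obtained by least squares on the Sneddon cone law

    F = (2/pi) tan(alpha) * E / (1 - nu^2) * delta^2,

with the indentation ``delta = (z - z_contact) - F/k_tip`` corrected for
cantilever deflection. Because only the elastic response contributes to
unloading, fits default to the retraction segment. The sample's effective
spring constant follows from the initial deflection-vs-piezo gradient m in
contact through the series-spring relation ``k_s = k_tip * m / (1 - m)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .afm_sim import ForceCurve, ForceMap, TipCalibration, hertz_cone_prefactor

__all__ = [
    "NoContactError", "InsufficientContactError", "PhysicalInconsistencyError",
    "ContactPoint", "HertzFit", "SpringEstimate", "ModulusMap",
    "deflection_to_force", "find_contact_point", "fit_hertz_cone",
    "analyze_curve", "contact_slope_from_stiffness", "stiffness_from_slope",
    "estimate_spring_constant", "map_modulus",
]


class NoContactError(ValueError):
    """The curve shows no detectable contact onset."""


class InsufficientContactError(ValueError):
    """Too few in-contact samples to fit the contact model."""


class PhysicalInconsistencyError(ValueError):
    """A measured contact slope outside (0, 1) has no series-spring solution."""


def deflection_to_force(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    """Convert a force curve to baseline-corrected force (nN) vs z (nm).

    Volt-unit deflection is converted to nm through the photodiode
    sensitivity, then to force through the tip spring constant (a length
    deflection bypasses the sensitivity). The baseline is the median force
    over the first 20% of samples on the far-from-sample side, subtracted
    so the non-contact force is zero. Samples are returned sorted by
    ascending z regardless of acquisition direction.
    """
    calib = curve.calib
    order = np.argsort(curve.z_nm, kind="stable")
    z = curve.z_nm[order]
    defl = curve.deflection[order]
    if curve.deflection_unit == "V":
        defl_nm = defl * calib.sensitivity
    else:
        defl_nm = defl
    force_nn = calib.k_tip * defl_nm  # N/m * nm = nN
    n0 = max(int(0.2 * len(z)), 1)
    force_nn = force_nn - np.median(force_nn[:n0])
    return z, force_nn


@dataclass
class ContactPoint:
    """Breakpoint of the baseline + quadratic-onset contact model."""

    z_nm: float
    index: int
    at_boundary: bool
    rss: float

    def __float__(self) -> float:
        return self.z_nm


def find_contact_point(z_nm: np.ndarray, force_nn: np.ndarray,
                       min_snr: float = 5.0) -> ContactPoint:
    """Locate the contact point of a force-vs-z curve.

    Fits, for every candidate breakpoint z_c, the two-regime model
    ``F = b`` below contact and ``F = b + a (z - z_c)^2`` above, and
    returns the breakpoint minimizing the total squared error (closed-form
    per candidate via suffix power sums, so the search is O(n)). Negative
    curvatures are rejected. If the force excursion never exceeds
    ``min_snr`` baseline noise standard deviations, a NoContactError is
    raised; a best breakpoint at the first sample is flagged as boundary.
    """
    z = np.asarray(z_nm, dtype=float)
    f = np.asarray(force_nn, dtype=float)
    n = len(z)
    if n < 10:
        raise InsufficientContactError("need at least 10 samples")

    n0 = max(int(0.2 * n), 3)
    noise = float(np.std(f[:n0]))
    if (f.max() - np.median(f[:n0])) < min_snr * max(noise, 1e-30):
        raise NoContactError("force excursion indistinguishable from baseline noise")

    # z is scaled to O(1) to keep the z^4 suffix sums well conditioned
    zs = (z - z[0]) / (z[-1] - z[0])
    # suffix sums S_k(c) = sum_{i>=c} f^p z^k
    def suffix(v):
        return np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])

    s1 = suffix(np.ones(n))
    sz = suffix(zs)
    sz2 = suffix(zs**2)
    sz3 = suffix(zs**3)
    sz4 = suffix(zs**4)
    sf = suffix(f)
    sfz = suffix(f * zs)
    sfz2 = suffix(f * zs**2)
    f_total = f.sum()
    f2_total = (f**2).sum()

    c = np.arange(n)  # candidate breakpoint = sample index
    zc = zs[c]
    m = s1[c]
    S2 = sz2[c] - 2 * zc * sz[c] + m * zc**2
    S4 = (sz4[c] - 4 * zc * sz3[c] + 6 * zc**2 * sz2[c]
          - 4 * zc**3 * sz[c] + m * zc**4)
    SF = f_total
    SFg2 = sfz2[c] - 2 * zc * sfz[c] + zc**2 * sf[c]

    # normal equations: [n, S2; S2, S4] [b, a]^T = [SF, SFg2]^T
    det = n * S4 - S2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (S4 * SF - S2 * SFg2) / det
        a = (n * SFg2 - S2 * SF) / det
    bad = ~np.isfinite(a) | (a < 0)
    b = np.where(bad, f_total / n, b)
    a = np.where(bad, 0.0, a)
    rss = (f2_total - 2 * b * SF - 2 * a * SFg2
           + n * b**2 + 2 * a * b * S2 + a**2 * S4)
    rss = np.where(np.isfinite(rss), rss, np.inf)

    best = int(np.argmin(rss))
    return ContactPoint(z_nm=float(z[best]), index=best,
                        at_boundary=best == 0, rss=float(rss[best]))


@dataclass
class HertzFit:
    """Result of a Sneddon-cone least-squares fit."""

    E_pa: float
    contact_z_nm: float
    rss: float
    max_indent_used_nm: float
    valid: bool
    segment: str
    n_points: int
    grid_index: Optional[tuple[int, int]] = None


def fit_hertz_cone(
    force_nn: np.ndarray,
    z_nm: np.ndarray,
    contact_z_nm: float,
    calib: TipCalibration,
    indent_cap_nm: float = 100.0,
    segment: str = "retract",
) -> HertzFit:
    """Fit E from force vs piezo position, given the contact point.

    The indentation is ``delta = (z - z_c) - F/k_tip``; only samples with
    ``0 < delta <= indent_cap_nm`` (the shallow-indentation validity
    window, ~10% of sample thickness) and nonnegative force enter the fit
    (adhesion dips are excluded). The modulus is the closed-form least
    squares solution ``E = sum(F d^2)/(C sum(d^4))``.
    """
    z = np.asarray(z_nm, dtype=float)
    f = np.asarray(force_nn, dtype=float)
    delta = (z - contact_z_nm) - f / calib.k_tip
    use = (delta > 0) & (delta <= indent_cap_nm) & (f >= 0)
    if use.sum() < 5:
        raise InsufficientContactError(
            f"only {int(use.sum())} in-contact samples within the indentation cap")
    d_m = delta[use] * 1e-9
    f_n = f[use] * 1e-9
    C = hertz_cone_prefactor(calib)
    E = float(np.sum(f_n * d_m**2) / (C * np.sum(d_m**4)))
    resid = f_n - C * E * d_m**2
    return HertzFit(
        E_pa=E,
        contact_z_nm=float(contact_z_nm),
        rss=float(np.sum(resid**2)),
        max_indent_used_nm=float(delta[use].max()),
        valid=E > 0,
        segment=segment,
        n_points=int(use.sum()),
    )


def analyze_curve(curve: ForceCurve, indent_cap_nm: float = 100.0,
                  refine_contact: bool = True) -> HertzFit:
    """Full single-curve pipeline: force conversion, contact point, fit.

    The breakpoint search locates the contact on the sample grid; with
    ``refine_contact`` the contact coordinate is then optimized
    continuously (within +-3 samples) by minimizing the Hertz-fit residual,
    removing the half-sample discretization bias of the grid search.
    """
    z, f = deflection_to_force(curve)
    cp = find_contact_point(z, f)
    zc = cp.z_nm
    if refine_contact and not cp.at_boundary:
        from scipy.optimize import minimize_scalar

        # the breakpoint model under-shoots on stiff (nearly linear) onsets;
        # rescan a Hertz-model residual around the breakpoint and polish
        # continuously. The residual is evaluated on a FIXED sample window
        # (slight pre-contact margin through the cap, chosen once from the
        # breakpoint), so moving the candidate cannot shed noisy points.
        k = curve.calib.k_tip
        C = hertz_cone_prefactor(curve.calib)
        delta0 = (z - cp.z_nm) - f / k
        fixed = (delta0 > -10.0) & (delta0 <= indent_cap_nm)
        zf, ff = z[fixed], f[fixed]

        def score(zc_try: float) -> float:
            d_m = np.maximum((zf - zc_try) - ff / k, 0.0) * 1e-9
            f_n = ff * 1e-9
            pos = d_m > 0
            denom = np.sum(d_m[pos] ** 4)
            if pos.sum() < 5 or denom <= 0:
                return np.inf
            E = np.sum(f_n[pos] * d_m[pos] ** 2) / (C * denom)
            if E <= 0:
                return np.inf
            return float(np.sum((f_n - C * E * d_m**2) ** 2))

        cand = z[max(cp.index - 15, 0):min(cp.index + 16, len(z))]
        scores = np.array([score(c) for c in cand])
        if np.isfinite(scores).any():
            best = float(cand[int(np.argmin(np.where(np.isfinite(scores),
                                                     scores, np.inf)))])
            dz = float(np.median(np.diff(z)))
            res = minimize_scalar(score, bounds=(best - dz, best + dz),
                                  method="bounded", options={"xatol": 1e-4 * dz})
            zc = float(res.x) if (np.isfinite(res.fun)
                                  and res.fun <= score(best)) else best
    fit = fit_hertz_cone(f, z, zc, curve.calib,
                         indent_cap_nm=indent_cap_nm, segment=curve.direction)
    fit.grid_index = curve.grid_index
    return fit


def contact_slope_from_stiffness(k_sample: float, k_tip: float) -> float:
    """Series-spring forward map: deflection-vs-piezo slope in contact."""
    if k_sample <= 0 or k_tip <= 0:
        raise ValueError("spring constants must be positive")
    return k_sample / (k_sample + k_tip)


def stiffness_from_slope(m: float, k_tip: float) -> float:
    """Invert the series-spring relation: k_s = k_tip * m / (1 - m)."""
    if not 0 < m < 1:
        raise PhysicalInconsistencyError(
            f"contact slope m={m:.4g} outside (0, 1) has no elastic solution")
    return k_tip * m / (1.0 - m)


@dataclass
class SpringEstimate:
    """Sample spring constant from the initial contact gradient."""

    k_sample: float
    slope: float
    k_tip: float
    window_nm: float


def estimate_spring_constant(
    curve: ForceCurve,
    contact_z_nm: Optional[float] = None,
    window_nm: float = 20.0,
) -> SpringEstimate:
    """Estimate the sample spring constant from the initial contact slope.

    Fits the gradient m of cantilever deflection (nm) vs piezo z over the
    first ``window_nm`` past contact and inverts the series-spring relation
    m = k_s/(k_s + k_tip). For a nonlinear (Hertzian) sample this is the
    effective secant stiffness of the shallow-contact region.
    """
    z, f = deflection_to_force(curve)
    if contact_z_nm is None:
        contact_z_nm = find_contact_point(z, f).z_nm
    defl_nm = f / curve.calib.k_tip
    use = (z >= contact_z_nm) & (z <= contact_z_nm + window_nm)
    if use.sum() < 3:
        raise InsufficientContactError("too few samples in the slope window")
    m = float(np.polyfit(z[use], defl_nm[use], 1)[0])
    k_s = stiffness_from_slope(m, curve.calib.k_tip)
    return SpringEstimate(k_sample=k_s, slope=m, k_tip=curve.calib.k_tip,
                          window_nm=window_nm)


@dataclass
class ModulusMap:
    """Grid of Hertz fits with fibril/base class masks and summaries."""

    E_pa: np.ndarray
    fits: list[Optional[HertzFit]]
    fibril_mask: np.ndarray
    central_mask: np.ndarray
    extent_um: tuple[float, float]
    summary: pd.DataFrame


def map_modulus(
    fmap: ForceMap,
    indent_cap_nm: float = 100.0,
    segment: str = "retract",
    mask_policy: str = "truth",
    erosion_radius: int = 2,
) -> ModulusMap:
    """Fit every curve of a force map and summarize per substrate class.

    ``mask_policy='truth'`` takes the fibril class from the map's ground
    truth (synthetic mode); ``'threshold'`` classifies by Otsu on log E
    (the softer class is the fibril). The quantitative fibril summary uses
    only the central part of the fibril region — a binary erosion by
    ``erosion_radius`` grid points — discarding edge points where the
    indentation is not normal to the surface. Emits a quality warning when
    more than 20% of fits fail.
    """
    rows, cols = fmap.shape
    E = np.full((rows, cols), np.nan)
    fits: list[Optional[HertzFit]] = []
    n_fail = 0
    for cyc in fmap.cycles:
        curve = cyc.retract if segment == "retract" else cyc.approach
        try:
            fit = analyze_curve(curve, indent_cap_nm=indent_cap_nm)
        except (NoContactError, InsufficientContactError):
            fit = None
        fits.append(fit)
        if fit is None or not fit.valid:
            n_fail += 1
            continue
        r, c = curve.grid_index
        E[r, c] = fit.E_pa
    if n_fail > 0.2 * len(fmap.cycles):
        warnings.warn(f"{n_fail}/{len(fmap.cycles)} fits failed: map quality suspect")

    if mask_policy == "truth":
        fibril = fmap.on_fibril.astype(bool)
    elif mask_policy == "threshold":
        valid = np.isfinite(E)
        logE = np.log(E[valid])
        if np.ptp(logE) == 0:
            fibril = np.zeros_like(E, dtype=bool)
        else:
            thr = threshold_otsu(logE)
            fibril = np.zeros_like(E, dtype=bool)
            fibril[valid] = np.log(E[valid]) < thr
    else:
        raise ValueError("mask_policy must be 'truth' or 'threshold'")

    if fibril.any() and not fibril.all():
        central = np.zeros_like(fibril)
        r = erosion_radius
        # coarse grids can lose the whole stripe to erosion; back off
        while r >= 0 and not central.any():
            central = fibril if r == 0 else ndimage.binary_erosion(
                fibril, structure=np.ones((2 * r + 1,) * 2))
            r -= 1
    else:  # degenerate (uniform) map: a single class, no erosion
        central = fibril.copy()

    rows_out = []
    for name, mask in (("fibril_central", central), ("base", ~fibril)):
        vals = E[mask & np.isfinite(E)]
        if vals.size:
            rows_out.append(dict(region=name, mean_E_pa=float(vals.mean()),
                                 sd_E_pa=float(vals.std()), n=int(vals.size)))
    summary = pd.DataFrame(rows_out, columns=["region", "mean_E_pa", "sd_E_pa", "n"])
    return ModulusMap(E_pa=E, fits=fits, fibril_mask=fibril,
                      central_mask=central, extent_um=fmap.extent_um,
                      summary=summary)
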