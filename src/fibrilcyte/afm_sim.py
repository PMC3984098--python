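"""Synthetic AFM indentation curves and force-volume grids.

Generates approach/retract force-distance cycles for a rigid conical tip on
an elastic half-space (Sneddon contact, ``F = (2/pi) tan(alpha) E/(1-nu^2)
delta^2``), including the cantilever compliance: past contact the piezo
travel splits into sample indentation ``delta`` and cantilever deflection
``F/k_tip``, which the generator resolves exactly (closed form) before
adding measurement noise. Deflection is emitted in volts by default and
converted through the photodiode sensitivity, mirroring real AFM exports.

Default calibration follows the in-situ measurement setup this package
models: cone half-angle 15 deg, spring constant 2.0 N/m, sensitivity
28 nm/V, incompressible sample (nu = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fibril import DegenerateGeometryError, FibrilArraySpec

__all__ = [
    "TipCalibration",
    "ForceCurve",
    "ForceCycle",
    "ForceMap",
    "hertz_cone_prefactor",
    "hertz_cone_force",
    "generate_force_curve",
    "generate_force_map",
]


@dataclass(frozen=True)
class TipCalibration:
    """Cantilever/tip calibration.

    k_tip in N/m, photodiode sensitivity in nm/V, cone half-angle in
    degrees, sample Poisson ratio (dimensionless; 0.5 = incompressible).
    """

    k_tip: float = 2.0
    sensitivity: float = 28.0
    half_angle_deg: float = 15.0
    poisson_nu: float = 0.5

    def __post_init__(self) -> None:
        if self.k_tip <= 0:
            raise ValueError("k_tip must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half_angle_deg must lie in (0, 90)")
        if not 0 <= self.poisson_nu <= 0.5:
            raise ValueError("poisson_nu must lie in [0, 0.5]")


def hertz_cone_prefactor(calib: TipCalibration) -> float:
    """Sneddon cone prefactor C so that F = C * E * delta^2 (SI units)."""
    alpha = np.deg2rad(calib.half_angle_deg)
    return (2.0 / np.pi) * np.tan(alpha) / (1.0 - calib.poisson_nu**2)


def hertz_cone_force(delta_nm, E_pa: float, calib: TipCalibration):
    """Elastic force (nN) of a rigid cone at indentation ``delta_nm``."""
    delta_m = np.maximum(np.asarray(delta_nm, dtype=float), 0.0) * 1e-9
    f_n = hertz_cone_prefactor(calib) * E_pa * delta_m**2
    return f_n * 1e9


@dataclass
class ForceCurve:
    """One segment of an indentation cycle.

    ``z_nm`` is piezo displacement (increasing toward the sample within an
    approach segment); ``deflection`` is the photodiode signal in the unit
    named by ``deflection_unit`` ("V" or "nm").
    """

    z_nm: np.ndarray
    deflection: np.ndarray
    deflection_unit: str
    direction: str
    calib: TipCalibration
    grid_index: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z_nm.shape != self.deflection.shape:
            raise ValueError("z and deflection must have the same length")
        if self.deflection_unit not in ("V", "nm"):
            raise ValueError("deflection_unit must be 'V' or 'nm'")
        if self.direction not in ("approach", "retract"):
            raise ValueError("direction must be 'approach' or 'retract'")
        dz = np.diff(self.z_nm)
        if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone within a segment")


@dataclass
class ForceCycle:
    """Approach + retract segments with the generative ground truth."""

    approach: ForceCurve
    retract: ForceCurve
    true_E_pa: float
    true_contact_z_nm: float


def _resolve_indentation(s_nm: np.ndarray, E_pa: float, calib: TipCalibration) -> np.ndarray:
    """Split piezo travel past contact into indentation (nm).

    Solves k*(s - delta) = C*E*delta^2 for delta >= 0:
    delta = (-k + sqrt(k^2 + 4*C*E*k*s)) / (2*C*E).
    """
    s_m = np.maximum(np.asarray(s_nm, dtype=float), 0.0) * 1e-9
    c = hertz_cone_prefactor(calib) * E_pa
    k = calib.k_tip
    delta_m = (-k + np.sqrt(k**2 + 4.0 * c * k * s_m)) / (2.0 * c)
    return delta_m * 1e9


def generate_force_curve(
    E_pa: float,
    calib: TipCalibration = TipCalibration(),
    contact_z_nm: float = 200.0,
    max_indent_nm: float = 100.0,
    noise_sd_nn: float = 0.0,
    seed: int = 0,
    n_samples: int = 400,
    z_range_nm: Optional[float] = None,
    adhesion_nn: float = 0.0,
    adhesion_range_nm: float = 20.0,
    deflection_unit: str = "V",
    grid_index: Optional[tuple[int, int]] = None,
) -> ForceCycle:
    """Simulate one indentation cycle on a uniform elastic sample.

    The approach ramps the piezo until the sample indentation reaches
    ``max_indent_nm``; the retract mirrors the approach (purely elastic
    response) except for an optional square adhesion well of depth
    ``adhesion_nn`` over ``adhesion_range_nm`` just before pull-off.
    Gaussian noise of ``noise_sd_nn`` (nN) is added to the deflection.

    Raises a configuration error when the requested z range cannot contain
    the contact point plus the travel needed to reach ``max_indent_nm``.
    """
    if E_pa <= 0:
        raise ValueError("E must be positive")
    if max_indent_nm <= 0:
        raise ValueError("max_indent must be positive")
    rng = np.random.default_rng(seed)

    f_max_nn = hertz_cone_force(max_indent_nm, E_pa, calib)
    travel_nm = max_indent_nm + f_max_nn / calib.k_tip  # nN/(N/m) = nm
    z_end = contact_z_nm + travel_nm
    if z_range_nm is None:
        z_range_nm = z_end * 1.02
    if z_range_nm < z_end:
        raise ValueError(
            f"z range {z_range_nm:.0f} nm cannot reach max indentation "
            f"(needs {z_end:.0f} nm past origin)"
        )
    z = np.linspace(0.0, z_range_nm, n_samples)

    delta = _resolve_indentation(z - contact_z_nm, E_pa, calib)
    force_nn = hertz_cone_force(delta, E_pa, calib)

    segs = {}
    for direction in ("approach", "retract"):
        f = force_nn.copy()
        zz = z.copy()
        if direction == "retract":
            if adhesion_nn > 0:
                well = (zz > contact_z_nm - adhesion_range_nm) & (zz <= contact_z_nm)
                f[well] -= adhesion_nn
            zz = zz[::-1]
            f = f[::-1]
        if noise_sd_nn > 0:
            f = f + rng.normal(0.0, noise_sd_nn, f.shape)
        defl_nm = f / calib.k_tip
        if deflection_unit == "V":
            defl = defl_nm / calib.sensitivity
        else:
            defl = defl_nm
        segs[direction] = ForceCurve(zz, defl, deflection_unit, direction,
                                     calib, grid_index)
    return ForceCycle(segs["approach"], segs["retract"], E_pa, contact_z_nm)


@dataclass
class ForceMap:
    """A grid of indentation cycles with its ground-truth modulus map."""

    cycles: list[ForceCycle]
    shape: tuple[int, int]
    extent_um: tuple[float, float]
    true_E_pa: np.ndarray
    on_fibril: np.ndarray
    calib: TipCalibration

    def cycle(self, row: int, col: int) -> ForceCycle:
        return self.cycles[row * self.shape[1] + col]


def generate_force_map(
    E_fibril_pa: float = 226e3,
    E_base_pa: float = 1e6,
    grid: tuple[int, int] = (32, 32),
    extent_um: tuple[float, float] = (10.0, 10.0),
    fibril_width_um: float = 4.0,
    fibril_center_um: Optional[float] = None,
    fibril_axis: str = "vertical",
    calib: TipCalibration = TipCalibration(),
    seed: int = 0,
    noise_sd_nn: float = 0.0,
    modulus_spread: float = 0.0,
    **curve_kwargs,
) -> ForceMap:
    """Simulate a force-volume grid spanning a soft fibril on a stiff base.

    Grid points whose position falls within the (vertical or horizontal)
    fibril stripe get ground truth ``E_fibril_pa``, others ``E_base_pa``,
    optionally with a lognormal spread (``modulus_spread`` = sd of log E).
    Each point yields a full cycle via :func:`generate_force_curve`.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    w_um, h_um = extent_um
    if w_um / cols <= 0 or h_um / rows <= 0 or min(w_um, h_um) <= 0:
        raise DegenerateGeometryError("extent smaller than one grid pitch")
    if fibril_center_um is None:
        fibril_center_um = (w_um if fibril_axis == "vertical" else h_um) / 2.0

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(rows * cols + 1)
    rng = np.random.default_rng(child[-1])

    xs = (np.arange(cols) + 0.5) * w_um / cols
    ys = (np.arange(rows) + 0.5) * h_um / rows
    if fibril_axis == "vertical":
        on = np.abs(xs[None, :] - fibril_center_um) <= fibril_width_um / 2.0
        on = np.broadcast_to(on, (rows, cols)).copy()
    else:
        on = np.abs(ys[:, None] - fibril_center_um) <= fibril_width_um / 2.0
        on = np.broadcast_to(on, (rows, cols)).copy()

    true_E = np.where(on, E_fibril_pa, E_base_pa).astype(float)
    if modulus_spread > 0:
        true_E = true_E * rng.lognormal(0.0, modulus_spread, true_E.shape)

    cycles = []
    for r in range(rows):
        for c in range(cols):
            sub = int(child[r * cols + c].generate_state(1)[0] % (2**31))
            cycles.append(
                generate_force_curve(
                    true_E[r, c], calib=calib, noise_sd_nn=noise_sd_nn,
                    seed=sub, grid_index=(r, c), **curve_kwargs,
                )
            )
    return ForceMap(cycles, (rows, cols), extent_um, true_E, on, calib)
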