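"""Ground-truthed synthetic cell populations on fibril-array substrates.

Emulates endothelial cells plated at low density (default 100 cells/mm^2) on
a parallel fibril array: each cell is an ellipse whose major axis is drawn
around the fibril axis with a tunable concentration, optionally decorated
with slender protrusion rectangles whose length grows with the dose of a
ROCK inhibitor. Two fluorescence-like channels (nucleus, actin) are rendered
with a Gaussian PSF, Poisson shot noise and Gaussian read noise.

All randomness flows through one seeded :class:`numpy.random.Generator`; a
fixed seed reproduces rasters bit for bit. The per-cell random draws are
independent of dose (the dose only rescales protrusion lengths), so sweeps
that reuse a seed across doses are coupled by common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .angles import wrap_axial
from .fibril import FibrilArraySpec

__all__ = [
    "CellPopulationModel",
    "ImagingModel",
    "SyntheticImage",
    "PackingError",
    "sample_cells",
    "render_channels",
    "generate_image",
]


class PackingError(ValueError):
    """Raised when the requested density cannot be placed without total overlap."""


def sample_alignment_angles(kappa: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` axial alignment angles (deg, in (-90, 90]) around 0.

    Von Mises on the doubled angle with concentration ``kappa``; ``kappa=0``
    is the uniform axial distribution (std 180/sqrt(12) ~ 51.96 deg). This
    is the same law :func:`sample_cells` uses per cell.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    return wrap_axial(np.degrees(rng.vonmises(0.0, kappa, int(n))) / 2.0)


@dataclass(frozen=True)
class CellPopulationModel:
    """Statistical model of the plated cell population.

    Parameters
    ----------
    density : float
        Plating density in cells per mm^2.
    base_radius : float
        Radius (um) of the equal-area circle of the cell body ellipse.
    elongation_mean, elongation_sd : float
        Major/minor axis ratio of the body ellipse (normal, clipped >= 1).
    orientation_kappa : float
        Concentration of the alignment angle around the fibril axis
        (von Mises on the doubled angle; 0 means uniform on (-90, 90]).
    protrusion_base_um : float
        Mean protrusion length (um) of untreated cells.
    protrusion_max_um : float
        Dose-driven ceiling of the mean protrusion length (um).
    protrusion_halfmax_dose : float
        Dose (uM) at which half of the ceiling is reached (Hill-type map).
    protrusion_width : float
        Protrusion rectangle width (um).
    protrusion_prob : float
        Per-slot probability of growing a protrusion (two slots per cell).
    on_fibril_fraction : float
        Probability that a cell centroid snaps to the nearest fibril line.
    """

    density: float = 100.0
    base_radius: float = 14.0
    elongation_mean: float = 2.0
    elongation_sd: float = 0.4
    orientation_kappa: float = 4.0
    protrusion_base_um: float = 4.0
    protrusion_max_um: float = 80.0
    protrusion_halfmax_dose: float = 2.5
    protrusion_width: float = 2.0
    protrusion_prob: float = 0.7
    on_fibril_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be nonnegative")
        if self.elongation_mean < 1:
            raise ValueError("elongation_mean must be >= 1")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if not 0 <= self.on_fibril_fraction <= 1:
            raise ValueError("on_fibril_fraction must be a probability")
        if not 0 <= self.protrusion_prob <= 1:
            raise ValueError("protrusion_prob must be a probability")

    def protrusion_length_scale(self, dose: float) -> float:
        """Mean protrusion length (um) at an inhibitor dose (uM).

        Saturating Hill-type map, nondecreasing in dose, chosen so the
        steepest growth falls below ~5 uM.
        """
        if dose < 0:
            raise ValueError("dose must be nonnegative")
        return self.protrusion_base_um + self.protrusion_max_um * dose / (
            dose + self.protrusion_halfmax_dose
        )


def _mask_box(labels: np.ndarray, mask_fn, cx_px: float, cy_px: float,
              reach_px: float):
    """Evaluate ``mask_fn(x, y)`` on the clipped bounding box; returns the
    box slices and the boolean mask (or None when fully off-field)."""
    rows, cols = labels.shape
    r0 = max(int(cy_px - reach_px) - 1, 0)
    r1 = min(int(cy_px + reach_px) + 2, rows)
    c0 = max(int(cx_px - reach_px) - 1, 0)
    c1 = min(int(cx_px + reach_px) + 2, cols)
    if r0 >= r1 or c0 >= c1:
        return None, None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), mask_fn(xx + 0.5, yy + 0.5)


def _paint(labels: np.ndarray, mask_fn, cx_px: float, cy_px: float,
           reach_px: float, label: int) -> int:
    """Paint ``label`` where ``mask_fn(x, y)`` is true, only over background
    (later cells yield to earlier ones). Returns pixels painted."""
    box, m = _mask_box(labels, mask_fn, cx_px, cy_px, reach_px)
    if box is None:
        return 0
    sub = labels[box]
    write = m & (sub == 0)
    sub[write] = label
    return int(write.sum())


def sample_cells(
    spec: FibrilArraySpec,
    model: CellPopulationModel,
    dose: float = 0.0,
    seed: int = 0,
    substrate: str = "fibril",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place a random cell population and rasterize it into a label image.

    The cell count is Poisson with mean ``density * field area``. Each cell
    is an ellipse (area ``pi * base_radius^2``, axis ratio drawn from the
    elongation distribution) whose major axis sits at the fibril axis plus
    an alignment angle with concentration ``orientation_kappa``; up to two
    protrusion rectangles extend along the fibril axis (or along the cell's
    own axis on a ``"flat"`` substrate) with exponential lengths of mean
    ``protrusion_length_scale(dose)``. On a flat substrate the orientation
    concentration is ignored (uniform axial orientations): the alignment
    cue is the fibrils themselves. Overlapping cells are not merged: later
    cells yield their overlapping pixels to earlier labels.

    Returns
    -------
    labels : ndarray of uint16
        Ground-truth label raster, 0 = background.
    truth : DataFrame
        One row per placed cell: label, centroid (um), generative
        orientation and alignment angle (deg), elongation, protrusion count
        and total length, rendered area (um^2, 0 if fully occluded), and the
        on-fibril flag.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if substrate not in ("fibril", "flat"):
        raise ValueError("substrate must be 'fibril' or 'flat'")
    rng = np.random.default_rng(seed)
    rows, cols = spec.shape
    px = spec.pixel_size
    area_mm2 = spec.field_width * spec.field_height / 1e6
    n = int(rng.poisson(model.density * area_mm2))
    body_area = np.pi * model.base_radius**2
    if n * body_area > 0.8 * spec.field_width * spec.field_height:
        raise PackingError(
            f"{n} cells of ~{body_area:.0f} um^2 cannot be placed on "
            f"{spec.field_width}x{spec.field_height} um^2 without total overlap"
        )

    labels = np.zeros((rows, cols), dtype=np.uint16)
    scale = model.protrusion_length_scale(dose)
    axis = spec.axis_angle
    records = []
    placements = []
    # pass 1: cell bodies. Placement retries emulate excluded volume
    # (plated cells touch but do not stack): a body mostly hidden under
    # earlier cells is re-drawn at a new position, up to a retry budget.
    # Neither the placement nor the retry decisions depend on dose, so a
    # fixed seed yields identical geometry across a dose sweep.
    # alignment concentration is caused by the fibrils; a flat substrate
    # has no reference axis, so orientations there are uniform
    kappa = model.orientation_kappa if substrate == "fibril" else 0.0
    for i in range(n):
        lab = i + 1
        phi = np.degrees(rng.vonmises(0.0, kappa)) / 2.0
        theta = wrap_axial(axis + phi)
        elong = max(1.0, rng.normal(model.elongation_mean, model.elongation_sd))
        a_um = model.base_radius * np.sqrt(elong)
        b_um = model.base_radius / np.sqrt(elong)
        th = np.deg2rad(theta)
        ct, st = np.cos(th), np.sin(th)

        # protrusion randomness drawn unconditionally (common random numbers)
        grow = rng.random(2) < model.protrusion_prob
        unit_len = rng.exponential(1.0, 2)
        signs = rng.choice([-1.0, 1.0], 2)

        best = None
        for _attempt in range(30):
            cx = rng.uniform(0, spec.field_width)
            cy = rng.uniform(0, spec.field_height)
            snap = rng.random() < model.on_fibril_fraction
            on_fibril = False
            if substrate == "fibril" and snap:
                d = spec.across_axis_coordinate(cx, cy)
                shift = spec.nearest_fibril_center(d) - d
                a = np.deg2rad(axis)
                cx, cy = cx - shift * np.sin(a), cy + shift * np.cos(a)
                on_fibril = True

            def body(xpx, ypx, cx=cx, cy=cy, ct=ct, st=st, a=a_um, b=b_um):
                dx = xpx * px - cx
                dy = ypx * px - cy
                u = dx * ct + dy * st
                v = -dx * st + dy * ct
                return (u / a) ** 2 + (v / b) ** 2 <= 1.0

            box, m = _mask_box(labels, body, cx / px, cy / px, a_um / px)
            total = int(m.sum()) if box is not None else 0
            free = int((m & (labels[box] == 0)).sum()) if total else 0
            frac = free / total if total else 0.0
            if best is None or frac > best[0]:
                best = (frac, box, m, cx, cy, on_fibril)
            if total and frac >= 0.9:
                break
        frac, box, m, cx, cy, on_fibril = best
        painted = 0
        if box is not None:
            sub = labels[box]
            write = m & (sub == 0)
            sub[write] = lab
            painted = int(write.sum())
        placements.append((lab, cx, cy, theta, grow, unit_len * scale, signs))
        records.append(
            dict(
                label=lab, x_um=cx, y_um=cy,
                orientation_deg=theta, alignment_deg=wrap_axial(phi),
                elongation=elong, n_protrusions=int(grow.sum()),
                protrusion_total_um=0.0,
                area_um2=painted * px**2, on_fibril=on_fibril,
            )
        )

    # pass 2: protrusions, painted over remaining background only so they
    # run underneath every cell body
    for (lab, cx, cy, theta, grow, prot_lens, signs), rec in zip(placements, records):
        prot_dir = axis if substrate == "fibril" else theta
        pd_rad = np.deg2rad(prot_dir)
        cp, sp = np.cos(pd_rad), np.sin(pd_rad)
        painted = 0
        total_prot = 0.0
        for k in range(2):
            if not grow[k]:
                continue
            length = float(prot_lens[k])
            sgn = signs[k]
            total_prot += length

            def rect(xpx, ypx, cx=cx, cy=cy, cp=cp, sp=sp, sgn=sgn,
                     length=length, w=model.protrusion_width):
                dx = xpx * px - cx
                dy = ypx * px - cy
                u = (dx * cp + dy * sp) * sgn
                v = -dx * sp + dy * cp
                return (u >= 0) & (u <= length) & (np.abs(v) <= w / 2.0)

            painted += _paint(labels, rect, cx / px, cy / px, length / px + 2, lab)
        rec["protrusion_total_um"] = total_prot
        rec["area_um2"] += painted * px**2
    truth = pd.DataFrame.from_records(
        records,
        columns=["label", "x_um", "y_um", "orientation_deg", "alignment_deg",
                 "elongation", "n_protrusions", "protrusion_total_um",
                 "area_um2", "on_fibril"],
    )
    return labels, truth


@dataclass(frozen=True)
class ImagingModel:
    """Rendering model for the two fluorescence-like channels.

    ``psf_sigma_um`` is the Gaussian blur applied before noise;
    ``*_peak_photons`` set the expected photon count inside objects and
    ``background_photons`` outside; shot noise is Poisson on those counts
    and ``read_noise_sd`` adds Gaussian read noise (photon units). With the
    blur and all noise switched off the actin channel support equals the
    label support exactly.
    """

    psf_sigma_um: float = 0.6
    nucleus_radius_um: float = 5.0
    cell_peak_photons: float = 200.0
    nucleus_peak_photons: float = 300.0
    background_photons: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True


@dataclass
class SyntheticImage:
    """A rendered two-channel synthetic field with its ground truth."""

    nucleus_channel: np.ndarray
    actin_channel: np.ndarray
    truth_labels: np.ndarray
    truth_table: pd.DataFrame
    seed: int
    spec: FibrilArraySpec

    def __post_init__(self) -> None:
        if not (self.nucleus_channel.shape == self.actin_channel.shape
                == self.truth_labels.shape):
            raise ValueError("channel and label rasters must share one shape")


def render_channels(
    truth_labels: np.ndarray,
    pixel_size: float,
    imaging: ImagingModel = ImagingModel(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render nucleus and actin channels from a ground-truth label raster.

    The nucleus channel is one disk per label at the label's centroid, the
    actin channel the full cell body; both are blurred with the Gaussian
    PSF, then Poisson shot noise and Gaussian read noise are applied.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    fg = truth_labels > 0
    actin = fg.astype(float) * imaging.cell_peak_photons

    nucleus = np.zeros_like(actin)
    labs = np.unique(truth_labels)
    labs = labs[labs > 0]
    if labs.size:
        coms = ndimage.center_of_mass(fg, truth_labels, labs)
        r_px = imaging.nucleus_radius_um / pixel_size
        yy, xx = np.mgrid[0:truth_labels.shape[0], 0:truth_labels.shape[1]]
        for (cy, cx) in coms:
            r0 = max(int(cy - r_px) - 1, 0)
            r1 = min(int(cy + r_px) + 2, nucleus.shape[0])
            c0 = max(int(cx - r_px) - 1, 0)
            c1 = min(int(cx + r_px) + 2, nucleus.shape[1])
            if r0 >= r1 or c0 >= c1:
                continue
            d2 = (yy[r0:r1, c0:c1] - cy) ** 2 + (xx[r0:r1, c0:c1] - cx) ** 2
            nucleus[r0:r1, c0:c1][d2 <= r_px**2] = imaging.nucleus_peak_photons

    sigma_px = imaging.psf_sigma_um / pixel_size
    out = []
    for chan in (nucleus, actin):
        if sigma_px > 0:
            chan = ndimage.gaussian_filter(chan, sigma_px)
        expected = chan + imaging.background_photons
        img = rng.poisson(expected).astype(float) if imaging.shot_noise else expected.copy()
        if imaging.read_noise_sd > 0:
            img += rng.normal(0.0, imaging.read_noise_sd, img.shape)
        out.append(np.clip(img, 0, None))
    return out[0], out[1]


def generate_image(
    spec: FibrilArraySpec,
    model: CellPopulationModel = CellPopulationModel(),
    imaging: ImagingModel = ImagingModel(),
    dose: float = 0.0,
    seed: int = 0,
    substrate: str = "fibril",
) -> SyntheticImage:
    """Sample a population and render it: one simulated microscope field."""
    ss = np.random.SeedSequence(seed)
    s_cells, s_render = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    labels, truth = sample_cells(spec, model, dose=dose, seed=s_cells, substrate=substrate)
    nuc, act = render_channels(labels, spec.pixel_size, imaging, seed=s_render)
    return SyntheticImage(nuc, act, labels, truth, seed, spec)
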