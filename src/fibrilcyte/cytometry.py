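"""Fibril-referenced orientation statistics and dose-response indicators.

Per-cell shape tables are reduced to the condition-level quantities used to
read out ROCK-inhibition dose response on a fibril array:

* the alignment angle of each cell's major axis relative to the fibril axis
  (axial, wrapped to ``(-90, 90]`` degrees);
* *Orientation Deviation* (OD) — the standard deviation of alignment
  angles; uniformly random axial orientations give the reference value
  ``180/sqrt(12) ~ 51.96`` degrees and mean 0;
* the fraction of cells aligned within a threshold angle;
* the modal perimeter (center of the most populated histogram bin);
* the *Solidity* indicator (mean +- sd of area / convex area per dose), a
  protrusion-phenotype readout that decreases as protrusions grow;
* the perimeter-area envelope: through-origin slopes bounding the P vs A
  scatter, operationalized as quantiles of the per-cell ratio P/A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .angles import wrap_axial

__all__ = [
    "RANDOM_LIMIT_OD_DEG", "RANDOM_MEAN_DEG", "InsufficientSampleError",
    "alignment_angle", "orientation_deviation", "fraction_within",
    "modal_perimeter", "solidity_indicator", "perimeter_area_envelope",
    "CytometrySummary", "summarize_condition", "dose_response_report",
]

#: standard deviation of axial angles uniform on (-90, 90], degrees
RANDOM_LIMIT_OD_DEG: float = 180.0 / np.sqrt(12.0)
#: mean orientation of a randomly oriented population, degrees
RANDOM_MEAN_DEG: float = 0.0


class InsufficientSampleError(ValueError):
    """Raised when a statistic is requested on too small a sample."""


def alignment_angle(theta_cell_deg, theta_fibril_deg):
    """Axial angle between a cell's major axis and the fibril axis.

    Both inputs are axial angles in degrees; the difference is wrapped into
    ``(-90, 90]`` (0 and 180 are the same direction). Works elementwise on
    arrays.
    """
    return wrap_axial(np.asarray(theta_cell_deg, dtype=float)
                      - np.asarray(theta_fibril_deg, dtype=float))


def orientation_deviation(angles_deg: Sequence[float], about_zero: bool = False) -> float:
    """Orientation Deviation: std (degrees) of alignment angles.

    By default the ordinary standard deviation about the sample mean; with
    ``about_zero=True`` the root mean square about the fibril axis. The two
    coincide for a symmetric population centered on the fibril. Requires
    n >= 2.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise InsufficientSampleError("orientation deviation needs n >= 2")
    if about_zero:
        return float(np.sqrt(np.mean(a**2)))
    return float(np.std(a))


def fraction_within(angles_deg: Sequence[float], threshold_deg: float) -> float:
    """Fraction of cells with |alignment angle| <= threshold (degrees)."""
    if not 0 < threshold_deg <= 90:
        raise ValueError("threshold must lie in (0, 90]")
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise InsufficientSampleError("fraction_within of an empty sample is undefined")
    return float(np.mean(np.abs(a) <= threshold_deg))


def modal_perimeter(perimeters_um: Sequence[float], bin_width_um: float = 20.0) -> float:
    """Center (um) of the most populated perimeter histogram bin.

    Bins start at 0 with the given width; ties go to the smaller bin.
    """
    p = np.asarray(perimeters_um, dtype=float)
    if p.size == 0:
        raise InsufficientSampleError("modal perimeter of an empty sample is undefined")
    if bin_width_um <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, p.max() + 2 * bin_width_um, bin_width_um)
    counts, _ = np.histogram(p, bins=edges)
    i = int(np.argmax(counts))  # argmax returns the first (smallest) max bin
    return float(edges[i] + bin_width_um / 2.0)


def solidity_indicator(frame: pd.DataFrame, dose_col: str = "dose",
                       solidity_col: str = "solidity") -> pd.DataFrame:
    """Per-dose Solidity summary (mean, sd, n) plus a trend diagnostic.

    Empty dose groups are dropped. The returned frame is sorted by dose and
    carries the sign of the Spearman correlation of mean solidity vs dose
    in ``.attrs['trend_sign']`` (0 for a single dose group).
    """
    groups = []
    for dose, g in frame.groupby(dose_col):
        if len(g) == 0:
            continue
        s = g[solidity_col].to_numpy(dtype=float)
        groups.append(dict(dose=float(dose), mean_solidity=float(s.mean()),
                           sd_solidity=float(s.std()), n=int(s.size)))
    if not groups:
        raise InsufficientSampleError("no nonempty dose groups")
    out = pd.DataFrame(groups).sort_values("dose").reset_index(drop=True)
    if len(out) > 1 and out["mean_solidity"].nunique() > 1:
        rho = sstats.spearmanr(out["dose"], out["mean_solidity"]).statistic
        out.attrs["trend_sign"] = int(np.sign(rho)) if np.isfinite(rho) else 0
    else:
        out.attrs["trend_sign"] = 0
    return out


def perimeter_area_envelope(
    areas_um2: Sequence[float],
    perimeters_um: Sequence[float],
    quantiles: tuple[float, float] = (0.025, 0.975),
    min_n: int = 10,
) -> tuple[float, float]:
    """Through-origin slopes (1/um) bounding the perimeter-vs-area scatter.

    The lower/upper envelope slopes are the given quantiles of the per-cell
    ratio P/A. For a population of disks of radius r the ratio is 2/r, so
    the upper slope approaches 2/r_min.
    """
    a = np.asarray(areas_um2, dtype=float)
    p = np.asarray(perimeters_um, dtype=float)
    if a.size != p.size:
        raise ValueError("areas and perimeters must have equal length")
    if a.size < min_n:
        raise InsufficientSampleError(f"envelope needs n >= {min_n}")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    lo_q, hi_q = quantiles
    if not 0 <= lo_q <= hi_q <= 1:
        raise ValueError("quantiles must satisfy 0 <= lo <= hi <= 1")
    ratio = p / a
    lo, hi = np.quantile(ratio, [lo_q, hi_q])
    return float(lo), float(hi)


@dataclass
class CytometrySummary:
    """Condition-level cytometry statistics."""

    condition: str
    dose: float
    n_cells: int
    modal_perimeter_um: float
    mean_solidity: float
    sd_solidity: float
    orientation_deviation_deg: float
    mean_alignment_deg: float
    fraction_aligned: float
    alignment_threshold_deg: float
    envelope_lower: Optional[float]
    envelope_upper: Optional[float]


def summarize_condition(
    frame: pd.DataFrame,
    fibril_axis_deg: float,
    condition: str = "fibril",
    dose: float = 0.0,
    alignment_threshold_deg: float = 20.0,
    perimeter_bin_um: float = 20.0,
    envelope_quantiles: tuple[float, float] = (0.025, 0.975),
    od_about_zero: bool = False,
    exclude_flagged: bool = True,
    min_eccentricity_orientation: float = 0.6,
) -> CytometrySummary:
    """Reduce one condition's CellRecord table to a CytometrySummary.

    ``frame`` needs columns orientation_deg, perimeter_um, area_um2 and
    solidity (the morphometry output schema).

    With ``exclude_flagged`` (default) border-clipped and sub-50-um^2
    artifact records are left out of the statistics; all records stay in
    the input table. Orientation statistics additionally drop cells below
    ``min_eccentricity_orientation`` — a near-round cell has no defined
    major axis, so its measured orientation is rasterization noise. Both
    exclusions are independent of a cell's alignment angle, so they leave
    the orientation statistics unbiased.
    """
    if exclude_flagged:
        for col in ("touches_border", "artifact_flag"):
            if col in frame.columns:
                frame = frame[~frame[col].astype(bool)]
    oriented = frame
    if min_eccentricity_orientation > 0 and "eccentricity" in frame.columns:
        oriented = frame[frame["eccentricity"] >= min_eccentricity_orientation]
    if len(oriented) < 2 or len(frame) < 1:
        raise InsufficientSampleError("too few usable cells in this condition")
    phi = alignment_angle(oriented["orientation_deg"].to_numpy(), fibril_axis_deg)
    try:
        env = perimeter_area_envelope(frame["area_um2"], frame["perimeter_um"],
                                      envelope_quantiles)
    except InsufficientSampleError:
        env = (None, None)
    sol = frame["solidity"].to_numpy(dtype=float)
    return CytometrySummary(
        condition=condition,
        dose=float(dose),
        n_cells=int(len(frame)),
        modal_perimeter_um=modal_perimeter(frame["perimeter_um"], perimeter_bin_um),
        mean_solidity=float(sol.mean()),
        sd_solidity=float(sol.std()),
        orientation_deviation_deg=orientation_deviation(phi, about_zero=od_about_zero),
        mean_alignment_deg=float(np.mean(phi)),
        fraction_aligned=fraction_within(phi, alignment_threshold_deg),
        alignment_threshold_deg=float(alignment_threshold_deg),
        envelope_lower=env[0],
        envelope_upper=env[1],
    )


def dose_response_report(
    tables: dict[tuple[str, float], pd.DataFrame],
    fibril_axis_deg: float,
    **summary_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize every (condition, dose) cell table.

    Parameters
    ----------
    tables : mapping (condition, dose) -> CellRecord DataFrame
        Empty groups are omitted with a warning row left out.
    fibril_axis_deg : float
        Reference axis for the alignment angles.

    Returns
    -------
    summary : DataFrame
        One CytometrySummary row per nonempty condition x dose, with the
        random-orientation reference in ``.attrs['random_limit_od_deg']``.
    scatter : DataFrame
        Per-cell scatter data (perimeter, area, alignment angle, solidity,
        condition, dose) for plotting.
    """
    import warnings

    rows, scat = [], []
    for (condition, dose), frame in sorted(tables.items()):
        if len(frame) < 2:
            warnings.warn(f"group ({condition}, {dose}) has <2 cells; omitted")
            continue
        try:
            s = summarize_condition(frame, fibril_axis_deg, condition=condition,
                                    dose=dose, **summary_kwargs)
        except InsufficientSampleError as exc:
            warnings.warn(f"group ({condition}, {dose}) omitted: {exc}")
            continue
        rows.append(vars(s))
        phi = alignment_angle(frame["orientation_deg"].to_numpy(), fibril_axis_deg)
        scat.append(pd.DataFrame(dict(
            condition=condition, dose=dose,
            area_um2=frame["area_um2"].to_numpy(),
            perimeter_um=frame["perimeter_um"].to_numpy(),
            alignment_deg=phi,
            solidity=frame["solidity"].to_numpy(),
        )))
    if not rows:
        raise InsufficientSampleError("no condition had enough cells")
    summary = pd.DataFrame(rows)
    summary.attrs["random_limit_od_deg"] = RANDOM_LIMIT_OD_DEG
    scatter = pd.concat(scat, ignore_index=True)
    return summary, scatter
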