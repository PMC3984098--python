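"""File formats: multi-page TIFF images, per-curve TSV force data, CSVs.

Images travel as multi-page TIFF (nucleus page 0, actin page 1) with the
pixel size recorded in the TIFF resolution tags; label rasters as 16-bit
single-page TIFF. A force curve is one TSV (columns z_nm, deflection, and
segment) plus a JSON sidecar holding the tip calibration, deflection unit
and grid index; a force map is a directory of such pairs with an index CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .afm_sim import ForceCurve, ForceCycle, ForceMap, TipCalibration
from .cells import SyntheticImage
from .fibril import FibrilArraySpec

__all__ = [
    "write_image", "read_image", "write_labels", "read_labels",
    "write_force_cycle", "read_force_cycle", "write_force_map",
    "read_force_map",
]


def _resolution(pixel_size_um: float):
    # TIFF resolution = pixels per unit; store as pixels/cm
    per_cm = 1e4 / pixel_size_um
    return (per_cm, per_cm)


def write_image(path: str | Path, image: SyntheticImage) -> None:
    """Write a two-channel synthetic field as a multi-page TIFF plus
    sidecars (<stem>_labels.tif, <stem>_truth.csv)."""
    path = Path(path)
    px = image.spec.pixel_size
    stack = np.stack([image.nucleus_channel, image.actin_channel]).astype(np.float32)
    tifffile.imwrite(path, stack, resolution=_resolution(px),
                     resolutionunit="CENTIMETER",
                     metadata={"pixel_size_um": px, "seed": image.seed,
                               "channels": ["nucleus", "actin"]})
    write_labels(path.with_name(path.stem + "_labels.tif"), image.truth_labels, px)
    image.truth_table.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)


def read_image(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read (nucleus, actin, pixel_size_um) from a multi-page TIFF."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        px = _pixel_size_from_tif(tif)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"{path} is not a two-channel image stack")
    return stack[0].astype(float), stack[1].astype(float), px


def _pixel_size_from_tif(tif: tifffile.TiffFile) -> float:
    meta = tif.shaped_metadata
    if meta and "pixel_size_um" in meta[0]:
        return float(meta[0]["pixel_size_um"])
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is None:
        raise ValueError("TIFF carries no pixel size metadata")
    num, den = xres.value
    unit = page.tags.get("ResolutionUnit")
    per_unit = num / den
    scale = {2: 2.54e4, 3: 1e4}.get(getattr(unit, "value", 3).real, 1e4)
    return scale / per_unit


def write_labels(path: str | Path, labels: np.ndarray, pixel_size_um: float) -> None:
    """Write a ground-truth/segmentation label raster as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), labels.astype(np.uint16),
                     resolution=_resolution(pixel_size_um),
                     resolutionunit="CENTIMETER",
                     metadata={"pixel_size_um": pixel_size_um})


def read_labels(path: str | Path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(Path(path)) as tif:
        return tif.asarray().astype(np.int32), _pixel_size_from_tif(tif)


def _calib_dict(calib: TipCalibration) -> dict:
    return dict(k_tip=calib.k_tip, sensitivity=calib.sensitivity,
                half_angle_deg=calib.half_angle_deg,
                poisson_nu=calib.poisson_nu)


def write_force_cycle(path: str | Path, cycle: ForceCycle) -> None:
    """Write one indentation cycle as TSV + JSON sidecar."""
    path = Path(path)
    frames = []
    for seg in (cycle.approach, cycle.retract):
        frames.append(pd.DataFrame({
            "z_nm": seg.z_nm,
            "deflection": seg.deflection,
            "segment": seg.direction,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    sidecar = {
        "calibration": _calib_dict(cycle.approach.calib),
        "deflection_unit": cycle.approach.deflection_unit,
        "grid_index": list(cycle.approach.grid_index)
        if cycle.approach.grid_index is not None else None,
        "true_E_pa": cycle.true_E_pa,
        "true_contact_z_nm": cycle.true_contact_z_nm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_force_cycle(path: str | Path) -> ForceCycle:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    side = json.loads(path.with_suffix(".json").read_text())
    calib = TipCalibration(**side["calibration"])
    gi = tuple(side["grid_index"]) if side.get("grid_index") else None
    segs = {}
    for direction in ("approach", "retract"):
        sub = table[table["segment"] == direction]
        segs[direction] = ForceCurve(
            sub["z_nm"].to_numpy(), sub["deflection"].to_numpy(),
            side["deflection_unit"], direction, calib, gi)
    return ForceCycle(segs["approach"], segs["retract"],
                      side.get("true_E_pa", float("nan")),
                      side.get("true_contact_z_nm", float("nan")))


def write_force_map(directory: str | Path, fmap: ForceMap) -> None:
    """Write a force map as a directory of curve TSVs plus index.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for cyc in fmap.cycles:
        r, c = cyc.approach.grid_index
        name = f"curve_r{r:03d}_c{c:03d}.tsv"
        write_force_cycle(directory / name, cyc)
        rows.append(dict(row=r, col=c, file=name,
                         true_E_pa=fmap.true_E_pa[r, c],
                         on_fibril=bool(fmap.on_fibril[r, c])))
    index = pd.DataFrame(rows)
    index.attrs = {}
    index.to_csv(directory / "index.csv", index=False)
    meta = dict(shape=list(fmap.shape), extent_um=list(fmap.extent_um),
                calibration=_calib_dict(fmap.calib))
    (directory / "map.json").write_text(json.dumps(meta, indent=1))


def read_force_map(directory: str | Path) -> ForceMap:
    directory = Path(directory)
    meta = json.loads((directory / "map.json").read_text())
    index = pd.read_csv(directory / "index.csv")
    shape = tuple(meta["shape"])
    true_E = np.full(shape, np.nan)
    on_fibril = np.zeros(shape, dtype=bool)
    cycles: list[Optional[ForceCycle]] = [None] * (shape[0] * shape[1])
    for rec in index.itertuples():
        cyc = read_force_cycle(directory / rec.file)
        cycles[rec.row * shape[1] + rec.col] = cyc
        true_E[rec.row, rec.col] = rec.true_E_pa
        on_fibril[rec.row, rec.col] = bool(rec.on_fibril)
    if any(c is None for c in cycles):
        raise ValueError(f"incomplete force map in {directory}")
    calib = TipCalibration(**meta["calibration"])
    return ForceMap(cycles, shape, tuple(meta["extent_um"]), true_E,
                    on_fibril, calib)
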