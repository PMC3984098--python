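"""Convenience composition of the image-analysis stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import SyntheticImage
from .morphometry import measure_cells, records_to_frame, segment_cells, segment_nuclei

__all__ = ["measure_image", "measure_channels"]


def measure_channels(
    nucleus: np.ndarray,
    actin: np.ndarray,
    pixel_size_um: float,
    min_nucleus_area_um2: float = 20.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run segmentation + morphometry on a two-channel field.

    Returns the per-cell measurement table and the cell label raster.
    """
    seeds = segment_nuclei(nucleus, pixel_size_um, min_area_um2=min_nucleus_area_um2)
    labels = segment_cells(actin, seeds, pixel_size_um)
    frame = records_to_frame(measure_cells(labels, pixel_size_um))
    return frame, labels


def measure_image(image: SyntheticImage, **kwargs) -> tuple[pd.DataFrame, np.ndarray]:
    """measure_channels applied to a rendered synthetic field."""
    return measure_channels(image.nucleus_channel, image.actin_channel,
                            image.spec.pixel_size, **kwargs)
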