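"""End-to-end analysis of one ROI image: stains -> nuclei -> signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import (
    NucleusRecord,
    SegmentationParams,
    SpotCall,
    SpotParams,
    assign_spots,
    detect_spots,
    segment_nuclei,
)
from .stains import (
    StainModel,
    chromatic_red_channel,
    estimate_background,
    rgb_to_od,
    separate_stains,
    gated_silver_channel,
)
from .synth import CEP17, HER2


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the image-analysis stage in one block."""

    stain: StainModel = field(default_factory=StainModel.default)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: SpotParams = field(default_factory=SpotParams)


@dataclass
class RoiAnalysis:
    """Per-ROI analysis products."""

    nuclei: list[NucleusRecord]
    spots: list[SpotCall]
    labels: np.ndarray
    resolution_um_per_px: float
    roi_id: str = ""


def analyze_roi_image(
    image: np.ndarray,
    resolution_um_per_px: float,
    params: PipelineParams = PipelineParams(),
    roi_id: str = "",
) -> RoiAnalysis:
    """Run the full single-ROI pipeline on an RGB tile.

    Unmixes the stains, segments nuclei on the hematoxylin map, calls HER2
    signals on the achromatic-darkness (silver) channel and CEP17 signals on
    the chromatic Fast Red channel, then assigns signals to their containing
    nucleus.
    """
    model = params.stain
    if model.background_intensity is None:
        i0 = estimate_background(image)
        model = StainModel(
            od_vectors=model.od_vectors,
            background_intensity=tuple(i0),
            darkness_saturation_cutoff=model.darkness_saturation_cutoff,
            saturation_softness=model.saturation_softness,
        )
    od = rgb_to_od(image, model.background_intensity)
    maps = separate_stains(od, model)

    nuclei, labels = segment_nuclei(maps.hematoxylin, resolution_um_per_px, params.segmentation)
    for n in nuclei:
        n.roi_id = roi_id

    silver = gated_silver_channel(image, model)
    red = chromatic_red_channel(image, model)
    spots = detect_spots(silver, resolution_um_per_px, HER2, params.spots)
    spots += detect_spots(red, resolution_um_per_px, CEP17, params.spots)
    spots, nuclei = assign_spots(spots, labels, nuclei)
    return RoiAnalysis(nuclei, spots, labels, resolution_um_per_px, roi_id=roi_id)
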