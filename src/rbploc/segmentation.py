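"""Compartment masks: labeled nuclei, perinuclear rings, neurite mask.

The three products mirror the compartments of a neuronal high-content
localization assay: a DAPI-derived nuclear mask, a fixed-width (default
1.5 µm) cytoplasmic ring sampled immediately around each nucleus, and a
tubulin-derived neurite mask from which all nuclei — expanded by a fixed
pixel radius (default 30 px) — are removed so that somata are excluded.

All distances are exact Euclidean on pixel centers. Contested ring pixels
go to the nearest nucleus, ties to the lower label id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .imaging import FieldImage, rescale_to_range

__all__ = [
    "SegmentationOptions",
    "CompartmentMasks",
    "segment_nuclei",
    "select_neurons",
    "make_cyto_ring",
    "make_neurite_mask",
    "segment_field",
]


@dataclass(frozen=True)
class SegmentationOptions:
    """All thresholds and widths of the mask-building stage.

    Defaults follow the assay conventions: DAPI pre-scaled 0-500 before
    detection, 1.5 µm perinuclear ring, nuclei expanded by 30 px before
    neurite masking, morphology gates standing in for the trained neuron
    classifier of the original screen.
    """

    # nuclear detection
    dapi_rescale: tuple[float, float] = (0.0, 500.0)
    smooth_sigma_px: float = 1.0
    min_nucleus_area_um2: float = 10.0
    #: minimum separation of watershed seeds, about one nucleus radius
    min_seed_separation_um: float = 4.0
    # neuron gating
    area_gate_um2: tuple[float, float] = (25.0, 300.0)
    max_eccentricity: float = 0.95
    dapi_mean_gate: tuple[float, float] = (0.0, float("inf"))
    # cytoplasmic ring
    ring_width_um: float = 1.5
    # neurite mask
    nucleus_expand_px: int = 30
    tubulin_threshold: float | None = None  # None -> Otsu
    tubulin_smooth_sigma_px: float = 1.0
    min_neurite_object_px: int = 20


@dataclass
class CompartmentMasks:
    """Consistent mask set for one field.

    ``ring_labels`` shares ids with ``nuclear_labels`` and never overlaps
    it; ``neurite_mask`` excludes every pixel within ``nucleus_expand_px``
    (Euclidean) of any nucleus.
    """

    nuclear_labels: np.ndarray
    ring_labels: np.ndarray
    neurite_mask: np.ndarray
    selected_ids: frozenset[int]
    border_ids: frozenset[int]
    params_used: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.nuclear_labels) if i != 0]


def segment_nuclei(
    dapi: np.ndarray,
    pixel_size: float,
    opts: SegmentationOptions = SegmentationOptions(),
) -> tuple[np.ndarray, frozenset[int]]:
    """Detect nuclei in a DAPI projection.

    The image is linearly pre-scaled to a fixed range, lightly smoothed,
    Otsu-thresholded, hole-filled and size-filtered; touching nuclei are
    split by marker-controlled watershed on the distance transform.
    Returns the label image and the set of border-touching ids (flagged,
    not removed).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.min() < 0:
        raise ValueError("DAPI image must be non-negative")
    scaled = rescale_to_range(dapi, *opts.dapi_rescale)
    if scaled.max() == scaled.min():
        return np.zeros(dapi.shape, dtype=np.int32), frozenset()
    if opts.smooth_sigma_px > 0:
        scaled = ndi.gaussian_filter(scaled, opts.smooth_sigma_px)
    binary = scaled > threshold_otsu(scaled)
    binary = ndi.binary_fill_holes(binary)
    min_px = max(1, round(opts.min_nucleus_area_um2 / pixel_size**2))
    binary = remove_small_objects(binary, max_size=min_px - 1)
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32), frozenset()
    dist = ndi.distance_transform_edt(binary)
    sep_px = max(1, round(opts.min_seed_separation_um / pixel_size))
    peaks = peak_local_max(
        dist, min_distance=sep_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=binary)
    labels = _relabel_sequential(labels)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    return labels, frozenset(int(i) for i in border if i != 0)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def select_neurons(
    nuclear_labels: np.ndarray,
    dapi: np.ndarray,
    pixel_size: float,
    opts: SegmentationOptions = SegmentationOptions(),
) -> tuple[frozenset[int], dict[int, dict]]:
    """Gate detected nuclei on area, eccentricity and mean DAPI intensity.

    Explicit morphology gating standing in for a trained per-object neuron
    classifier; every gate and each cell's pass/fail record is returned for
    auditability.
    """
    lo_a, hi_a = opts.area_gate_um2
    lo_d, hi_d = opts.dapi_mean_gate
    log: dict[int, dict] = {}
    selected = []
    for prop in regionprops(nuclear_labels, intensity_image=dapi):
        area_um2 = prop.area * pixel_size**2
        checks = {
            "area": lo_a <= area_um2 <= hi_a,
            "eccentricity": prop.eccentricity <= opts.max_eccentricity,
            "dapi_mean": lo_d <= prop.intensity_mean <= hi_d,
        }
        log[prop.label] = {
            "area_um2": area_um2,
            "eccentricity": prop.eccentricity,
            "dapi_mean": prop.intensity_mean,
            **{f"pass_{k}": v for k, v in checks.items()},
        }
        if all(checks.values()):
            selected.append(prop.label)
    return frozenset(selected), log


def make_cyto_ring(
    nuclear_labels: np.ndarray,
    width_um: float = 1.5,
    pixel_size: float = 0.3,
) -> np.ndarray:
    """Fixed-width perinuclear ring labels.

    A background pixel belongs to nucleus k's ring iff its Euclidean
    distance to nucleus k is <= the ring width (in whole pixels) and
    nucleus k is the nearest nucleus (ties to the lower id). Clipped at
    image borders; never overlaps any nucleus.
    """
    if width_um <= 0:
        raise ValueError("width_um must be > 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    ids = np.unique(nuclear_labels)
    ids = ids[ids != 0]
    rings = np.zeros_like(nuclear_labels, dtype=np.int32)
    if len(ids) == 0:
        return rings
    width_px = max(1, round(width_um / pixel_size))
    # exact per-label distance maps; argmin over the id axis implements the
    # nearest-nucleus rule with ties to the lower label id
    dists = np.stack(
        [ndi.distance_transform_edt(nuclear_labels != lab) for lab in ids]
    )
    nearest = np.argmin(dists, axis=0)
    mind = np.take_along_axis(dists, nearest[None], axis=0)[0]
    inside = (nuclear_labels == 0) & (mind <= width_px) & (mind > 0)
    rings[inside] = ids[nearest[inside]]
    return rings


def make_neurite_mask(
    tubulin: np.ndarray,
    nuclear_labels: np.ndarray,
    pixel_size: float = 0.3,
    expand_px: int = 30,
    opts: SegmentationOptions = SegmentationOptions(),
) -> np.ndarray:
    """Tubulin foreground minus all nuclei expanded by ``expand_px``.

    The expansion (Euclidean disc, radius in pixels exactly as configured)
    removes somata so only neurites remain; objects smaller than
    ``opts.min_neurite_object_px`` are dropped as speckle.
    """
    if expand_px < 0 or int(expand_px) != expand_px:
        raise ValueError("expand_px must be a non-negative integer")
    tubulin = np.asarray(tubulin, dtype=np.float64)
    img = (
        ndi.gaussian_filter(tubulin, opts.tubulin_smooth_sigma_px)
        if opts.tubulin_smooth_sigma_px > 0
        else tubulin
    )
    if opts.tubulin_threshold is not None:
        thr = opts.tubulin_threshold
    else:
        if img.max() == img.min():
            return np.zeros(tubulin.shape, dtype=bool)
        thr = threshold_otsu(img)
    fg = img > thr
    if (nuclear_labels > 0).any():
        dist_to_nucleus = ndi.distance_transform_edt(nuclear_labels == 0)
        fg &= dist_to_nucleus > expand_px
    if opts.min_neurite_object_px > 1:
        fg = remove_small_objects(fg, max_size=opts.min_neurite_object_px - 1)
    return fg


def segment_field(
    image: FieldImage,
    opts: SegmentationOptions = SegmentationOptions(),
) -> CompartmentMasks:
    """Run the full mask-building stage on one projected field."""
    px = image.pixel_size
    nuclear, border = segment_nuclei(image["dapi"], px, opts)
    selected, gate_log = select_neurons(nuclear, image["dapi"], px, opts)
    rings = make_cyto_ring(nuclear, opts.ring_width_um, px)
    neurites = make_neurite_mask(
        image["tubulin"], nuclear, px, opts.nucleus_expand_px, opts
    )
    return CompartmentMasks(
        nuclear_labels=nuclear,
        ring_labels=rings,
        neurite_mask=neurites,
        selected_ids=selected,
        border_ids=border,
        params_used={**asdict(opts), "pixel_size": px, "gate_log": gate_log},
    )
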