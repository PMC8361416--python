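"""Per-cell N:C ratios, per-field Nu:Ne ratios, compartment attribution.

N:C is each cell's mean nuclear intensity over its mean perinuclear-ring
intensity; Nu:Ne is a field's pooled nuclear mean over its neurite-mask
mean. Marker channels (DAPI for nuclei, tubulin for neurites) are measured
identically to the protein channel so that a ratio change can be attributed
to nuclear loss, neurite gain, or both.

Ratios are scale invariant: multiplying a channel by any c > 0 leaves every
N:C and Nu:Ne unchanged. No background subtraction is applied by default;
an optional constant offset is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import FieldImage
from .segmentation import CompartmentMasks

__all__ = ["measure_cells", "measure_field", "attribute_compartments"]

CELL_COLUMNS = [
    "cell",
    "nuclear_mean",
    "cytoplasmic_mean",
    "nc_ratio",
    "flag_border",
    "flag_empty_ring",
    "valid",
]


def _label_means(image: np.ndarray, labels: np.ndarray, ids: Sequence[int]):
    """Mean intensity and pixel count per label id (0 pixels -> NaN mean)."""
    if len(ids) == 0:
        return np.array([]), np.array([], dtype=int)
    ids = np.asarray(ids)
    maxid = int(labels.max()) if labels.size else 0
    maxid = max(maxid, int(ids.max()))
    counts = np.bincount(labels.ravel(), minlength=maxid + 1)
    sums = np.bincount(labels.ravel(), weights=image.ravel(), minlength=maxid + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means[ids], counts[ids]


def measure_cells(
    field: FieldImage,
    masks: CompartmentMasks,
    target_channel: str = "target",
    background_offset: float = 0.0,
) -> pd.DataFrame:
    """One row per selected cell with nuclear/ring means and the N:C ratio.

    Cells whose ring is empty (fully clipped or crowded out) are flagged and
    carry no ratio; border-touching cells keep their measurements but are
    flagged so aggregation can exclude them.
    """
    img = np.asarray(field[target_channel], dtype=np.float64) - background_offset
    if img.shape != masks.nuclear_labels.shape:
        raise ValueError("mask shape does not match image shape")
    ids = sorted(masks.selected_ids)
    nuc_means, _ = _label_means(img, masks.nuclear_labels, ids)
    ring_means, ring_counts = _label_means(img, masks.ring_labels, ids)
    rows = []
    prov = field.provenance
    for i, cid in enumerate(ids):
        empty_ring = ring_counts[i] == 0 if len(ids) else True
        border = cid in masks.border_ids
        cyt = np.nan if empty_ring else ring_means[i]
        ratio = (
            nuc_means[i] / cyt if not empty_ring and cyt > 0 else np.nan
        )
        rows.append(
            {
                **prov,
                "cell": cid,
                "nuclear_mean": nuc_means[i],
                "cytoplasmic_mean": cyt,
                "nc_ratio": ratio,
                "flag_border": border,
                "flag_empty_ring": bool(empty_ring),
                "valid": not border and not empty_ring and np.isfinite(ratio),
            }
        )
    columns = [*prov.keys(), *CELL_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def measure_field(
    field: FieldImage,
    masks: CompartmentMasks,
    channels: Iterable[str] | None = None,
    background_offset: float = 0.0,
) -> pd.DataFrame:
    """One row per channel: pooled nuclear mean, neurite mean, Nu:Ne ratio.

    The nuclear mean pools pixels across all selected nuclei (pixel-
    weighted, flagged cells included); the neurite mean pools the whole
    neurite mask. An empty neurite mask yields a QC-flagged row with no
    ratio.
    """
    if channels is None:
        channels = list(field.channels)
    nuc_sel = np.isin(masks.nuclear_labels, sorted(masks.selected_ids)) & (
        masks.nuclear_labels > 0
    )
    neurite = masks.neurite_mask
    n_nuc, n_neu = int(nuc_sel.sum()), int(neurite.sum())
    rows = []
    for name in channels:
        img = np.asarray(field[name], dtype=np.float64) - background_offset
        nuclear_mean = img[nuc_sel].mean() if n_nuc else np.nan
        neurite_mean = img[neurite].mean() if n_neu else np.nan
        ratio = (
            nuclear_mean / neurite_mean
            if n_neu and n_nuc and neurite_mean > 0
            else np.nan
        )
        rows.append(
            {
                **field.provenance,
                "channel": name,
                "nuclear_mean": nuclear_mean,
                "neurite_mean": neurite_mean,
                "nu_ne_ratio": ratio,
                "n_cells": len(masks.selected_ids),
                "neurite_area": n_neu,
                "flag_empty_neurite": n_neu == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttributionOptions:
    """Thresholding for calling a per-compartment direction of change."""

    #: relative change below which a compartment is called unchanged
    change_threshold: float = 0.05
    target_channel: str = "target"
    dapi_channel: str = "dapi"
    tubulin_channel: str = "tubulin"


def attribute_compartments(
    field_records: pd.DataFrame,
    reference_condition: str,
    opts: AttributionOptions = AttributionOptions(),
) -> pd.DataFrame:
    """Attribute a ratio change to nuclear loss, neurite gain, or both.

    For each condition the protein's nuclear and neurite means are first
    referenced to the matching compartment marker measured in the same
    pixels (nuclear/DAPI, neurite/tubulin), which cancels global staining
    or acquisition scale. Each non-reference condition is then compared to
    the reference and a direction (decrease / none / increase) is emitted
    per compartment.

    ``field_records`` is the output of :func:`measure_field` (stacked over
    fields), and must contain >= 2 conditions.
    """
    conditions = field_records["condition"].unique()
    if len(conditions) < 2:
        raise ValueError("attribution needs at least two conditions")
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} absent")

    def _norm_means(sub: pd.DataFrame) -> dict:
        by = {ch: g for ch, g in sub.groupby("channel")}
        tgt = by.get(opts.target_channel)
        dapi = by.get(opts.dapi_channel)
        tub = by.get(opts.tubulin_channel)
        if tgt is None:
            raise ValueError(f"target channel {opts.target_channel!r} absent")
        out = {"nuclear": np.nan, "neurite": np.nan,
               "nuclear_ok": False, "neurite_ok": False}
        if dapi is not None:
            marker = dapi["nuclear_mean"].mean()
            if marker > 0:
                out["nuclear"] = tgt["nuclear_mean"].mean() / marker
                out["nuclear_ok"] = True
        if tub is not None:
            marker = tub["neurite_mean"].mean()
            if marker > 0:
                out["neurite"] = tgt["neurite_mean"].mean() / marker
                out["neurite_ok"] = True
        return out

    ref = _norm_means(field_records[field_records["condition"] == reference_condition])
    rows = []
    for cond in conditions:
        cur = _norm_means(field_records[field_records["condition"] == cond])
        for comp in ("nuclear", "neurite"):
            ok = ref[f"{comp}_ok"] and cur[f"{comp}_ok"]
            change = cur[comp] / ref[comp] - 1.0 if ok else np.nan
            if not ok:
                direction = "unavailable"
            elif change <= -opts.change_threshold:
                direction = "decrease"
            elif change >= opts.change_threshold:
                direction = "increase"
            else:
                direction = "none"
            rows.append(
                {
                    "condition": cond,
                    "compartment": comp,
                    "marker_normalized_mean": cur[comp],
                    "relative_change": change,
                    "direction": direction,
                    "is_reference": cond == reference_condition,
                }
            )
    return pd.DataFrame(rows)
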