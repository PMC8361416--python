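"""Synthetic neuronal fluorescence fields with known ground truth.

Generates scenes of cultured neurons — DAPI-positive nuclei, tubulin-positive
somata and neurites — and renders them as 3-channel confocal z-stacks
(Gaussian PSF blur, Gaussian defocus falloff in z, Poisson-Gaussian noise).
Every scene carries its ground-truth compartment masks and true
nuclear:cytoplasmic / nuclear:neurite intensity ratios, so the whole
measurement pipeline can be validated against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .imaging import FieldStack

__all__ = [
    "CompartmentIntensity",
    "CompartmentScale",
    "SceneParams",
    "CellTruth",
    "SceneTruth",
    "PlateLayout",
    "FieldSample",
    "MUTANT_EFFECT",
    "generate_scene",
    "render_stack",
    "generate_experiment",
    "write_field",
    "write_experiment",
    "um_to_px",
]

#: Default pixel size in µm/pixel, typical for a x40 water-immersion
#: high-content objective with a 2x-binned sCMOS camera.
DEFAULT_PIXEL_SIZE = 0.3


def um_to_px(value_um: float, pixel_size: float) -> int:
    """Convert a µm length to pixels, rounding to the nearest integer >= 1."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return max(1, round(value_um / pixel_size))


@dataclass(frozen=True)
class CompartmentIntensity:
    """Mean fluorescence of one channel in each compartment (a.u.)."""

    nuclear: float
    cytoplasmic: float
    neurite: float

    def __post_init__(self) -> None:
        for name in ("nuclear", "cytoplasmic", "neurite"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} intensity must be >= 0")

    def scaled(self, s: "CompartmentScale") -> "CompartmentIntensity":
        return CompartmentIntensity(
            self.nuclear * s.nuclear,
            self.cytoplasmic * s.cytoplasmic,
            self.neurite * s.neurite,
        )


@dataclass(frozen=True)
class CompartmentScale:
    """Per-compartment multipliers applied to a target channel's means."""

    nuclear: float = 1.0
    cytoplasmic: float = 1.0
    neurite: float = 1.0


#: Mislocalization preset: nuclear loss with cytoplasmic and neurite gain,
#: the pattern shown by TDP-43/FUS/SFPQ-like proteins in disease lines.
MUTANT_EFFECT = CompartmentScale(nuclear=0.8, cytoplasmic=1.2, neurite=1.5)


def _as_intensity(value) -> CompartmentIntensity:
    if isinstance(value, CompartmentIntensity):
        return value
    return CompartmentIntensity(*value)


@dataclass
class SceneParams:
    """Generative parameters for one field of view.

    Lengths are in µm unless the name says otherwise; intensities are
    arbitrary fluorescence units. ``target_intensity`` may be a single
    (nuclear, cytoplasmic, neurite) triple — rendered as channel
    ``"target"`` — or a mapping of channel name to triple when several
    proteins are imaged in the same field.
    """

    field_shape: tuple[int, int] = (256, 256)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_cells: int = 6
    nucleus_radius_range: tuple[float, float] = (3.5, 5.0)
    soma_radius_range: tuple[float, float] = (6.5, 9.5)
    #: Minimum width of the soma cytoplasm annulus; keeps the sampled soma
    #: wider than the 1.5 µm analysis ring regardless of the sampled radii.
    min_cytoplasm_width: float = 2.0
    #: Minimum clearance between nucleus rims of different cells.
    min_nucleus_gap: float = 2.0
    neurites_per_cell_range: tuple[int, int] = (1, 3)
    neurite_length_range: tuple[float, float] = (40.0, 80.0)
    neurite_width: float = 1.5
    target_intensity: Mapping[str, CompartmentIntensity] | CompartmentIntensity | tuple = (
        200.0,
        100.0,
        50.0,
    )
    dapi_intensity: float = 300.0
    tubulin_intensity: tuple[float, float] = (150.0, 120.0)  # (soma, neurite)
    background_level: float = 1.0
    #: Lateral PSF sigma; ~0.2 µm approximates a near-diffraction-limited
    #: confocal at NA ~1.1.
    psf_sigma: float = 0.2
    #: Axial falloff sigma of the defocus model.
    z_sigma: float = 1.5
    poisson_scale: float = 1.0
    gaussian_sd: float = 5.0
    #: Optional cell-to-cell staining variability: lognormal sd of a
    #: per-cell brightness factor applied to all target compartments of
    #: that cell (per-cell ratios are preserved). Off by default so the
    #: parametric compartment means are exactly the rendered truth.
    cell_brightness_cv: float = 0.0
    n_z: int = 5
    z_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.target_intensity, Mapping):
            self.target_intensity = {
                str(k): _as_intensity(v) for k, v in self.target_intensity.items()
            }
        else:
            self.target_intensity = {"target": _as_intensity(self.target_intensity)}
        self.validate()

    def validate(self) -> None:
        h, w = self.field_shape
        if h < 64 or w < 64:
            raise ValueError("field_shape dimensions must be >= 64 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        for lo, hi, name in (
            (*self.nucleus_radius_range, "nucleus_radius_range"),
            (*self.soma_radius_range, "soma_radius_range"),
            (*self.neurite_length_range, "neurite_length_range"),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive interval")
        n_lo, n_hi = self.neurites_per_cell_range
        if n_lo < 0 or n_hi < n_lo:
            raise ValueError("neurites_per_cell_range must be a non-negative interval")
        if self.neurite_width <= 0:
            raise ValueError("neurite_width must be > 0")
        for v, name in (
            (self.dapi_intensity, "dapi_intensity"),
            (self.background_level, "background_level"),
            (self.psf_sigma, "psf_sigma"),
            (self.poisson_scale, "poisson_scale"),
            (self.gaussian_sd, "gaussian_sd"),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.tubulin_intensity):
            raise ValueError("tubulin_intensity means must be >= 0")

    @property
    def target_channels(self) -> tuple[str, ...]:
        return tuple(self.target_intensity)

    def with_effect(
        self, effect: Mapping[str, CompartmentScale] | CompartmentScale
    ) -> "SceneParams":
        """Return a copy whose target means are scaled per compartment.

        ``effect`` is either one :class:`CompartmentScale` applied to every
        target channel, or a mapping of channel name (or ``"*"``) to scale.
        """
        if isinstance(effect, CompartmentScale):
            effect = {"*": effect}
        unknown = set(effect) - set(self.target_intensity) - {"*"}
        if unknown:
            raise KeyError(f"unknown target channel in effect map: {sorted(unknown)}")
        scaled = {}
        for name, inten in self.target_intensity.items():
            s = effect.get(name, effect.get("*"))
            scaled[name] = inten.scaled(s) if s is not None else inten
        return replace(self, target_intensity=scaled)


@dataclass
class CellTruth:
    """Geometry and true intensities of one simulated neuron."""

    id: int
    center: tuple[float, float]  # (row, col), pixels
    nucleus_radius_px: float
    soma_radius_px: float
    neurite_paths: list[np.ndarray]  # each (n, 2) float pixel coords
    brightness: float  # per-cell staining factor on target channels


@dataclass
class SceneTruth:
    """Ground truth for one rendered field.

    The three compartment masks are pairwise disjoint by construction:
    ``cyto_labels`` is the soma disc minus the nucleus and ``neurite_labels``
    excludes all somata.
    """

    params: SceneParams
    cells: list[CellTruth]
    nuclear_labels: np.ndarray  # int, 0 = background
    cyto_labels: np.ndarray
    neurite_labels: np.ndarray
    channel_means: dict[str, CompartmentIntensity]

    @property
    def neurite_mask(self) -> np.ndarray:
        return self.neurite_labels > 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def true_nc_ratio(self, channel: str = "target") -> float:
        m = self.channel_means[channel]
        if m.cytoplasmic <= 0:
            return float("nan")
        return m.nuclear / m.cytoplasmic

    def true_nu_ne_ratio(self, channel: str = "target") -> float:
        """True pooled-nuclear over pooled-neurite mean of the rendered field.

        Equals nuclear/neurite of the channel's parametric means when
        per-cell brightness variability is off; otherwise both pools are
        brightness-weighted by each cell's realized mask areas.
        """
        m = self.channel_means[channel]
        if m.neurite <= 0:
            return float("nan")
        if not self.cells:
            return m.nuclear / m.neurite
        b = {c.id: c.brightness for c in self.cells}
        nuc_counts = np.bincount(self.nuclear_labels.ravel())
        neu_counts = np.bincount(self.neurite_labels.ravel())

        def _pool(counts: np.ndarray, mean: float) -> float:
            tot = sum(counts[i] for i in b if i < len(counts))
            if tot == 0:
                return np.nan
            return mean * sum(
                counts[i] * b[i] for i in b if i < len(counts)
            ) / tot

        num = _pool(nuc_counts, m.nuclear)
        den = _pool(neu_counts, m.neurite)
        return num / den if den and np.isfinite(den) and den > 0 else float("nan")


class FieldTooCrowdedError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed in the field."""


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

_PLACEMENT_ATTEMPTS_PER_CELL = 400


def _place_cells(params: SceneParams, rng: np.random.Generator) -> list[CellTruth]:
    h, w = params.field_shape
    px = params.pixel_size
    ring_px = um_to_px(1.5, px)  # keep the analysis ring inside the field
    cells: list[CellTruth] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, nucleus_radius_px)
    gap_px = params.min_nucleus_gap / px
    budget = _PLACEMENT_ATTEMPTS_PER_CELL * max(1, params.n_cells)
    attempts = 0
    for i in range(params.n_cells):
        r_nuc = rng.uniform(*params.nucleus_radius_range) / px
        r_soma = rng.uniform(*params.soma_radius_range)
        r_soma = max(r_soma, r_nuc * px + params.min_cytoplasm_width) / px
        margin = r_nuc + ring_px + 2
        if 2 * margin >= min(h, w):
            raise FieldTooCrowdedError(
                "field too crowded: cell radius exceeds half the field size"
            )
        while True:
            attempts += 1
            if attempts > budget:
                raise FieldTooCrowdedError(
                    f"field too crowded: placed {len(cells)} of {params.n_cells} "
                    f"cells in {budget} attempts"
                )
            cr = rng.uniform(margin, h - 1 - margin)
            cc = rng.uniform(margin, w - 1 - margin)
            if all(
                np.hypot(cr - pr, cc - pc) >= r_nuc + pn + gap_px
                for pr, pc, pn in placed
            ):
                break
        placed.append((cr, cc, r_nuc))
        n_neur = int(rng.integers(params.neurites_per_cell_range[0],
                                  params.neurites_per_cell_range[1] + 1))
        paths = [
            _grow_neurite(params, rng, (cr, cc), r_soma)
            for _ in range(n_neur)
        ]
        brightness = (
            float(rng.lognormal(0.0, params.cell_brightness_cv))
            if params.cell_brightness_cv > 0
            else 1.0
        )
        cells.append(
            CellTruth(
                id=i + 1,
                center=(cr, cc),
                nucleus_radius_px=r_nuc,
                soma_radius_px=r_soma,
                neurite_paths=paths,
                brightness=brightness,
            )
        )
    return cells


def _grow_neurite(
    params: SceneParams,
    rng: np.random.Generator,
    center: tuple[float, float],
    r_soma: float,
) -> np.ndarray:
    """Smoothed random-walk polyline starting on the soma boundary."""
    length_px = rng.uniform(*params.neurite_length_range) / params.pixel_size
    theta = rng.uniform(0, 2 * np.pi)
    step = 2.0  # px
    n_steps = max(2, int(np.ceil(length_px / step)))
    pts = np.empty((n_steps + 1, 2))
    pts[0] = (center[0] + r_soma * np.sin(theta), center[1] + r_soma * np.cos(theta))
    heading = theta
    for k in range(1, n_steps + 1):
        heading += rng.normal(0.0, 0.15)
        pts[k] = pts[k - 1] + step * np.array([np.sin(heading), np.cos(heading)])
    return pts


def _paint_discs(
    shape: tuple[int, int], cells: Sequence[CellTruth]
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize nucleus and soma-cytoplasm discs as label images."""
    nuclear = np.zeros(shape, dtype=np.int32)
    cyto = np.zeros(shape, dtype=np.int32)
    h, w = shape
    for cell in cells:
        cr, cc = cell.center
        rad = int(np.ceil(cell.soma_radius_px)) + 1
        r0, r1 = max(0, int(cr) - rad), min(h, int(cr) + rad + 2)
        c0, c1 = max(0, int(cc) - rad), min(w, int(cc) + rad + 2)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cr) ** 2 + (xx - cc) ** 2
        nuc = d2 <= cell.nucleus_radius_px**2
        soma = d2 <= cell.soma_radius_px**2
        sub_n = nuclear[r0:r1, c0:c1]
        sub_c = cyto[r0:r1, c0:c1]
        sub_n[nuc & (sub_n == 0)] = cell.id
        sub_c[soma & ~nuc & (sub_c == 0)] = cell.id
    # somata of later cells may overlap earlier nuclei; nuclei win
    cyto[nuclear > 0] = 0
    return nuclear, cyto


def _paint_neurites(
    params: SceneParams,
    cells: Sequence[CellTruth],
    nuclear: np.ndarray,
    cyto: np.ndarray,
) -> np.ndarray:
    """Dilate each cell's polylines to neurite_width, excluding all somata."""
    shape = params.field_shape
    centerline = np.zeros(shape, dtype=np.int32)
    h, w = shape
    for cell in cells:
        for path in cell.neurite_paths:
            for p, q in zip(path[:-1], path[1:]):
                seg_len = max(1, int(np.ceil(np.hypot(*(q - p)) * 2)))
                ts = np.linspace(0.0, 1.0, seg_len + 1)
                pts = np.round(p[None, :] + ts[:, None] * (q - p)[None, :]).astype(int)
                ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
                pts = pts[ok]
                cur = centerline[pts[:, 0], pts[:, 1]]
                centerline[pts[:, 0], pts[:, 1]] = np.where(cur == 0, cell.id, cur)
    if not centerline.any():
        return np.zeros(shape, dtype=np.int32)
    half_px = max(1, round(params.neurite_width / 2 / params.pixel_size))
    dist, (ir, ic) = ndi.distance_transform_edt(centerline == 0, return_indices=True)
    labels = centerline[ir, ic].astype(np.int32)
    labels[dist > half_px] = 0
    labels[(nuclear > 0) | (cyto > 0)] = 0
    return labels


def generate_scene(params: SceneParams) -> SceneTruth:
    """Sample one field's geometry and ground truth. Deterministic in seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    nuclear, cyto = _paint_discs(params.field_shape, cells)
    neurites = _paint_neurites(params, cells, nuclear, cyto)
    return SceneTruth(
        params=params,
        cells=cells,
        nuclear_labels=nuclear,
        cyto_labels=cyto,
        neurite_labels=neurites,
        channel_means=dict(params.target_intensity),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _channel_signal(truth: SceneTruth, channel: str) -> np.ndarray:
    """Noise-free, background-free in-focus signal of one channel."""
    params = truth.params
    sig = np.zeros(params.field_shape, dtype=np.float64)
    if channel == "dapi":
        sig[truth.nuclear_labels > 0] = params.dapi_intensity
        return sig
    if channel == "tubulin":
        soma_i, neur_i = params.tubulin_intensity
        sig[truth.cyto_labels > 0] = soma_i
        sig[truth.neurite_labels > 0] = neur_i
        return sig
    means = truth.channel_means[channel]
    for cell in truth.cells:
        b = cell.brightness
        sig[truth.nuclear_labels == cell.id] = b * means.nuclear
        sig[truth.cyto_labels == cell.id] = b * means.cytoplasmic
        sig[truth.neurite_labels == cell.id] = b * means.neurite
    return sig


def render_stack(truth: SceneTruth, params: SceneParams | None = None) -> FieldStack:
    """Render a scene into a blurred, noisy, defocus-attenuated z-stack.

    The in-focus slice is the painted scene convolved with a Gaussian PSF;
    out-of-focus slices are the same signal attenuated by a Gaussian falloff
    in z (so a max projection of the noise-free stack recovers the in-focus
    slice exactly). Poisson-then-Gaussian noise is applied per slice.
    """
    if params is None:
        params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    k0 = (params.n_z - 1) // 2
    zw = np.ones(params.n_z)
    if params.n_z > 1 and params.z_sigma > 0:
        dz = (np.arange(params.n_z) - k0) * params.z_step
        zw = np.exp(-0.5 * (dz / params.z_sigma) ** 2)
    elif params.n_z > 1:
        zw = np.where(np.arange(params.n_z) == k0, 1.0, 0.0)
    psf_px = params.psf_sigma / params.pixel_size
    channels: dict[str, np.ndarray] = {}
    for name in ("dapi", "tubulin", *truth.params.target_channels):
        sig = _channel_signal(truth, name)
        if psf_px > 0:
            sig = ndi.gaussian_filter(sig, psf_px, mode="nearest")
        stack = np.empty((params.n_z,) + params.field_shape, dtype=np.float64)
        for k in range(params.n_z):
            plane = params.background_level + (sig if k == k0 else zw[k] * sig)
            if params.poisson_scale > 0:
                plane = rng.poisson(plane * params.poisson_scale) / params.poisson_scale
            if params.gaussian_sd > 0:
                plane = plane + rng.normal(0.0, params.gaussian_sd, plane.shape)
            stack[k] = np.maximum(plane, 0.0)
        channels[name] = stack
    return FieldStack(
        channels=channels,
        pixel_size=params.pixel_size,
        z_step=params.z_step,
        provenance={},
    )


# ---------------------------------------------------------------------------
# Plate-scale experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateLayout:
    """Nested acquisition layout: lines (each with a condition) x repeats x
    wells x fields, mirroring a high-content screening plate."""

    lines: Mapping[str, str]  # line name -> condition label
    wells_per_line: int = 6
    fields_per_well: int = 12
    repeats: int = 3

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("layout needs at least one line")
        if self.wells_per_line < 1 or self.fields_per_well < 1 or self.repeats < 1:
            raise ValueError("wells, fields and repeats must all be >= 1")

    @property
    def conditions(self) -> set[str]:
        return set(self.lines.values())


@dataclass
class FieldSample:
    stack: FieldStack
    truth: SceneTruth
    provenance: dict


def generate_experiment(
    layout: PlateLayout,
    effects: Mapping[str, Mapping[str, CompartmentScale] | CompartmentScale],
    base_params: SceneParams,
    seed: int = 0,
) -> tuple[list[FieldSample], pd.DataFrame]:
    """Render a whole plate layout with per-condition intensity effects.

    ``effects`` maps condition labels to compartment multipliers (see
    :meth:`SceneParams.with_effect`); conditions absent from the map render
    at baseline. Returns the field samples and a manifest table with one
    row per field.
    """
    unknown = set(effects) - layout.conditions
    if unknown:
        raise KeyError(f"unknown condition in effect map: {sorted(unknown)}")
    per_condition = {
        cond: base_params.with_effect(effects[cond]) if cond in effects else base_params
        for cond in layout.conditions
    }
    ss = np.random.SeedSequence(seed)
    samples: list[FieldSample] = []
    rows = []
    for repeat in range(1, layout.repeats + 1):
        for line, cond in layout.lines.items():
            for well in range(1, layout.wells_per_line + 1):
                well_id = f"{line}-r{repeat}-w{well}"
                for fov in range(1, layout.fields_per_well + 1):
                    child = int(ss.spawn(1)[0].generate_state(1, np.uint32)[0] >> 1)
                    p = replace(per_condition[cond], seed=child)
                    truth = generate_scene(p)
                    stack = render_stack(truth, p)
                    prov = {
                        "line": line,
                        "condition": cond,
                        "repeat": repeat,
                        "well": well_id,
                        "field": f"{well_id}-f{fov}",
                    }
                    stack.provenance = dict(prov)
                    samples.append(FieldSample(stack, truth, prov))
                    rows.append({**prov, "path": ""})
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------


def write_field(sample: FieldSample, directory: Path | str) -> Path:
    """Write one field as ImageJ-style ZCYX TIFF + truth sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = sample.provenance.get("field", "field")
    names = list(sample.stack.channels)
    arr = np.stack([sample.stack.channels[c] for c in names], axis=1).astype(np.float32)
    path = directory / f"{name}.tif"
    tifffile.imwrite(
        path,
        arr,
        imagej=True,
        metadata={
            "axes": "ZCYX",
            "Labels": names,
            "spacing": sample.stack.z_step,
            "unit": "um",
        },
    )
    truth = sample.truth
    masks = np.stack(
        [truth.nuclear_labels, truth.cyto_labels, truth.neurite_labels]
    ).astype(np.uint16)
    tifffile.imwrite(
        directory / f"{name}_truth_masks.tif", masks, photometric="minisblack"
    )
    sidecar = {
        "channels": names,
        "pixel_size_um": sample.stack.pixel_size,
        "z_step_um": sample.stack.z_step,
        "provenance": sample.provenance,
        "true_ratios": {
            c: {
                "nc": truth.true_nc_ratio(c),
                "nu_ne": truth.true_nu_ne_ratio(c),
            }
            for c in truth.params.target_channels
        },
        "cells": [
            {
                "id": c.id,
                "center": list(c.center),
                "nucleus_radius_px": c.nucleus_radius_px,
                "soma_radius_px": c.soma_radius_px,
                "brightness": c.brightness,
            }
            for c in truth.cells
        ],
    }
    (directory / f"{name}_truth.json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_experiment(
    samples: Iterable[FieldSample],
    manifest: pd.DataFrame,
    directory: Path | str,
) -> Path:
    """Write all fields and a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    manifest = manifest.copy()
    paths = []
    for sample in samples:
        paths.append(str(write_field(sample, directory)))
    manifest["path"] = paths
    out = directory / "manifest.csv"
    manifest.to_csv(out, index=False)
    return out
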