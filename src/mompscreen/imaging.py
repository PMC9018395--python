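"""Image-analysis front end: nuclear segmentation, cell regions, granule detection.

Cells are identified from the nuclear (DAPI) channel; each nucleus seeds a
cell region by bounded expansion, and bright sub-resolution granules
(puncta) are detected in the two reporter channels (YFP for Venus-BAX,
Texas Red for OMI-mCherry) by white-top-hat enhancement followed by
local-maximum seeding and half-maximum region growing.  A granule is kept
only if its equivalent diameter lies within the configured range and its
integrated (background-free) intensity exceeds the channel threshold —
the two published stringency criteria of the assay.

Conventions: 0-based (row, col) pixel coordinates with pixel centres at
integer positions; all masks are full-frame boolean rasters or coordinate
arrays over the same frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat
from skimage.segmentation import expand_labels, watershed

log = logging.getLogger(__name__)

#: canonical channel order: nuclear stain, Venus-BAX, OMI-mCherry
CHANNELS = ("DAPI", "YFP", "TexasRed")
REPORTER_CHANNELS = ("YFP", "TexasRed")

UINT16_MAX = 65535


@dataclass
class FieldImage:
    """One imaging site: three co-registered single-channel rasters."""

    channels: Mapping[str, np.ndarray]
    well_id: str
    site_index: int
    pixel_size: float = 0.65  # micrometres per pixel

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, img in self.channels.items():
            if np.asarray(img).ndim != 2:
                raise ValueError(f"channel {ch} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class ChannelParams:
    """Granule-detection parameters for one reporter channel.

    ``min_diameter``/``max_diameter`` bound the accepted equivalent
    diameter (px); ``intensity_threshold`` is the minimum integrated
    top-hat intensity of a granule; ``peak_height`` is the minimum
    top-hat amplitude for a local maximum to seed a granule;
    ``fluorescence_floor`` is the minimum integrated background-subtracted
    cell fluorescence below which a cell counts as non-fluorescent.
    """

    min_diameter: float = 2.0
    max_diameter: float = 10.0
    intensity_threshold: float = 5000.0
    peak_height: float = 300.0
    fluorescence_floor: float = 60000.0

    def __post_init__(self) -> None:
        if not self.min_diameter < self.max_diameter:
            raise ValueError("min_diameter must be < max_diameter")


def _default_channels() -> dict[str, ChannelParams]:
    return {"YFP": ChannelParams(), "TexasRed": ChannelParams()}


@dataclass
class DetectionParams:
    """All thresholds of the analysis, adjusted for stringency once per run."""

    nucleus_smooth_sigma: float = 2.0
    nucleus_threshold_method: str = "otsu"
    min_fragment_area: float = 12.0
    max_fragment_area: float = 4000.0
    normal_nucleus_min_area: float = 230.0
    fragment_grouping_radius: float = 15.0
    watershed_min_distance: int = 7
    cell_expansion_radius: float = 14.0
    channels: dict[str, ChannelParams] = field(default_factory=_default_channels)

    def __post_init__(self) -> None:
        for name in ("min_fragment_area", "max_fragment_area",
                     "normal_nucleus_min_area", "fragment_grouping_radius",
                     "cell_expansion_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "DetectionParams":
        """All intensity thresholds multiplied by ``factor`` (geometry unchanged)."""
        chans = {
            ch: replace(
                p,
                intensity_threshold=p.intensity_threshold * factor,
                peak_height=p.peak_height * factor,
                fluorescence_floor=p.fluorescence_floor * factor,
            )
            for ch, p in self.channels.items()
        }
        out = replace(self)
        out.channels = chans
        return out


@dataclass
class NucleusObject:
    """A segmented nucleus; possibly several grouped apoptotic fragments."""

    label: int
    centroid: tuple[float, float]
    area: float
    mean_dapi_intensity: float
    fragment_count: int
    fragmented: bool
    coords: np.ndarray = field(repr=False)  # (n, 2) pixel coordinates


@dataclass
class CellRegion:
    cell_id: int
    coords: np.ndarray = field(repr=False)  # (n, 2) pixel coordinates


@dataclass
class Granule:
    channel: str
    centroid: tuple[float, float]
    equivalent_diameter: float
    integrated_intensity: float
    cell_id: int


# ---------------------------------------------------------------------------
# nuclear segmentation


def _robust_sigma(img: np.ndarray) -> float:
    med = np.median(img)
    return float(1.4826 * np.median(np.abs(img - med)))


def segment_nuclei(dapi: np.ndarray, params: DetectionParams) -> list[NucleusObject]:
    """Segment nuclei in a DAPI image and group apoptotic fragments.

    Thresholds a smoothed image (Otsu with a bimodality guard), fills
    holes, splits touching nuclei by distance-transform watershed, drops
    objects outside the fragment-area bounds, and merges nearby sub-normal
    fragments into a single :class:`NucleusObject` with
    ``fragment_count > 1``.  An object (merged or single) is *fragmented*
    when its total area falls below ``normal_nucleus_min_area``.

    Empty/constant images yield an empty list rather than an error.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("dapi must be a 2-D array")
    if dapi.size == 0 or np.ptp(dapi) == 0:
        return []
    if np.mean(dapi >= UINT16_MAX) > 0.001:
        log.warning("DAPI image appears saturated (>0.1%% at max value)")

    smoothed = gaussian(dapi, sigma=params.nucleus_smooth_sigma, preserve_range=True)
    if params.nucleus_threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {params.nucleus_threshold_method!r}")
    thr = threshold_otsu(smoothed)

    # bimodality guard: on a pure-noise field Otsu splits the noise in half;
    # require the threshold to clear the background by several noise widths.
    sigma = _robust_sigma(smoothed)
    if thr < np.median(smoothed) + 4.0 * max(sigma, 1e-12):
        return []

    binary = smoothed > thr
    binary = ndi.binary_fill_holes(binary)
    lab0, n0 = ndi.label(binary)
    if n0:
        sizes = np.bincount(lab0.ravel())
        keep = sizes >= params.min_fragment_area
        keep[0] = False
        binary = keep[lab0]
    if not binary.any():
        return []

    # watershed within each connected component only (nuclei are sparse)
    comp_lab, n_comp = ndi.label(binary)
    labels = np.zeros(binary.shape, dtype=np.int32)
    next_label = 1
    for comp_id, sl in enumerate(ndi.find_objects(comp_lab), start=1):
        if sl is None:
            continue
        local = comp_lab[sl] == comp_id
        distance = ndi.distance_transform_edt(local)
        peaks = peak_local_max(
            distance, min_distance=params.watershed_min_distance, labels=local,
            exclude_border=False,
        )
        if len(peaks) <= 1:
            labels[sl][local] = next_label
            next_label += 1
            continue
        markers = np.zeros(local.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers, _ = ndi.label(markers)
        ws = watershed(-distance, markers, mask=local)
        labels[sl][local] = np.where(local, ws + (next_label - 1), 0)[local]
        next_label += int(ws.max())

    objs = []
    for rp in regionprops(labels, intensity_image=dapi):
        if rp.area < params.min_fragment_area or rp.area > params.max_fragment_area:
            continue
        objs.append(rp)
    if not objs:
        return []

    # group sub-normal fragments by single linkage on centroid distance
    small = [i for i, rp in enumerate(objs) if rp.area < params.normal_nucleus_min_area]
    parent = list(range(len(objs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cents = np.array([rp.centroid for rp in objs])
    for ii, i in enumerate(small):
        for j in small[ii + 1:]:
            if np.hypot(*(cents[i] - cents[j])) <= params.fragment_grouping_radius:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(objs)):
        groups.setdefault(find(i), []).append(i)

    nuclei: list[NucleusObject] = []
    for members in groups.values():
        rps = [objs[i] for i in members]
        area = float(sum(rp.area for rp in rps))
        centroid = tuple(
            float(sum(rp.centroid[k] * rp.area for rp in rps) / area) for k in (0, 1)
        )
        mean_int = float(sum(rp.intensity_mean * rp.area for rp in rps) / area)
        coords = np.vstack([rp.coords for rp in rps])
        nuclei.append(
            NucleusObject(
                label=min(rp.label for rp in rps),
                centroid=centroid,
                area=area,
                mean_dapi_intensity=mean_int,
                fragment_count=len(rps),
                fragmented=area < params.normal_nucleus_min_area,
                coords=coords,
            )
        )
    # relabel sequentially for stable downstream ids
    nuclei.sort(key=lambda n: (n.centroid[0], n.centroid[1]))
    for new_label, nuc in enumerate(nuclei, start=1):
        nuc.label = new_label
    return nuclei


# ---------------------------------------------------------------------------
# cell regions


def nucleus_label_image(nuclei: Sequence[NucleusObject], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for nuc in nuclei:
        lab[nuc.coords[:, 0], nuc.coords[:, 1]] = nuc.label
    return lab


def assign_cell_regions(
    nuclei: Sequence[NucleusObject],
    shape: tuple[int, int],
    params: DetectionParams,
) -> list[CellRegion]:
    """Expand each nucleus into a disjoint cell region.

    Every background pixel within ``cell_expansion_radius`` of a nucleus is
    assigned to its nearest nucleus; collisions are resolved by the
    nearest-nucleus rule, so the partition is disjoint by construction.
    """
    labels = [n.label for n in nuclei]
    if len(set(labels)) != len(labels):
        raise ValueError("nucleus labels must be unique")
    if not nuclei:
        return []
    lab = nucleus_label_image(nuclei, shape)
    expanded = expand_labels(lab, distance=params.cell_expansion_radius)
    regions = []
    for nuc in nuclei:
        rows, cols = np.nonzero(expanded == nuc.label)
        regions.append(CellRegion(cell_id=nuc.label, coords=np.column_stack([rows, cols])))
    return regions


def region_label_image(regions: Sequence[CellRegion], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for reg in regions:
        lab[reg.coords[:, 0], reg.coords[:, 1]] = reg.cell_id
    return lab


# ---------------------------------------------------------------------------
# granule detection


def detect_granules(
    channel_image: np.ndarray,
    regions: Sequence[CellRegion],
    params: DetectionParams,
    channel: str,
) -> list[Granule]:
    """Detect suprathreshold granules in one reporter channel.

    White-top-hat at the maximum-diameter scale suppresses diffuse
    fluorescence; local maxima above ``peak_height`` seed granules, each
    grown to its half-maximum support to measure equivalent diameter and
    integrated intensity.  A granule is kept only if the diameter lies in
    the configured range, the integrated intensity exceeds the channel
    threshold, and its centroid falls inside a cell region.
    """
    if channel not in params.channels:
        raise ValueError(f"unknown channel {channel!r}; configured: {sorted(params.channels)}")
    p = params.channels[channel]
    img = np.asarray(channel_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("channel_image must be 2-D")
    if not regions:
        return []

    radius = int(np.ceil(p.max_diameter / 2.0)) + 2
    footprint = disk(radius, decomposition="sequence")
    tophat = white_tophat(img, footprint=footprint)
    # light smoothing for seeding only, to avoid shot-noise double peaks
    seed_img = gaussian(tophat, sigma=1.0, preserve_range=True)
    min_dist = max(2, int(round(p.min_diameter)))
    peaks = peak_local_max(
        seed_img, min_distance=min_dist, threshold_abs=p.peak_height,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return []

    lab = region_label_image(regions, img.shape)
    win = int(np.ceil(p.max_diameter)) + 2
    granules: list[Granule] = []
    h, w = img.shape
    for r0, c0 in peaks:
        rlo, rhi = max(0, r0 - win), min(h, r0 + win + 1)
        clo, chi = max(0, c0 - win), min(w, c0 + win + 1)
        window = tophat[rlo:rhi, clo:chi]
        peak_val = tophat[r0, c0]
        if peak_val <= 0:
            continue
        support = window >= 0.5 * peak_val
        comp = cc_label(support)
        comp_id = comp[r0 - rlo, c0 - clo]
        if comp_id == 0:
            continue
        mask = comp == comp_id
        area = int(mask.sum())
        eq_diam = float(np.sqrt(4.0 * area / np.pi))
        integrated = float(window[mask].sum())
        rr, cc = np.nonzero(mask)
        wts = window[rr, cc]
        cy = float((rr * wts).sum() / wts.sum()) + rlo
        cx = float((cc * wts).sum() / wts.sum()) + clo
        if not (p.min_diameter <= eq_diam <= p.max_diameter):
            continue
        if integrated < p.intensity_threshold:
            continue
        cell_id = int(lab[int(round(cy)), int(round(cx))])
        if cell_id == 0:
            continue
        granules.append(
            Granule(
                channel=channel,
                centroid=(cy, cx),
                equivalent_diameter=eq_diam,
                integrated_intensity=integrated,
                cell_id=cell_id,
            )
        )
    return granules
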