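"""Classical 3D instance segmentation of adipocytes.

A marker-controlled watershed on the Euclidean distance transform of the
cell foreground. This is a self-contained classical stand-in for
learning-based segmenters: externally produced label stacks (e.g.
Cellpose ``*_masks`` TIFFs) can be ingested instead via
:func:`adipo3d.stacks.load_labels` and fed straight to the morphometry
stage.

Pipeline for two-channel tissue stacks: Gaussian smoothing of both
channels → foreground = high-lipid voxels that are not ECM wall →
distance transform in physical units (so anisotropic spacing is handled)
→ seeds from the h-maxima of the distance map, merged within a minimum
separation → watershed on the negated distance map restricted to the
foreground. Single-channel (extracted-cell) stacks threshold the lipid
channel, fill holes, and split touching cells the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import InputError
from .stacks import ImageStack, LabelStack

#: 26-connected structuring element used for components, maxima and the
#: watershed neighbourhood.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tunable parameters of the watershed segmenter.

    ``expected_diameter`` (µm) scales the seed-detection depth: seeds are
    h-maxima of the distance map with depth
    ``h_maxima_depth × expected_diameter / 2``. Defaults are 60 µm for
    tissue and 40 µm for extracted cells. ``ecm_threshold`` selects the
    ECM wall veto: ``"otsu"`` (automatic — veto voxels where the smoothed
    ECM exceeds the smoothed lipid signal) or ``"fixed"`` (absolute veto
    at ``ecm_threshold_value``). The lipid channel is Otsu-thresholded
    unless ``lipid_threshold_value`` is set. Thresholds actually used are
    recorded in ``resolved_thresholds`` for the run manifest.
    """

    expected_diameter: float = 60.0
    smoothing_sigma: float = 1.0  # µm
    ecm_threshold: str = "otsu"
    ecm_threshold_value: float | None = None
    lipid_threshold_value: float | None = None
    h_maxima_depth: float = 0.25  # fraction of expected radius
    min_seed_separation: float = 15.0  # µm
    resolved_thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.expected_diameter <= 0:
            raise ValueError("expected_diameter must be positive")
        if self.ecm_threshold not in ("otsu", "fixed"):
            raise ValueError("ecm_threshold must be 'otsu' or 'fixed'")
        if self.ecm_threshold == "fixed" and self.ecm_threshold_value is None:
            raise ValueError("fixed ecm_threshold requires ecm_threshold_value")


DEFAULT_IN_SITU = SegmentationParams(expected_diameter=60.0)
DEFAULT_EX_SITU = SegmentationParams(expected_diameter=40.0)


@dataclass
class MatchReport:
    """Greedy one-to-one matching of predicted to ground-truth cells."""

    n_truth: int
    n_predicted: int
    n_matched: int
    iou_threshold: float
    truth_ious: dict[int, float]  # best matched IoU per truth label (0 if none)

    def __post_init__(self):
        assert 0 <= self.n_matched <= min(self.n_truth, self.n_predicted)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0


def _smooth(volume: np.ndarray, sigma_um: float, spacing) -> np.ndarray:
    if sigma_um <= 0:
        return volume.astype(np.float32)
    sigmas = [sigma_um / s for s in spacing]
    return ndimage.gaussian_filter(volume.astype(np.float32), sigmas)


def _threshold(volume: np.ndarray, fixed: float | None) -> float:
    if fixed is not None:
        return float(fixed)
    if np.ptp(volume) == 0:
        return float(volume.max()) + 1.0  # flat image: nothing is foreground
    return float(threshold_otsu(volume))


def _merge_close_seeds(markers: np.ndarray, min_sep_um: float, spacing) -> np.ndarray:
    """Union seed blobs whose centroids are closer than ``min_sep_um``."""
    ids = np.unique(markers)
    ids = ids[ids > 0]
    if ids.size < 2 or min_sep_um <= 0:
        return markers
    centroids = np.array(ndimage.center_of_mass(markers > 0, markers, ids))
    centroids = centroids * np.asarray(spacing)[None, :]
    parent = {int(i): int(i) for i in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    for i, j in zip(*np.nonzero(np.triu(d < min_sep_um, 1))):
        ri, rj = find(int(ids[i])), find(int(ids[j]))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    lut = np.zeros(int(ids.max()) + 1, dtype=markers.dtype)
    for i in ids:
        lut[int(i)] = find(int(i))
    return lut[markers]


def _watershed_split(foreground: np.ndarray, params: SegmentationParams, spacing) -> np.ndarray:
    """Seeded watershed of a binary foreground into cell instances."""
    if not foreground.any():
        return np.zeros(foreground.shape, dtype=np.int32)
    edt = ndimage.distance_transform_edt(foreground, sampling=spacing)
    h = max(params.h_maxima_depth * params.expected_diameter / 2.0, max(spacing))
    maxima = h_maxima(edt, h, footprint=CONN26)
    markers, _ = ndimage.label(maxima, structure=CONN26)
    markers = _merge_close_seeds(markers, params.min_seed_separation, spacing)
    if markers.max() == 0:  # degenerate: every component is its own cell
        markers, _ = ndimage.label(foreground, structure=CONN26)
    labels = watershed(-edt, markers, mask=foreground, connectivity=CONN26)
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max()) + 1 if ids.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]


def segment_in_situ(stack: ImageStack, params: SegmentationParams | None = None) -> LabelStack:
    """Segment a two-channel (ECM + lipid) tissue stack into cells.

    Foreground voxels are bright in the smoothed lipid channel and
    lipid-dominated (lipid > ECM after smoothing), so the bright ECM
    walls separate neighbouring cells before the watershed splits any
    remaining bridges. The channel comparison is invariant to depth
    attenuation, which scales both channels alike. With
    ``ecm_threshold="fixed"`` an absolute ECM veto at
    ``ecm_threshold_value`` is applied instead of the comparison.
    An empty foreground yields an empty label stack (0 labels).
    """
    params = params or DEFAULT_IN_SITU
    if stack.n_channels < 2:
        raise InputError("in situ segmentation requires ECM + lipid channels")
    ecm = _smooth(stack.channel(0), params.smoothing_sigma, stack.spacing)
    lipid = _smooth(stack.channel(1), params.smoothing_sigma, stack.spacing)
    t_lipid = _threshold(lipid, params.lipid_threshold_value)
    params.resolved_thresholds = {"lipid": t_lipid}
    if params.ecm_threshold == "fixed":
        params.resolved_thresholds["ecm"] = params.ecm_threshold_value
        foreground = (lipid >= t_lipid) & (ecm < params.ecm_threshold_value)
    else:
        foreground = (lipid >= t_lipid) & (lipid > ecm)
    return LabelStack(_watershed_split(foreground, params, stack.spacing), stack.spacing)


def segment_ex_situ(stack: ImageStack, params: SegmentationParams | None = None) -> LabelStack:
    """Segment a single-channel extracted-cell stack.

    Threshold → fill holes → distance-transform watershed to split
    touching cells.
    """
    params = params or DEFAULT_EX_SITU
    if stack.n_channels != 1:
        raise InputError("ex situ segmentation expects a single-channel stack")
    lipid = _smooth(stack.channel(0), params.smoothing_sigma, stack.spacing)
    t = _threshold(lipid, params.lipid_threshold_value)
    params.resolved_thresholds = {"lipid": t}
    foreground = ndimage.binary_fill_holes(lipid >= t)
    return LabelStack(_watershed_split(foreground, params, stack.spacing), stack.spacing)


def match_labels(
    predicted: LabelStack, truth: LabelStack, iou_threshold: float = 0.5
) -> MatchReport:
    """Score a predicted segmentation against ground truth.

    Candidate (truth, predicted) pairs are every overlapping label pair;
    they are matched greedily one-to-one by descending IoU, keeping pairs
    with IoU ≥ ``iou_threshold``. Counts are invariant to relabelling of
    either stack.
    """
    if predicted.shape != truth.shape:
        raise InputError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    t = truth.labels.ravel()
    p = predicted.labels.ravel()
    t_ids, t_areas = np.unique(t[t > 0], return_counts=True)
    p_ids, p_areas = np.unique(p[p > 0], return_counts=True)
    t_area = dict(zip(t_ids.tolist(), t_areas.tolist()))
    p_area = dict(zip(p_ids.tolist(), p_areas.tolist()))

    both = (t > 0) & (p > 0)
    pairs, inter = np.unique(
        np.stack([t[both], p[both]]).astype(np.int64), axis=1, return_counts=True
    )
    candidates = []
    for (ti, pi), n in zip(pairs.T.tolist(), inter.tolist()):
        union = t_area[ti] + p_area[pi] - n
        candidates.append((n / union, ti, pi))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    truth_ious = {int(i): 0.0 for i in t_ids}
    used_t, used_p = set(), set()
    n_matched = 0
    for iou, ti, pi in candidates:
        if iou < iou_threshold:
            break
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        truth_ious[ti] = iou
        n_matched += 1
    return MatchReport(
        n_truth=int(t_ids.size),
        n_predicted=int(p_ids.size),
        n_matched=n_matched,
        iou_threshold=float(iou_threshold),
        truth_ious=truth_ious,
    )
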