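"""3D puncta segmentation, voxel-overlap colocalization and the CCF test.

Objects are connected components (26-connectivity by default) of voxels
above an explicit intensity threshold inside an optional nuclear mask;
components below a minimum size (10 voxels by default) are discarded as
background.  A channel-B object colocalizes when it shares at least one
voxel with any channel-A object.  Randomness of colocalization is tested
with the cross-correlation function: Pearson correlation between the two
channels as one is translated voxel-wise along a lateral axis — a global
peak at zero shift that stands above the far-shift baseline indicates
non-random colocalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

__all__ = [
    "Volume",
    "SegmentedObject",
    "ColocSummary",
    "CCFProfile",
    "segment_objects",
    "coloc_by_voxel_overlap",
    "compare_object_properties",
    "ccf_van_steensel",
    "normalize_nuclear_intensity",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbour count -> skimage connectivity


@dataclass
class Volume:
    """A single-channel 3D intensity volume with physical voxel size.

    ``voxel_size`` is µm per axis in (z, y, x) order; ``mask`` restricts the
    analysis to a region (e.g. the stained nuclear volume).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.1, 0.05, 0.05)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume.data must be a 3D array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be > 0 on every axis")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must equal intensity shape")


@dataclass
class SegmentedObject:
    object_id: str
    channel: str
    voxel_count: int
    intensity_sum: float
    length_um: float
    centroid_um: tuple[float, float, float]
    voxel_indices: np.ndarray = field(repr=False)  # flat indices into the volume
    shape: tuple[int, int, int] = field(repr=False, default=(0, 0, 0))

    @property
    def physical_volume_um3(self) -> float:
        return self.voxel_count * self._voxel_volume

    _voxel_volume: float = field(repr=False, default=0.0)


@dataclass(frozen=True)
class ColocSummary:
    n_objects_b: int
    n_coloc: int

    @property
    def pct_coloc(self) -> float:
        if self.n_objects_b == 0:
            return float("nan")
        return 100.0 * self.n_coloc / self.n_objects_b


@dataclass(frozen=True)
class CCFProfile:
    shifts: np.ndarray  # signed voxel shifts, symmetric about 0
    r: np.ndarray  # Pearson r at each shift
    peak_shift: int
    verdict: str  # "random" | "nonrandom"


def _object_length_um(coords: np.ndarray, voxel_size: np.ndarray) -> float:
    """Maximal physical extent along the first principal axis of the voxels.

    Voxel centres are projected onto the principal axis (in µm space) and
    the peak-to-peak extent is widened by one voxel footprint along that
    axis, so a single voxel has length equal to its own size.
    """
    xyz = coords * voxel_size
    centered = xyz - xyz.mean(axis=0)
    if len(coords) == 1:
        return float(voxel_size.max())
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    footprint = float(np.abs(axis) @ voxel_size)
    return float(np.ptp(proj) + footprint)


def segment_objects(
    vol: Volume,
    threshold: float,
    min_voxels: int = 10,
    connectivity: int = 26,
    channel: str = "A",
) -> list[SegmentedObject]:
    """Segment puncta as connected components of voxels above ``threshold``.

    Components smaller than ``min_voxels`` are discarded as background (the
    default keeps objects of 10 voxels or more).  Thresholding is an explicit
    input — absolute intensity units; no automatic threshold is applied.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if vol.mask is not None and not vol.mask.any():
        raise ValueError("nuclear mask is empty")
    binary = vol.data > threshold
    if vol.mask is not None:
        binary &= vol.mask
    labels = measure.label(binary, connectivity=_CONNECTIVITY[connectivity])
    voxel_size = np.asarray(vol.voxel_size, dtype=float)
    voxel_volume = float(np.prod(voxel_size))
    objects: list[SegmentedObject] = []
    for region in measure.regionprops(labels, intensity_image=vol.data):
        if region.area < min_voxels:
            continue
        coords = region.coords
        flat = np.ravel_multi_index(coords.T, vol.data.shape)
        centroid = tuple(float(c) for c in (np.asarray(region.centroid) * voxel_size))
        obj = SegmentedObject(
            object_id=f"{channel}_{len(objects):04d}",
            channel=channel,
            voxel_count=int(region.area),
            intensity_sum=float(vol.data[tuple(coords.T)].sum()),
            length_um=_object_length_um(coords, voxel_size),
            centroid_um=centroid,
            voxel_indices=flat,
            shape=vol.data.shape,
        )
        obj._voxel_volume = voxel_volume
        objects.append(obj)
    return objects


def coloc_by_voxel_overlap(
    objects_a: list[SegmentedObject], objects_b: list[SegmentedObject]
) -> tuple[np.ndarray, ColocSummary]:
    """Flag each B object that shares >= 1 voxel with any A object.

    Returns the per-B-object boolean flags (in input order) and a summary
    with the percentage of colocalizing B objects.
    """
    shapes = {o.shape for o in objects_a} | {o.shape for o in objects_b}
    if len(shapes) > 1:
        raise ValueError("objects come from volumes of different shapes")
    if objects_a:
        occupancy = np.zeros(int(np.prod(objects_a[0].shape)), dtype=bool)
        for obj in objects_a:
            occupancy[obj.voxel_indices] = True
        flags = np.array([occupancy[o.voxel_indices].any() for o in objects_b], dtype=bool)
    else:
        flags = np.zeros(len(objects_b), dtype=bool)
    return flags, ColocSummary(n_objects_b=len(objects_b), n_coloc=int(flags.sum()))


_PROPERTIES = ("intensity_sum", "voxel_count", "length_um")


def compare_object_properties(
    objects_b: list[SegmentedObject], flags: np.ndarray
) -> dict[str, dict]:
    """Group statistics (mean, SD, one-way ANOVA) per object property.

    Compares colocalizing vs non-colocalizing B objects on intensity sum,
    voxel count and length.  If either group is empty the statistics are
    omitted and the property flagged.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(objects_b):
        raise ValueError("flags length must match the number of B objects")
    out: dict[str, dict] = {}
    for prop in _PROPERTIES:
        values = np.array([getattr(o, prop) for o in objects_b], dtype=float)
        coloc, non = values[flags], values[~flags]
        entry: dict = {
            "n_coloc": int(coloc.size),
            "n_noncoloc": int(non.size),
        }
        if coloc.size == 0 or non.size == 0:
            entry["flag"] = "empty_group"
            logger.warning("property %s: one group empty; ANOVA omitted", prop)
        else:
            f_stat, p = stats.f_oneway(coloc, non)
            entry.update(
                mean_coloc=float(coloc.mean()),
                sd_coloc=float(coloc.std(ddof=1)) if coloc.size > 1 else 0.0,
                mean_noncoloc=float(non.mean()),
                sd_noncoloc=float(non.std(ddof=1)) if non.size > 1 else 0.0,
                anova_f=float(f_stat),
                anova_p=float(p),
            )
        out[prop] = entry
    return out


def _shifted_views(a: np.ndarray, b: np.ndarray, dx: int, axis: int):
    """Overlapping views of ``a`` and ``b`` with ``b`` read at index + dx."""
    n = a.shape[axis]
    if abs(dx) >= n:
        raise ValueError("shift exceeds axis extent")
    sl_a = [slice(None)] * a.ndim
    sl_b = [slice(None)] * a.ndim
    if dx >= 0:
        sl_a[axis] = slice(0, n - dx)
        sl_b[axis] = slice(dx, n)
    else:
        sl_a[axis] = slice(-dx, n)
        sl_b[axis] = slice(0, n + dx)
    return a[tuple(sl_a)], b[tuple(sl_b)]


def ccf_van_steensel(
    vol_a: Volume, vol_b: Volume, max_shift: int, axis: int = 2
) -> CCFProfile:
    """Cross-correlation function between two channels along one lateral axis.

    For each signed shift dx in [-max_shift, max_shift] the Pearson r between
    channel A and channel B read at index + dx is computed over the in-mask
    overlap region; the reported ``peak_shift`` is the dx that best realigns
    B with A.  Verdict is ``"nonrandom"`` iff r at dx = 0 is the global
    maximum and exceeds mean + 3 SD of the baseline r values at
    |dx| > max_shift / 2.
    """
    if vol_a.data.shape != vol_b.data.shape:
        raise ValueError("volumes must have identical shapes")
    if not 0 < max_shift < vol_a.data.shape[axis]:
        raise ValueError("max_shift must be positive and below the axis extent")
    mask = None
    if vol_a.mask is not None or vol_b.mask is not None:
        mask = np.ones(vol_a.data.shape, dtype=bool)
        if vol_a.mask is not None:
            mask &= vol_a.mask
        if vol_b.mask is not None:
            mask &= vol_b.mask

    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.full(shifts.shape, np.nan)
    for i, dx in enumerate(shifts):
        a_view, b_view = _shifted_views(vol_a.data, vol_b.data, int(dx), axis)
        if mask is not None:
            m_a, m_b = _shifted_views(mask, mask, int(dx), axis)
            sel = m_a & m_b
            if not sel.any():
                logger.warning("empty overlap at shift %d; omitted", dx)
                continue
            x, y = a_view[sel], b_view[sel]
        else:
            x, y = a_view.ravel(), b_view.ravel()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("zero variance at shift %d; omitted", dx)
            continue
        r[i] = np.corrcoef(x, y)[0, 1]

    valid = ~np.isnan(r)
    peak_shift = int(shifts[valid][np.argmax(r[valid])])
    zero_idx = max_shift
    baseline = r[valid & (np.abs(shifts) > max_shift / 2)]
    nonrandom = (
        not np.isnan(r[zero_idx])
        and peak_shift == 0
        and baseline.size >= 2
        and r[zero_idx] > baseline.mean() + 3 * baseline.std(ddof=1)
    )
    return CCFProfile(
        shifts=shifts,
        r=r,
        peak_shift=peak_shift,
        verdict="nonrandom" if nonrandom else "random",
    )


def normalize_nuclear_intensity(values, reference) -> np.ndarray:
    """Divide intensities by the median of a reference population.

    Mirrors per-experiment normalization of nuclear staining intensities to
    the median of the control sample.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference population is empty")
    med = float(np.median(ref))
    if med <= 0:
        raise ValueError("reference median must be > 0")
    return np.asarray(values, dtype=float) / med
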