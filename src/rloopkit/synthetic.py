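"""Synthetic-data generators with recorded ground truth.

Every analysis stage in :mod:`rloopkit` can be exercised on data produced
here: DNA-fibre sister-fork populations with stall-induced asymmetry,
two-channel 3D puncta volumes with a controllable colocalized fraction,
birth--death locus intensity traces, per-gene peak/expression tables with a
shared confounder, and growth plates under a multiplicative independence
null.  Each generator takes a frozen config carrying its own ``seed`` and
draws all randomness from one ``numpy.random.Generator``, so identical
config implies bitwise-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FibreSimConfig",
    "VolumeSimConfig",
    "KineticsSimConfig",
    "GenomicsSimConfig",
    "PlacementError",
    "FibrePopulation",
    "VolumePair",
    "LocusTraceSim",
    "GenomicsSim",
    "gen_fibre_population",
    "gen_two_channel_volume",
    "gen_locus_trace",
    "gen_gene_peak_table",
    "gen_growth_plate",
]

KB_PER_UM = 2.59  # fibre-length to kilobase conversion used throughout


class PlacementError(RuntimeError):
    """Raised when puncta cannot be placed in the volume within bounded retries."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibreSimConfig:
    """Sister-fork fibre population parameters.

    Defaults emulate a dual-pulse (20 min + 20 min) labelling experiment with
    ~250 measured tracks per condition and typical human fork speeds around
    1.5 kb/min.  ``stall_prob`` is the probability that a sister-fork pair
    contains one stalled arm; the stalled arm loses ``stall_severity`` of its
    length, producing a longer/shorter ratio of 1/(1 - stall_severity) in the
    noise-free case.
    """

    n_tracks: int = 250
    mean_speed: float = 1.5  # kb/min
    speed_sd: float = 0.35  # kb/min
    stall_prob: float = 0.0
    stall_severity: float = 0.5  # fraction of arm length lost on stall
    pulse_min_first: float = 20.0
    pulse_min_second: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be > 0")
        if self.speed_sd < 0:
            raise ValueError("speed_sd must be >= 0")
        if not 0.0 <= self.stall_prob <= 1.0:
            raise ValueError("stall_prob must be in [0, 1]")
        if not 0.0 < self.stall_severity < 1.0 and self.stall_prob > 0:
            raise ValueError("stall_severity must be in (0, 1)")
        if self.pulse_min_first <= 0 or self.pulse_min_second <= 0:
            raise ValueError("pulse durations must be > 0")


@dataclass(frozen=True)
class VolumeSimConfig:
    """Two-channel 3D puncta volume parameters.

    Spheres stand in for nuclear puncta (channel A ~ remodeller foci,
    channel B ~ RNA:DNA-hybrid foci).  ``coloc_fraction`` is the probability
    that a B object is centred inside an A object and therefore shares at
    least one voxel with it.  Non-colocalized B objects are kept at a
    centre-to-centre distance greater than the sum of radii so they share no
    voxels by construction.  The default colocalized fraction sits in the
    middle of the 25-52 % range reported for hybrid foci overlapping
    remodeller foci in super-resolved nuclei.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.1, 0.05, 0.05)  # µm, (z, y, x)
    n_objects_a: int = 50
    n_objects_b: int = 50
    coloc_fraction: float = 0.4
    radius_mean: float = 2.5  # voxels
    radius_sd: float = 0.5
    intensity_mean: float = 200.0  # arbitrary units
    intensity_sd: float = 40.0
    noise_sd: float = 5.0
    seed: int = 0
    max_retries: int = 500

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be three positive extents")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive on all axes")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.n_objects_a < 0 or self.n_objects_b < 0:
            raise ValueError("object counts must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class KineticsSimConfig:
    """Birth--death locus trace parameters.

    The latent R-loop count follows an immigration--death process: new loops
    form at ``formation_rate`` (events/min) and each existing loop resolves
    independently at ``resolution_rate`` (per loop per min), giving a
    stationary mean of formation_rate/resolution_rate.  Sampling every
    ``dt_min`` for ``duration_min`` reproduces the 6-min / 1500-min live
    imaging regime.  Rate defaults are illustrative, not fitted: no measured
    per-locus formation or resolution rates exist to calibrate against.
    """

    duration_min: float = 1500.0
    dt_min: float = 6.0
    formation_rate: float = 0.5  # events/min
    resolution_rate: float = 0.01  # per R-loop per min
    n0: int = 50
    reporter_gain: float = 10.0  # intensity units per R-loop
    reporter_noise_sd: float = 5.0
    normalizer_mean: float = 100.0
    normalizer_noise_sd: float = 2.0
    seed: int = 0

    REPORTER_FLOOR: float = field(default=1e-6, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.formation_rate < 0 or self.resolution_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        if self.duration_min < self.dt_min:
            raise ValueError("duration_min must be >= dt_min")
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if self.reporter_gain <= 0:
            raise ValueError("reporter_gain must be > 0")
        if self.normalizer_mean <= 0:
            raise ValueError("normalizer_mean must be > 0")


@dataclass(frozen=True)
class GenomicsSimConfig:
    """Per-gene two-signal table with a shared expression confounder.

    Both signals (remodeller occupancy and hybrid abundance) load on the
    same lognormal expression covariate with weight ``expression_effect``
    and on a shared latent factor with weight ``direct_association``; the
    latter is the "true" association that survives partialling out
    expression.
    """

    n_genes: int = 2000
    expression_effect: float = 1.0
    direct_association: float = 0.5
    noise_sd: float = 1.0
    n_states: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


class FibrePopulation(NamedTuple):
    pairs: pd.DataFrame  # origin_id, left_um, right_um, pulse_min + truth
    tracks: pd.DataFrame  # track_id, first_len_um, second_len_um, pulses


class VolumePair(NamedTuple):
    channel_a: np.ndarray
    channel_b: np.ndarray
    truth: pd.DataFrame  # channel, object_id, z, y, x, radius, intensity, coloc


class LocusTraceSim(NamedTuple):
    trace: pd.DataFrame  # t_min, reporter, normalizer
    latent_n: np.ndarray  # integer R-loop count at each timepoint


class GenomicsSim(NamedTuple):
    genes: pd.DataFrame  # gene_id, chrom, start, end, expression + signals
    peaks_a: pd.DataFrame  # chrom, start, end (200 bp, remodeller channel)
    peaks_b: pd.DataFrame  # chrom, start, end (200 bp, hybrid channel)
    states: pd.DataFrame  # chrom, start, end, state


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws clipped away from zero; exact when sd == 0."""
    return np.clip(rng.normal(mean, sd, size=n), 1e-3 * mean, None)


def gen_fibre_population(cfg: FibreSimConfig) -> FibrePopulation:
    """Simulate a population of sister-fork pairs with optional one-arm stalls.

    Each origin fires two sister forks whose speeds are drawn independently
    from N(mean_speed, speed_sd).  With probability ``stall_prob`` one arm of
    the pair (side chosen uniformly) is stalled and retains only
    (1 - stall_severity) of its length.  Arm length in µm is
    speed * pulse / 2.59.  Ground-truth speeds and the stalled side are
    recorded per pair.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tracks
    cols_pairs = [
        "origin_id", "left_um", "right_um", "pulse_min",
        "left_speed_kb_min", "right_speed_kb_min", "stalled_arm",
    ]
    cols_tracks = [
        "track_id", "first_len_um", "second_len_um",
        "first_pulse_min", "second_pulse_min",
    ]
    if n == 0:
        return FibrePopulation(
            pd.DataFrame(columns=cols_pairs), pd.DataFrame(columns=cols_tracks)
        )

    left_speed = _positive_normal(rng, cfg.mean_speed, cfg.speed_sd, n)
    right_speed = _positive_normal(rng, cfg.mean_speed, cfg.speed_sd, n)
    stalled = rng.random(n) < cfg.stall_prob
    stall_side = np.where(rng.random(n) < 0.5, "left", "right")
    stalled_arm = np.where(stalled, stall_side, "none")
    keep = 1.0 - cfg.stall_severity
    left_factor = np.where(stalled_arm == "left", keep, 1.0)
    right_factor = np.where(stalled_arm == "right", keep, 1.0)

    p1 = cfg.pulse_min_first
    left_um = left_speed * p1 / KB_PER_UM * left_factor
    right_um = right_speed * p1 / KB_PER_UM * right_factor

    pairs = pd.DataFrame(
        {
            "origin_id": [f"origin_{i:05d}" for i in range(n)],
            "left_um": left_um,
            "right_um": right_um,
            "pulse_min": p1,
            "left_speed_kb_min": left_speed,
            "right_speed_kb_min": right_speed,
            "stalled_arm": stalled_arm,
        }
    )

    # Per-arm dual-pulse tracks: the second analogue pulse continues at the
    # same per-arm speed; a stalled arm is shortened in both labels.
    p2 = cfg.pulse_min_second
    arm_speed = np.concatenate([left_speed, right_speed])
    arm_factor = np.concatenate([left_factor, right_factor])
    tracks = pd.DataFrame(
        {
            "track_id": [f"track_{i:05d}" for i in range(2 * n)],
            "first_len_um": arm_speed * p1 / KB_PER_UM * arm_factor,
            "second_len_um": arm_speed * p2 / KB_PER_UM * arm_factor,
            "first_pulse_min": p1,
            "second_pulse_min": p2,
        }
    )
    return FibrePopulation(pairs, tracks)


def _sphere_voxels(shape: tuple[int, int, int], center: np.ndarray, radius: float):
    """Index grids for voxels whose centres lie within ``radius`` of ``center``."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, shape)
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    inside = dist2 <= radius**2
    return zz[inside], yy[inside], xx[inside]


def gen_two_channel_volume(cfg: VolumeSimConfig) -> VolumePair:
    """Render two 3D sphere-puncta channels with a known colocalized fraction.

    Channel A spheres are placed uniformly (no wrap-around; centres kept one
    radius inside the boundary).  Each channel B sphere is, with probability
    ``coloc_fraction``, centred strictly inside a random A sphere (guaranteed
    >= 1 shared voxel) and otherwise placed so that its centre is farther than
    the sum of radii from every A centre (guaranteed 0 shared voxels).
    Additive Gaussian noise is applied last.  The truth table records every
    centre, radius, intensity and per-B-object coloc flag.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape)

    def draw_radius() -> float:
        # clip keeps every sphere >= 19 voxels, above the 10-voxel size filter
        return float(np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd), 1.5, None))

    def draw_intensity() -> float:
        return float(np.clip(rng.normal(cfg.intensity_mean, cfg.intensity_sd),
                             0.05 * cfg.intensity_mean, None))

    def uniform_center(radius: float) -> np.ndarray:
        margin = radius + 1.0
        if np.any(shape - 2 * margin <= 0):
            raise PlacementError("object radius exceeds volume extent")
        return rng.uniform(margin, shape - margin)

    a_centers: list[np.ndarray] = []
    a_radii: list[float] = []
    rows = []
    vol_a = np.zeros(cfg.shape, dtype=float)
    vol_b = np.zeros(cfg.shape, dtype=float)

    for i in range(cfg.n_objects_a):
        r = draw_radius()
        c = uniform_center(r)
        inten = draw_intensity()
        zz, yy, xx = _sphere_voxels(cfg.shape, c, r)
        vol_a[zz, yy, xx] += inten
        a_centers.append(c)
        a_radii.append(r)
        rows.append(("A", f"A_{i:04d}", *c, r, inten, False))

    a_centers_arr = np.array(a_centers) if a_centers else np.empty((0, 3))
    a_radii_arr = np.array(a_radii)

    coloc_flags = rng.random(cfg.n_objects_b) < cfg.coloc_fraction
    if len(a_centers) == 0:
        coloc_flags[:] = False

    for j in range(cfg.n_objects_b):
        r = draw_radius()
        inten = draw_intensity()
        placed = False
        for _ in range(cfg.max_retries):
            if coloc_flags[j]:
                k = rng.integers(len(a_centers))
                host_c, host_r = a_centers_arr[k], a_radii_arr[k]
                # centre voxel of B must fall inside the host sphere
                offset = rng.normal(size=3)
                offset *= rng.uniform(0, max(host_r - 0.75, 0.1)) / np.linalg.norm(offset)
                c = host_c + offset
                margin = r + 1.0
                if np.any(c < margin) or np.any(c > shape - margin):
                    continue
            else:
                c = uniform_center(r)
                if len(a_centers) and np.any(
                    np.linalg.norm(a_centers_arr - c, axis=1) <= a_radii_arr + r + 1.0
                ):
                    continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place channel-B object {j} after {cfg.max_retries} retries"
            )
        zz, yy, xx = _sphere_voxels(cfg.shape, c, r)
        vol_b[zz, yy, xx] += inten
        rows.append(("B", f"B_{j:04d}", *c, r, inten, bool(coloc_flags[j])))

    if cfg.noise_sd > 0:
        vol_a += rng.normal(0, cfg.noise_sd, size=cfg.shape)
        vol_b += rng.normal(0, cfg.noise_sd, size=cfg.shape)

    truth = pd.DataFrame(
        rows, columns=["channel", "object_id", "z", "y", "x", "radius", "intensity", "coloc"]
    )
    return VolumePair(vol_a, vol_b, truth)


def gen_locus_trace(cfg: KineticsSimConfig) -> LocusTraceSim:
    """Sample a locus reporter/normalizer trace over a latent birth--death path.

    The count update per frame is the exact transition of the discretely
    observed immigration--death process: each existing loop survives the
    interval with probability exp(-resolution_rate * dt) (binomial
    thinning), and the loops formed during the interval that are still
    present at its end are Poisson with mean
    (formation_rate / resolution_rate) * (1 - exp(-resolution_rate * dt))
    — which reduces to formation_rate * dt as resolution_rate -> 0 and
    makes the stationary mean exactly formation_rate / resolution_rate.

    Reporter = gain * N + Gaussian noise (floored at a small positive value so
    ratios stay defined); normalizer = constant + Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(np.floor(cfg.duration_min / cfg.dt_min)) + 1
    t = np.arange(n_frames) * cfg.dt_min

    n_path = np.empty(n_frames, dtype=np.int64)
    n_path[0] = cfg.n0
    p_resolve = 1.0 - np.exp(-cfg.resolution_rate * cfg.dt_min)
    if cfg.resolution_rate > 0:
        lam = cfg.formation_rate / cfg.resolution_rate * p_resolve
    else:
        lam = cfg.formation_rate * cfg.dt_min
    for k in range(1, n_frames):
        born = rng.poisson(lam)
        died = rng.binomial(n_path[k - 1], p_resolve) if n_path[k - 1] > 0 else 0
        n_path[k] = n_path[k - 1] + born - died

    reporter = cfg.reporter_gain * n_path + rng.normal(0, cfg.reporter_noise_sd, n_frames)
    reporter = np.maximum(reporter, cfg.REPORTER_FLOOR)
    normalizer = cfg.normalizer_mean + rng.normal(0, cfg.normalizer_noise_sd, n_frames)

    trace = pd.DataFrame({"t_min": t, "reporter": reporter, "normalizer": normalizer})
    return LocusTraceSim(trace, n_path)


_COUNT_CAP = 60  # generous cap so rounding/clipping barely perturbs correlations


def gen_gene_peak_table(cfg: GenomicsSimConfig) -> GenomicsSim:
    """Generate a per-gene two-signal table plus toy BED peaks and states.

    signal = 2 + expression_effect * e + direct_association * u + noise,
    with e ~ lognormal shared by both signals and u ~ N(0,1) the shared
    direct-association factor.  Signals are discretized to non-negative peak
    counts; each gene's peaks are laid out as disjoint 200 bp intervals
    inside its body on a toy single-chromosome genome, and the genome is
    partitioned exactly into labelled chromatin-state intervals.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    e = rng.lognormal(mean=1.0, sigma=0.75, size=n)
    u = rng.normal(size=n)
    sig_a = 2.0 + cfg.expression_effect * e + cfg.direct_association * u \
        + rng.normal(0, cfg.noise_sd, n)
    sig_b = 2.0 + cfg.expression_effect * e + cfg.direct_association * u \
        + rng.normal(0, cfg.noise_sd, n)
    count_a = np.clip(np.rint(sig_a), 0, _COUNT_CAP).astype(int)
    count_b = np.clip(np.rint(sig_b), 0, _COUNT_CAP).astype(int)

    bin_width = 200
    slots = _COUNT_CAP + 2
    gene_len = bin_width * slots
    spacer = 400
    stride = gene_len + spacer
    starts = np.arange(n) * stride
    ends = starts + gene_len

    genes = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n)],
            "chrom": "chrS",
            "start": starts,
            "end": ends,
            "expression": e,
            "ino80_count": count_a,
            "drip_count": count_b,
            "latent_u": u,
        }
    )

    def _peaks(counts: np.ndarray) -> pd.DataFrame:
        chroms, p_starts = [], []
        for i, c in enumerate(counts):
            if c == 0:
                continue
            chosen = rng.choice(slots, size=c, replace=False)
            chosen.sort()
            p_starts.extend(starts[i] + chosen * bin_width)
            chroms.extend(["chrS"] * c)
        p_starts = np.asarray(p_starts, dtype=int)
        return pd.DataFrame(
            {"chrom": chroms, "start": p_starts, "end": p_starts + bin_width}
        )

    peaks_a = _peaks(count_a)
    peaks_b = _peaks(count_b)

    genome_len = int(n * stride)
    n_intervals = 3 * cfg.n_states
    cuts = np.sort(rng.choice(np.arange(1, genome_len // bin_width), size=n_intervals - 1,
                              replace=False)) * bin_width
    bounds = np.concatenate([[0], cuts, [genome_len]])
    labels = np.concatenate(
        [rng.permutation(cfg.n_states) + 1,
         rng.integers(1, cfg.n_states + 1, n_intervals - cfg.n_states)]
    )
    labels = rng.permutation(labels)
    states = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": bounds[:-1].astype(int),
            "end": bounds[1:].astype(int),
            "state": [f"state_{int(s)}" for s in labels],
        }
    )
    return GenomicsSim(genes, peaks_a, peaks_b, states)


def gen_growth_plate(
    effect_a: float,
    effect_b: float,
    interaction: float = 1.0,
    n_wells: int = 6,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a growth plate under a multiplicative epistasis model.

    Per-well growth (fraction of the control mean) is: control = 1,
    single conditions = their effect, combined = effect_a * effect_b *
    interaction, each plus N(0, noise_sd) well noise.  interaction = 1
    encodes the multiplicative independence null; interaction > 1 is rescue.
    """
    for name, eff in (("effect_a", effect_a), ("effect_b", effect_b)):
        if not 0.0 < eff <= 1.5:
            raise ValueError(f"{name} must be in (0, 1.5]")
    if interaction <= 0:
        raise ValueError("interaction must be > 0")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    truth = {
        "control": 1.0,
        "condition_a": effect_a,
        "condition_b": effect_b,
        "combined": effect_a * effect_b * interaction,
    }
    rows = []
    for cond, mu in truth.items():
        values = mu + rng.normal(0, noise_sd, n_wells)
        for w, v in enumerate(values):
            rows.append((f"{cond}_w{w:02d}", cond, v, mu))
    return pd.DataFrame(rows, columns=["well", "condition", "growth_frac", "true_growth_frac"])
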