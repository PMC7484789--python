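"""Genome-wide co-enrichment of two peak classes and qPCR normalization.

Peak sets (e.g. chromatin-remodeller ChIP-seq and DRIP-seq hybrid peaks,
typically 200 bp bins) are counted per gene body, correlated pairwise and
partially — controlling for gene expression — and profiled across a
chromatin-state segmentation as fold enrichment per overlap class
(both / one-only / neither).  All coordinates are 0-based half-open (BED
convention); an overlap requires >= 1 bp.  Interval arithmetic is delegated
to pyranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

__all__ = [
    "CorrelationResult",
    "QpcrResult",
    "count_peaks_per_gene",
    "pairwise_correlation",
    "partial_correlation",
    "classify_peak_overlap",
    "state_enrichment",
    "drip_qpcr_enrichment",
]

logger = logging.getLogger(__name__)

OVERLAP_CLASSES = ("INO80+DRIP", "DRIP", "INO80", "NoDRIP+NoINO80")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str


@dataclass(frozen=True)
class QpcrResult:
    enrichment: float
    background: bool  # flagged when the IP signal is at mock/background level


def _validate_intervals(df: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{name}: start >= end at row {bad[0]}")
    if (df["start"] < 0).any():
        raise ValueError(f"{name}: negative coordinates")
    return df


def _to_pr(df: pd.DataFrame, **extra) -> pr.PyRanges:
    data = {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
    data.update(extra)
    return pr.PyRanges(pd.DataFrame(data))


def count_peaks_per_gene(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Number of peaks overlapping each gene body by >= 1 bp.

    A peak overlapping several genes counts once for each.  ``genes`` needs
    chrom/start/end plus a ``gene_id`` column; the result is indexed by
    gene_id in the input gene order.
    """
    _validate_intervals(peaks, "peaks")
    _validate_intervals(genes, "genes")
    if "gene_id" not in genes.columns:
        raise ValueError("genes table requires a gene_id column")
    gene_pr = _to_pr(genes, gene_id=genes["gene_id"])
    if len(peaks) == 0:
        return pd.Series(0, index=pd.Index(genes["gene_id"], name="gene_id"))
    counted = gene_pr.count_overlaps(_to_pr(peaks)).as_df()
    counts = counted.set_index("gene_id")["NumberOverlaps"]
    return counts.reindex(genes["gene_id"]).astype(int)


def pairwise_correlation(x, y, method: str = "spearman") -> CorrelationResult:
    """Pairwise correlation between two per-gene abundance vectors.

    Spearman is the default (robust to the heavy-tailed distribution of
    per-gene counts); Pearson is available.  Two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(float(r), float(p), len(x), method)


def partial_correlation(x, y, z, method: str = "pearson") -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with a
    two-sided p-value from t = r sqrt((n-3)/(1-r^2)) on n-3 degrees of
    freedom.  ``method='spearman'`` applies the same formula to
    rank-transformed data.  Equivalent to correlating the OLS residuals of
    x~z and y~z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y and z must be 1D vectors of equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if method == "spearman":
        x, y, z = (stats.rankdata(v) for v in (x, y, z))
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if np.isclose(abs(r_xz), 1.0) or np.isclose(abs(r_yz), 1.0):
        raise ValueError("degenerate: a variable is collinear with the covariate")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
    return CorrelationResult(r, float(p), n, f"partial_{method}")


def classify_peak_overlap(
    ino80: pd.DataFrame, drip: pd.DataFrame, genome_bins: pd.DataFrame
) -> pd.DataFrame:
    """Classify genome bins by presence of each peak type (>= 1 bp overlap).

    Returns the bins with an added ``overlap_class`` column taking values
    "INO80+DRIP", "DRIP", "INO80" or "NoDRIP+NoINO80"; the four classes
    partition the bins.
    """
    _validate_intervals(genome_bins, "genome_bins")
    widths = genome_bins["end"] - genome_bins["start"]
    if widths.nunique() > 1:
        raise ValueError("genome bins must all have the same width")
    bins_pr = _to_pr(genome_bins, bin_index=np.arange(len(genome_bins)))

    def _hits(peaks: pd.DataFrame, name: str) -> np.ndarray:
        _validate_intervals(peaks, name)
        has = np.zeros(len(genome_bins), dtype=bool)
        if len(peaks):
            counted = bins_pr.count_overlaps(_to_pr(peaks)).as_df()
            counted = counted.sort_values("bin_index")
            has[counted["bin_index"].to_numpy()] = counted["NumberOverlaps"].to_numpy() > 0
        return has

    has_ino80 = _hits(ino80, "ino80")
    has_drip = _hits(drip, "drip")
    cls = np.where(
        has_ino80 & has_drip, "INO80+DRIP",
        np.where(has_drip, "DRIP", np.where(has_ino80, "INO80", "NoDRIP+NoINO80")),
    )
    out = genome_bins.copy()
    out["overlap_class"] = cls
    return out


def state_enrichment(
    states: pd.DataFrame, class_regions: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Fold enrichment of each region class across chromatin states.

    fold(class, state) = (bp of class in state / total class bp)
                         / (state bp / genome bp),
    where the genome is the full segmented extent.  Class regions are merged
    (and clipped to the segmentation) before counting, so the
    genome-fraction-weighted mean fold per class is exactly 1.  Empty classes
    are flagged with NaN folds.  Output: one row per state with a
    ``genome_fraction`` column and one ``fold_<class>`` column per class.
    """
    _validate_intervals(states, "states")
    if "state" not in states.columns:
        raise ValueError("segmentation requires a 'state' column")
    states_pr = _to_pr(states, state=states["state"])
    state_bp = states.assign(width=states["end"] - states["start"]) \
        .groupby("state")["width"].sum()
    genome_bp = int(state_bp.sum())

    result = pd.DataFrame(index=state_bp.index)
    result.index.name = "state"
    result["genome_fraction"] = state_bp / genome_bp

    for cls_name, regions in class_regions.items():
        col = f"fold_{cls_name}"
        _validate_intervals(regions, cls_name)
        if len(regions) == 0:
            logger.warning("class %s is empty; enrichment undefined", cls_name)
            result[col] = np.nan
            continue
        merged = _to_pr(regions).merge()
        clipped = states_pr.intersect(merged).as_df()
        if len(clipped) == 0:
            logger.warning("class %s has no overlap with the segmentation", cls_name)
            result[col] = np.nan
            continue
        clipped["width"] = clipped["End"] - clipped["Start"]
        in_state = clipped.groupby("state")["width"].sum().reindex(state_bp.index, fill_value=0)
        class_bp = int(in_state.sum())
        result[col] = (in_state / class_bp) / (state_bp / genome_bp)
    return result


def drip_qpcr_enrichment(
    ip_sample: float,
    input_sample: float,
    ip_control: float,
    input_control: float,
    background_threshold: float = 0.1,
) -> QpcrResult:
    """IP/input fold enrichment of a sample over the matched control.

    (ip_sample / input_sample) / (ip_control / input_control).  Input
    quantities must be positive; an IP signal far below the control ratio
    (below ``background_threshold``-fold) is flagged as background, the
    mock-IP situation.
    """
    if input_sample <= 0 or input_control <= 0:
        raise ValueError("input DNA quantities must be > 0")
    if ip_control <= 0:
        raise ValueError("control IP quantity must be > 0")
    if ip_sample < 0:
        raise ValueError("IP quantities must be >= 0")
    enrichment = (ip_sample / input_sample) / (ip_control / input_control)
    return QpcrResult(float(enrichment), background=enrichment < background_threshold)
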