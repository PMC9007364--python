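"""Assembly quality metrics, filtering rules, and contamination screening.

Single-cell amplified genome (SAG) assemblies are described by a small set of
quality metrics (contig count, total length, longest contig, GC fraction) and
filtered by two explicit rules: contigs are end-trimmed and length-filtered,
and whole assemblies below 20 kb total are excluded. Suspected two-cell
(doublet) assemblies are flagged by a tetranucleotide-frequency screen: 4-mer
frequency vectors of fixed-width windows are projected onto their first
principal components, and a 2-cluster dispersion ratio measures whether the
windows fall into two compositionally distinct groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "QCMetrics",
    "FiveNumberSummary",
    "preprocess_contigs",
    "low_complexity_filter",
    "compute_metrics",
    "tetramer_vectors",
    "contamination_screen",
    "summarize",
]

#: total assembled length below which an assembly is excluded
MIN_ASSEMBLY_LENGTH = 20_000
#: contig end trim and strict minimum retained length
DEFAULT_END_TRIM = 100
DEFAULT_MIN_CONTIG = 2_000
#: tetramer windowing
DEFAULT_WINDOW = 5_000
MIN_PARTIAL_WINDOW = 1_600
#: calibrated default for the 2-cluster dispersion-ratio score (see docs)
DEFAULT_SCORE_THRESHOLD = 3.0


@dataclass(frozen=True)
class QCMetrics:
    n_contigs: int
    total_length: int
    longest_contig: int
    gc_fraction: float
    pass_length_filter: bool
    contamination_flag: bool = False
    contamination_score: float = math.nan


@dataclass(frozen=True)
class FiveNumberSummary:
    """Tukey five-number summary: min, lower quartile, median, upper
    quartile, max."""

    min: float
    q25: float
    median: float
    q75: float
    max: float


def preprocess_contigs(
    contigs: Sequence[str],
    end_trim: int = DEFAULT_END_TRIM,
    min_len: int = DEFAULT_MIN_CONTIG,
) -> List[str]:
    """Trim ``end_trim`` bp off both ends; keep contigs strictly longer than
    ``min_len`` afterwards. Order is preserved."""
    if end_trim < 0 or min_len < 0:
        raise ValueError("end_trim and min_len must be >= 0")
    out = []
    for seq in contigs:
        if len(seq) <= 2 * end_trim:
            continue
        trimmed = seq[end_trim : len(seq) - end_trim] if end_trim else seq
        if len(trimmed) > min_len:
            out.append(trimmed)
    return out


def low_complexity_filter(
    seqs: Sequence[str], min_each_base_fraction: float = 0.05
) -> List[str]:
    """Keep sequences in which every one of A, C, G, T makes up at least
    ``min_each_base_fraction`` of the A/C/G/T positions."""
    out = []
    for seq in seqs:
        up = seq.upper()
        counts = [up.count(b) for b in "ACGT"]
        total = sum(counts)
        if total == 0:
            continue
        if min(counts) / total >= min_each_base_fraction:
            out.append(seq)
    return out


def compute_metrics(
    contigs: Sequence[str],
    min_assembly_length: int = MIN_ASSEMBLY_LENGTH,
) -> QCMetrics:
    """Contig count, total/longest length, GC fraction (N positions excluded
    from numerator and denominator), and the total-length pass flag."""
    if not contigs:
        raise ValueError("assembly has no contigs")
    lengths = [len(c) for c in contigs]
    gc = at = 0
    for c in contigs:
        up = c.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    denom = gc + at
    total = sum(lengths)
    return QCMetrics(
        n_contigs=len(contigs),
        total_length=total,
        longest_contig=max(lengths),
        gc_fraction=(gc / denom) if denom else math.nan,
        pass_length_filter=total >= min_assembly_length,
    )


_TETRA_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _windows(contigs: Sequence[str], window: int) -> List[str]:
    """Non-overlapping windows per contig; partial windows (including whole
    contigs shorter than one window) are kept only if >= MIN_PARTIAL_WINDOW
    bp. When nothing passes the floor at all — degenerate, very short input —
    every piece of >= 4 bp is kept so the composition is still measurable.
    """
    wins, short = [], []
    for c in contigs:
        for start in range(0, len(c), window):
            piece = c[start : start + window]
            if len(piece) == window or len(piece) >= min(
                MIN_PARTIAL_WINDOW, window
            ):
                wins.append(piece)
            elif len(piece) >= 4:
                short.append(piece)
    return wins if wins else short


def _tetramer_row(seq: str) -> Optional[np.ndarray]:
    up = seq.upper()
    codes = np.full(len(up), -1, dtype=np.int64)
    for base, code in _TETRA_INDEX.items():
        codes[np.frombuffer(up.encode(), dtype="S1") == base.encode()] = code
    if len(codes) < 4:
        return None
    # sliding 4-mer codes; any window containing a non-ACGT position is dropped
    k = (
        codes[:-3] * 64
        + codes[1:-2] * 16
        + codes[2:-1] * 4
        + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    k = k[valid]
    if k.size == 0:
        return None
    row = np.bincount(k, minlength=256).astype(float)
    return row / row.sum()


def tetramer_vectors(
    contigs: Sequence[str], window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """One 256-entry 4-mer frequency row per window (rows sum to 1).

    4-mers containing any non-A/C/G/T character are excluded from the counts;
    windows with no valid 4-mer are dropped.
    """
    if window < 4:
        raise ValueError("window must be >= 4 bp")
    rows = []
    for piece in _windows(contigs, window):
        row = _tetramer_row(piece)
        if row is not None:
            rows.append(row)
    if not rows:
        return np.empty((0, 256))
    return np.vstack(rows)


def contamination_screen(
    contigs: Sequence[str],
    window: int = DEFAULT_WINDOW,
    k_components: int = 2,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> Tuple[bool, float]:
    """Flag assemblies whose tetramer windows split into two distinct groups.

    Window 4-mer rows are projected onto the first ``k_components`` principal
    components; a 2-means partition of the scores gives a bimodality
    statistic: between-cluster sum of squares over within-cluster sum of
    squares. Pure assemblies give a low ratio (any forced split of one cloud),
    two-genome mixtures a high one. Returns (flag, score); with fewer than 3
    windows the screen is inconclusive (False, NaN).
    """
    x = tetramer_vectors(contigs, window=window)
    if x.shape[0] < 3:
        logger.warning("contamination screen inconclusive: <3 tetramer windows")
        return False, math.nan
    if not np.any(np.ptp(x, axis=0) > 0):
        # identical windows: nothing to separate
        return False, 0.0
    n_comp = min(k_components, x.shape[0] - 1, x.shape[1])
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(x)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(scores)
    labels = km.labels_
    if len(set(labels)) < 2:
        return False, 0.0
    grand = scores.mean(axis=0)
    within = 0.0
    between = 0.0
    for lab in (0, 1):
        grp = scores[labels == lab]
        centroid = grp.mean(axis=0)
        within += float(((grp - centroid) ** 2).sum())
        between += len(grp) * float(((centroid - grand) ** 2).sum())
    if within == 0.0:
        # identical windows collapse to one point: nothing to separate
        score = 0.0 if between == 0.0 else math.inf
    else:
        score = between / within
    return bool(score > score_threshold), float(score)


def summarize(values: Sequence[float]) -> FiveNumberSummary:
    """Tukey five-number summary with linear-interpolation quantiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
    return FiveNumberSummary(*[float(v) for v in q])


def evaluate_assembly(
    contigs: Sequence[str],
    min_assembly_length: int = MIN_ASSEMBLY_LENGTH,
    window: int = DEFAULT_WINDOW,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> QCMetrics:
    """Metrics plus contamination screen in one record."""
    base = compute_metrics(contigs, min_assembly_length=min_assembly_length)
    flag, score = contamination_screen(
        contigs, window=window, score_threshold=score_threshold
    )
    return QCMetrics(
        n_contigs=base.n_contigs,
        total_length=base.total_length,
        longest_contig=base.longest_contig,
        gc_fraction=base.gc_fraction,
        pass_length_filter=base.pass_length_filter,
        contamination_flag=flag,
        contamination_score=score,
    )
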