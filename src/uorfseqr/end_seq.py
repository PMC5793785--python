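"""TSS / polyadenylation-site calling from single-nucleotide read-end pileups.

TL-seq and pA-seq reduce transcript 5' and 3' ends to per-position
read-end counts. True sites appear as sparse, very high spikes over a
low, locally constant background. The background is estimated by
first-order Poisson trend filtering with outlier detection
(:mod:`uorfseqr._trend`); positions are then tested against the fitted
local rate with an upper-tail Poisson p-value and controlled with
Benjamini-Hochberg at FDR beta (default 0.001). Significant positions
are clustered in 25-nt windows and usage fractions computed per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._trend import poisson_trend_admm

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.001
DEFAULT_CLUSTER_WINDOW = 25
OUTLIER_P = 1e-6
MAX_OUTLIER_ROUNDS = 20


@dataclass
class EndPileup:
    """Read-end counts over a contiguous genomic window.

    ``counts[i]`` is the number of read ends at genomic position
    ``offset + i`` on ``strand``.
    """

    chrom: str
    strand: str
    counts: np.ndarray
    offset: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("read-end counts must be non-negative")


@dataclass
class PeakRecord:
    position: int
    count: int
    background_rate: float
    p_value: float
    q_value: float


@dataclass
class PeakSet:
    peaks: list[PeakRecord] = field(default_factory=list)
    lambda_used: float | None = None
    n_tested: int = 0

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks], dtype=int)


@dataclass
class SiteCluster:
    """A 25-nt-window cluster of significant end sites."""

    representative: int
    members: list[int]
    total_count: int
    usage_fraction: float


# ---------------------------------------------------------------------------
# Trend filtering
# ---------------------------------------------------------------------------

def fit_poisson_trend(counts, lambda_penalty, rho: float = 1.0,
                      max_iter: int = 5000, tol: float = 1e-7,
                      outlier_p: float = OUTLIER_P, warn: bool = True):
    """Fit a piecewise-constant-tending Poisson background with outliers.

    Returns ``(background_rate, outlier_flags)``. Positions whose count
    is implausible under the current fit (upper-tail Poisson p <
    ``outlier_p``) are flagged and excluded, and the fit repeated until
    the flag set stabilises (at most 20 rounds). Flagged positions still
    receive a background rate through the smoothness penalty.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 3:
        raise ValueError("counts must be a 1-D window of length >= 3")
    if lambda_penalty <= 0:
        raise ValueError("lambda_penalty must be positive")
    if counts.sum() == 0:
        return np.zeros_like(counts), np.zeros(counts.size, dtype=bool)

    flags = np.zeros(counts.size, dtype=bool)
    rate = np.zeros_like(counts)
    for _ in range(MAX_OUTLIER_ROUNDS):
        weights = (~flags).astype(float)
        rate, n_iter = poisson_trend_admm(
            counts, weights, float(lambda_penalty), rho, max_iter, tol
        )
        if n_iter >= max_iter and warn:
            logger.warning(
                "trend filter did not reach tol=%g in %d iterations; "
                "returning last iterate", tol, max_iter,
            )
        with np.errstate(divide="ignore"):
            pvals = stats.poisson.sf(counts - 1, rate)
        new_flags = (counts > 0) & (pvals < outlier_p)
        if np.array_equal(new_flags, flags):
            break
        flags = new_flags
    return rate, flags


def choose_lambda(counts, floor: float = 2.0, rho: float = 1.0):
    """Pick a penalty by halving from lambda_max until >= 2 fitted levels.

    lambda_max is taken proportional to the window's total excess mass
    (n * (mean + 1)), above which the fit is globally flat. Outlier
    flags accumulate down the ladder: a position flagged against the
    flat large-lambda background stays excluded at every smaller
    penalty, so true site spikes cannot carve out their own background
    level as the penalty relaxes. Returns (lambda, rate, flags); if no
    penalty above ``floor`` yields two distinct background levels, the
    fit at ``floor`` is used.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    lam = n * (counts.mean() + 1.0)
    flags = np.zeros(n, dtype=bool)
    rate = np.zeros(n)
    while True:
        for _ in range(MAX_OUTLIER_ROUNDS):
            weights = (~flags).astype(float)
            rate, _ = poisson_trend_admm(counts, weights, float(lam), rho, 1500, 1e-5)
            with np.errstate(divide="ignore"):
                pvals = stats.poisson.sf(counts - 1, rate)
            new_flags = flags | ((counts > 0) & (pvals < OUTLIER_P))
            if np.array_equal(new_flags, flags):
                break
            flags = new_flags
        levels = np.unique(np.round(np.log(rate[~flags] + 1e-12), 4)).size
        if levels >= 2 or lam / 2.0 < floor:
            break
        lam /= 2.0
    # full-tolerance polish at the accepted penalty
    rate, _ = poisson_trend_admm(counts, (~flags).astype(float), float(lam),
                                 rho, 5000, 1e-7)
    return lam, rate, flags


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def call_end_peaks(pileup: EndPileup, beta: float = DEFAULT_BETA,
                   lambda_penalty: float | None = None) -> PeakSet:
    """Call significant read-end peaks in one pileup window.

    Per-position p-value: upper-tail Poisson probability of the observed
    count under the fitted local background; Benjamini-Hochberg across
    the tested universe (positions with count >= 1); a peak has q <=
    beta. Zero-count positions are never tested.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    counts = np.asarray(pileup.counts, dtype=float)
    if counts.sum() == 0:
        return PeakSet(lambda_used=lambda_penalty, n_tested=0)
    if lambda_penalty is None:
        lam, rate, _ = choose_lambda(counts)
    else:
        lam = float(lambda_penalty)
        rate, _ = fit_poisson_trend(counts, lam)

    tested = np.flatnonzero(counts >= 1)
    with np.errstate(divide="ignore"):
        pvals = stats.poisson.sf(counts[tested] - 1, rate[tested])
    if tested.size == 0:
        return PeakSet(lambda_used=lam, n_tested=0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = PeakSet(lambda_used=lam, n_tested=int(tested.size))
    for idx, p, q in zip(tested, pvals, qvals):
        if q <= beta and beta > 0:
            out.peaks.append(
                PeakRecord(
                    position=pileup.offset + int(idx),
                    count=int(counts[idx]),
                    background_rate=float(rate[idx]),
                    p_value=float(p),
                    q_value=float(q),
                )
            )
    return out


def cluster_sites(peaks: PeakSet | list[PeakRecord], window_nt: int = DEFAULT_CLUSTER_WINDOW,
                  strand: str = "+") -> list[SiteCluster]:
    """Single-linkage clustering of significant sites in 25-nt windows.

    Consecutive peaks <= window_nt apart join one cluster. The cluster
    representative is the member with the highest count (ties: most
    upstream, strand-aware); usage_fraction is the cluster's share of
    the total count over the peaks supplied (i.e. within one gene).
    """
    records = peaks.peaks if isinstance(peaks, PeakSet) else list(peaks)
    if not records:
        return []
    records = sorted(records, key=lambda r: r.position)
    groups: list[list[PeakRecord]] = [[records[0]]]
    for rec in records[1:]:
        if rec.position - groups[-1][-1].position <= window_nt:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    total = sum(r.count for r in records)
    clusters = []
    for grp in groups:
        best_count = max(r.count for r in grp)
        candidates = [r.position for r in grp if r.count == best_count]
        rep = min(candidates) if strand == "+" else max(candidates)
        csum = sum(r.count for r in grp)
        clusters.append(
            SiteCluster(
                representative=rep,
                members=[r.position for r in grp],
                total_count=csum,
                usage_fraction=csum / total,
            )
        )
    return clusters


def end_search_windows(models, chrom_lengths: dict, flank: int = 1000) -> dict:
    """Genomic search windows for TSS and pA peaks per gene.

    TSS: up to ``flank`` nt strand-aware upstream of the annotated mORF
    start; pA: up to ``flank`` nt downstream of the stop. Windows are
    truncated at the CDS of neighbouring genes (and at chromosome ends)
    to keep site-to-gene assignment unambiguous. Returns
    gene_id -> {"tss": (start, end), "pa": (start, end)} half-open.
    """
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        lo = min(m.morf_start, m.morf_stop)
        hi = max(m.morf_start, m.morf_stop) + 1
        cds_by_chrom.setdefault(m.chrom, []).append((lo, hi))
    for spans in cds_by_chrom.values():
        spans.sort()

    def truncate(chrom, lo, hi, own_lo, own_hi):
        lo = max(lo, 0)
        hi = min(hi, chrom_lengths[chrom])
        for s, e in cds_by_chrom[chrom]:
            if (s, e) == (own_lo, own_hi):
                continue
            if e <= lo or s >= hi:
                continue
            if e <= own_lo:
                lo = max(lo, e)
            elif s >= own_hi:
                hi = min(hi, s)
        return lo, hi

    out = {}
    for m in models:
        own = (min(m.morf_start, m.morf_stop), max(m.morf_start, m.morf_stop) + 1)
        if m.strand == "+":
            tss = truncate(m.chrom, m.morf_start - flank, m.morf_start, *own)
            pa = truncate(m.chrom, m.morf_stop + 1, m.morf_stop + 1 + flank, *own)
        else:
            tss = truncate(m.chrom, m.morf_start + 1, m.morf_start + 1 + flank, *own)
            pa = truncate(m.chrom, m.morf_stop - flank, m.morf_stop, *own)
        out[m.gene_id] = {"tss": tss, "pa": pa}
    return out


# ---------------------------------------------------------------------------
# Leader-length summaries
# ---------------------------------------------------------------------------

def weighted_avg_tl_length(model) -> float:
    """TSS-usage-weighted mean transcript-leader length (wAVG) of a gene."""
    if not model.tl_isoforms:
        raise ValueError(f"{model.gene_id}: no TSS isoforms")
    return float(
        sum(frac * model.leader_length_of(tss) for tss, frac in model.tl_isoforms)
    )


def tl_length_cv(lengths) -> float:
    """Population coefficient of variation (sd/mean) of leader lengths.

    Requires values from >= 2 species; a zero mean returns NaN.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise ValueError("need leader lengths from at least two species")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std() / mean)


def conserved_length_flags(cvs, threshold: float = 0.06) -> np.ndarray:
    """Flag genes with the most conserved leader lengths (CV < threshold)."""
    arr = np.asarray(cvs, dtype=float)
    return (arr < threshold) & np.isfinite(arr)
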