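"""Descriptive comparative statistics downstream of uORF calling.

Covers: observed/expected triplet ratios of transcript leaders versus
3' UTRs (the depletion of AUG and enrichment of near-cognate triplets
upstream), TSS-usage-weighted transcript inclusion of uORFs, rank-sum
comparisons of translation efficiency between gene groups, and the
RNA-binding-protein metagene around translation initiation sites with a
sampled background.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TRIPLETS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


# ---------------------------------------------------------------------------
# Triplet observed/expected
# ---------------------------------------------------------------------------

def _triplet_frequencies(seqs) -> tuple[Counter, int]:
    counts: Counter = Counter()
    total = 0
    for seq in seqs:
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if "N" in tri:
                continue
            counts[tri] += 1
            total += 1
    return counts, total


def triplet_oe(tl_seqs, utr3_seqs) -> pd.DataFrame:
    """Observed/expected ratio of each 3-nt triplet, leaders vs 3' UTRs.

    Overlapping windows (stride 1); frequencies are window counts over
    total windows in each region set; OE = leader frequency / 3' UTR
    frequency. Triplets absent from the 3' UTRs have an undefined OE
    (NaN, ``defined`` False).
    """
    tl_counts, tl_total = _triplet_frequencies(tl_seqs)
    u3_counts, u3_total = _triplet_frequencies(utr3_seqs)
    rows = []
    for tri in TRIPLETS:
        tl_freq = tl_counts[tri] / tl_total if tl_total else float("nan")
        u3_freq = u3_counts[tri] / u3_total if u3_total else float("nan")
        defined = u3_total > 0 and u3_freq > 0
        rows.append(
            {
                "triplet": tri,
                "rna_triplet": tri.replace("T", "U"),
                "tl_freq": tl_freq,
                "utr3_freq": u3_freq,
                "oe": tl_freq / u3_freq if defined else float("nan"),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("triplet")


def triplet_oe_by_species(tl_by_species: dict, utr3_by_species: dict) -> pd.DataFrame:
    """Per-species OE plus the across-species average (column ``oe_mean``)."""
    per = {sp: triplet_oe(tl_by_species[sp], utr3_by_species[sp])["oe"] for sp in tl_by_species}
    df = pd.DataFrame(per)
    df["oe_mean"] = df.mean(axis=1, skipna=True)
    return df


# ---------------------------------------------------------------------------
# Transcript inclusion
# ---------------------------------------------------------------------------

@dataclass
class InclusionRecord:
    uorf_id: str
    inclusion_fraction: float
    minority: bool  # present in under half the gene's transcripts


def transcript_inclusion(uorf, model) -> InclusionRecord:
    """TSS-usage-weighted fraction of a gene's transcripts holding the uORF.

    A transcript isoform contains the uORF when its TSS lies at or
    upstream of the uORF start codon. uORF coordinates are distal-leader
    transcript coordinates, so an isoform with leader offset d contains
    the uORF iff d <= start_pos.
    """
    inclusion = 0.0
    for offset, frac in model.tss_offsets():
        if offset <= uorf.start_pos:
            inclusion += frac
    if inclusion == 0.0:
        logger.warning(
            "uORF %s upstream of every annotated TSS (enumerated on the distal leader)",
            uorf.uid,
        )
    inclusion = min(inclusion, 1.0)
    return InclusionRecord(uorf.uid, inclusion, inclusion < 0.5)


# ---------------------------------------------------------------------------
# Translation efficiency comparisons
# ---------------------------------------------------------------------------

def translation_efficiency(ribo_density: float, rna_density: float) -> float:
    """TE = ribosome-footprint density / RNA density over a region."""
    if rna_density <= 0:
        return float("nan")
    return ribo_density / rna_density


def te_group_compare(te_values_by_group: dict) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with BH adjustment.

    Returns one row per group pair with the statistic, raw p, and the
    Benjamini-Hochberg adjusted p across all pairs.
    """
    names = sorted(te_values_by_group)
    rows = []
    for a, b in itertools.combinations(names, 2):
        va = np.asarray(te_values_by_group[a], dtype=float)
        vb = np.asarray(te_values_by_group[b], dtype=float)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        stat, p = sps.ranksums(va, vb)
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# RBP metagene
# ---------------------------------------------------------------------------

@dataclass
class MetageneRecord:
    """One TIS with its surrounding transcript region and binding sites.

    All coordinates are transcript coordinates. ``region`` is the
    half-open span usable around this TIS (already truncated by any
    upstream exclusion); ``sites`` are half-open binding intervals on
    the same transcript.
    """

    tis: int
    region: tuple[int, int]
    sites: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class MetageneProfile:
    offsets: np.ndarray          # step offsets in nt (multiples of 3)
    observed: np.ndarray         # per-step summed site overlaps
    expected_mean: np.ndarray
    lo: np.ndarray               # pointwise 2.5% of the sampled null
    hi: np.ndarray               # pointwise 97.5%
    lo_band: np.ndarray          # simultaneous 95% envelope (rank method)
    hi_band: np.ndarray
    n_eligible: np.ndarray       # TISs long enough to enclose each step


def _profile(records, offsets) -> tuple[np.ndarray, np.ndarray]:
    obs = np.zeros(offsets.size)
    n_elig = np.zeros(offsets.size, dtype=int)
    for rec in records:
        r0, r1 = rec.region
        for k, off in enumerate(offsets):
            w0 = rec.tis + off
            w1 = w0 + 3
            if w0 < r0 or w1 > r1:
                continue  # transcript not long enough to enclose this step
            n_elig[k] += 1
            for s0, s1 in rec.sites:
                if s0 < w1 and w0 < s1:
                    obs[k] += 1
    return obs, n_elig


def rbp_metagene(records, half_window_nt: int = 30, n_samples: int = 1000,
                 seed=None) -> MetageneProfile:
    """Protein-occupancy metagene in 3-nt steps around TISs.

    ``observed[k]`` sums, over TISs whose transcript encloses step k,
    the number of binding sites overlapping the 3-nt window at offset
    3k - half_window. The expected background re-samples, ``n_samples``
    times, both the TIS position (uniform in its region) and each
    binding site (uniform placement of the same length in the same
    region), giving the mean, pointwise 95% limits, and a simultaneous
    95% envelope (per-profile rank method).
    """
    offsets = np.arange(-half_window_nt, half_window_nt + 1, 3)
    observed, n_eligible = _profile(records, offsets)

    rng = np.random.default_rng(seed)
    samples = np.empty((n_samples, offsets.size))
    for i in range(n_samples):
        resampled = []
        for rec in records:
            r0, r1 = rec.region
            tis = int(rng.integers(r0, r1))
            sites = []
            for s0, s1 in rec.sites:
                length = s1 - s0
                hi = max(r1 - length, r0 + 1)
                new0 = int(rng.integers(r0, hi))
                sites.append((new0, new0 + length))
            resampled.append(MetageneRecord(tis, rec.region, sites))
        samples[i], _ = _profile(resampled, offsets)

    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    # simultaneous envelope: widen per-step rank until 95% of sampled
    # profiles lie entirely inside
    lo_band, hi_band = lo.copy(), hi.copy()
    for alpha in np.linspace(2.5, 0.0, 26):
        lo_band = np.percentile(samples, alpha, axis=0)
        hi_band = np.percentile(samples, 100 - alpha, axis=0)
        inside = np.all((samples >= lo_band) & (samples <= hi_band), axis=1)
        if inside.mean() >= 0.95:
            break
    return MetageneProfile(offsets, observed, samples.mean(axis=0), lo, hi,
                           lo_band, hi_band, n_eligible)
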