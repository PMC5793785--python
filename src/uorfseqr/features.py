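"""The 18-feature vector scored for every candidate uORF.

Features capture ribosome P-site occupancy of the candidate (density,
start-codon peak, 3-nt periodicity, codon coverage, enrichment over the
leader background and the main ORF, boundary drop-offs), RNA abundance,
and the candidate's geometry within the transcript leader. The identity
of the start codon is deliberately NOT a feature, so that the model
cannot learn an AUG/NCC bias. Pooled (replicate-summed) tracks feed
features; individual replicate tracks feed only the per-replicate
detection labels the regression is trained against.

Conventions: log-scale features use log2(x + 1); density-ratio features
are per-nucleotide with a one-pseudo-event floor on an empty
denominator region; peak ratios use +0.5 pseudocounts on both sides.
Candidates with zero pooled P-sites get occupancy features of 0 and a
``has_coverage`` indicator of 0, with geometry features still defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FEATURE_NAMES: tuple[str, ...] = (
    "uorf_density_log",      # log2(P-sites per nt of the uORF + 1)
    "start_count_log",       # log2(P-sites on the start codon + 1)
    "inframe_fraction",      # frame-0 share of uORF P-sites
    "codon_coverage",        # fraction of uORF codons with >= 1 P-site
    "leader_enrichment_log", # log2(uORF density / leader background density + 1)
    "morf_ratio_log",        # log2(uORF density / mORF density + 1)
    "start_peak_ratio_log",  # log2((first-codon mean + .5)/(rest-of-uORF mean + .5))
    "upstream_count_log",    # log2(P-sites in 6 nt upstream of the start + 1)
    "downstream_count_log",  # log2(P-sites in 6 nt downstream of the stop + 1)
    "stop_dropoff_ratio_log",# log2((last-6-nt mean + .5)/(next-6-nt mean + .5))
    "rna_coverage_log",      # log2(mean RNA coverage over the uORF + 1)
    "ribo_rna_ratio_log",    # log2((uORF density + .5)/(RNA mean + .5))
    "length_codons",
    "tss_distance",          # distal TSS -> start codon, nt
    "morf_distance",         # stop codon -> mORF start, nt
    "relative_position",     # start position / (leader length - 1), in [0, 1]
    "leader_length_log",     # log2(leader length + 1)
    "has_coverage",          # 1 if any pooled P-site in the uORF
)

N_FEATURES = len(FEATURE_NAMES)

#: per-replicate detection thresholds (min_start_count, min_total, min_inframe_frac)
DEFAULT_DETECT_PARAMS = (1, 4, 0.5)


@dataclass(frozen=True)
class DetectionLabel:
    candidate_id: str
    replicate_id: str
    detected: bool


def _log2p1(x: float) -> float:
    return float(np.log2(x + 1.0))


def compute_features(candidate, pooled_psites, rna_cov, leader_len: int) -> np.ndarray:
    """Feature vector (length 18, order of :data:`FEATURE_NAMES`).

    ``pooled_psites`` and ``rna_cov`` are transcript-coordinate arrays
    covering leader + mORF; ``leader_len`` is the distal leader length.
    Deterministic given its inputs.
    """
    pooled = np.asarray(pooled_psites, dtype=float)
    rna = np.asarray(rna_cov, dtype=float)
    s, e = candidate.start_pos, candidate.stop_pos
    if s < 0 or e >= pooled.size:
        raise ValueError(f"candidate {candidate.uid} outside track bounds")
    nu = e - s + 1
    region = pooled[s : e + 1]
    total = float(region.sum())
    u_dens = total / nu

    inframe = float(region[0::3].sum() / total) if total > 0 else 0.0
    codon_cov = float((region.reshape(-1, 3).sum(axis=1) > 0).mean())

    # leader background: leader positions outside the candidate
    in_leader_end = min(e + 1, leader_len)
    bg_total = float(pooled[:leader_len].sum() - pooled[s:in_leader_end].sum())
    bg_len = leader_len - max(0, in_leader_end - s)
    if bg_len > 0:
        bg_dens = bg_total / bg_len if bg_total > 0 else 1.0 / bg_len
    else:
        bg_dens = 1.0
    morf = pooled[leader_len:]
    if morf.size > 0:
        m_dens = float(morf.mean()) if morf.sum() > 0 else 1.0 / morf.size
    else:
        m_dens = 1.0

    first_mean = float(pooled[s : s + 3].mean())
    rest = pooled[s + 3 : e + 1]
    rest_mean = float(rest.mean()) if rest.size else 0.0
    last_mean = float(pooled[max(s, e - 5) : e + 1].mean())
    after = pooled[e + 1 : e + 7]
    after_mean = float(after.mean()) if after.size else 0.0
    rna_mean = float(rna[s : e + 1].mean())

    return np.array(
        [
            _log2p1(u_dens),
            _log2p1(float(pooled[s : s + 3].sum())),
            inframe,
            codon_cov,
            _log2p1(u_dens / bg_dens),
            _log2p1(u_dens / m_dens),
            float(np.log2((first_mean + 0.5) / (rest_mean + 0.5))),
            _log2p1(float(pooled[max(0, s - 6) : s].sum())),
            _log2p1(float(pooled[e + 1 : e + 7].sum())),
            float(np.log2((last_mean + 0.5) / (after_mean + 0.5))),
            _log2p1(rna_mean),
            float(np.log2((u_dens + 0.5) / (rna_mean + 0.5))),
            nu / 3.0,
            float(s),
            float(leader_len - e - 1),
            s / max(leader_len - 1, 1),
            _log2p1(float(leader_len)),
            1.0 if total > 0 else 0.0,
        ]
    )


def feature_matrix(candidates, pooled_psites, rna_cov, leader_len: int) -> np.ndarray:
    """Stack :func:`compute_features` over candidates of one gene."""
    if not candidates:
        return np.empty((0, N_FEATURES))
    return np.vstack(
        [compute_features(c, pooled_psites, rna_cov, leader_len) for c in candidates]
    )


def detect_in_replicate(candidate, replicate_track,
                        params=DEFAULT_DETECT_PARAMS,
                        replicate_id: str = "",
                        require_start_peak: bool = True) -> DetectionLabel:
    """Heuristic per-replicate detection call used as the training label.

    Detected iff P-sites on the start codon >= min_start_count AND total
    uORF P-sites >= min_total AND in-frame fraction >= min_inframe_frac
    AND (by default) the start codon shows an initiation peak: its
    P-site count exceeds the codon-scaled count of the <= 3 nt
    immediately upstream. The peak requirement is what separates a
    genuine initiation site from an in-frame codon inside an already
    translated region, where elongating ribosomes produce the same
    density, periodicity, and totals; under the scanning model only a
    true start accumulates an initiation peak against a quiet upstream.
    """
    min_start, min_total, min_inframe = params
    counts = np.asarray(
        replicate_track.counts if hasattr(replicate_track, "counts") else replicate_track,
        dtype=float,
    )
    s, e = candidate.start_pos, candidate.stop_pos
    region = counts[s : e + 1]
    total = region.sum()
    start_count = counts[s : s + 3].sum()
    detected = (
        start_count >= min_start
        and total >= min_total
        and total > 0
        and region[0::3].sum() / total >= min_inframe
    )
    if detected and require_start_peak:
        upstream = counts[max(0, s - 3) : s]
        upstream_codon = upstream.sum() * 3.0 / upstream.size if upstream.size else 0.0
        detected = start_count > upstream_codon
    return DetectionLabel(candidate.uid, replicate_id, bool(detected))
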