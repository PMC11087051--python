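"""Structural candidate filters for receptor protein sets.

Class A neuropeptide GPCRs are seven-transmembrane proteins; candidate
lists are filtered on a predicted transmembrane-segment count (kept between
4 and 9 to tolerate truncated or over-predicted models) and reduced for
redundancy by greedy identity clustering.

``count_tm_segments`` is an explicit hydropathy *stand-in* for a dedicated
topology predictor: it counts disjoint hydrophobic stretches on a
Kyte-Doolittle sliding-window profile. Externally produced TM counts (TSV:
id<TAB>count) take precedence wherever both are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "TmAnnotation",
    "count_tm_segments",
    "filter_tm_range",
    "reduce_redundancy",
    "global_identity",
]


@dataclass(frozen=True)
class TmAnnotation:
    sequence_id: str
    tm_count: int
    source: str = "hydropathy"  # or "external"

    def __post_init__(self):
        if self.tm_count < 0:
            raise ValueError("tm_count must be >= 0")


def count_tm_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_sep: int = 3,
) -> int:
    """Count candidate transmembrane segments by sliding-window hydropathy.

    A residue position is membrane-like when the mean Kyte-Doolittle
    hydropathy of the length-``window`` window centred on it is >=
    ``threshold``; maximal membrane-like runs closer than ``min_sep``
    residues are merged and the merged runs counted.
    """
    if len(sequence) < window:
        warnings.warn(
            f"sequence shorter than window ({len(sequence)} < {window}); tm_count = 0",
            stacklevel=2,
        )
        return 0
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence])
    kernel = np.ones(window) / window
    profile = np.convolve(values, kernel, mode="valid")  # window means
    hot = profile >= threshold

    runs: list[list[int]] = []
    for i, h in enumerate(hot):
        if h and runs and i - runs[-1][1] <= min_sep:
            runs[-1][1] = i
        elif h:
            runs.append([i, i])
    return len(runs)


def filter_tm_range(
    annotations: list[TmAnnotation], min_tm: int = 4, max_tm: int = 9
) -> list[str]:
    """Keep sequence ids whose TM count lies in [min_tm, max_tm]."""
    return [a.sequence_id for a in annotations if min_tm <= a.tm_count <= max_tm]


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = 0
    al.open_gap_score = -1
    al.extend_gap_score = -0.5
    return al


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if not a or not b:
        return 0.0
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / aln.length


def reduce_redundancy(
    sequences: dict[str, str], identity_threshold: float = 0.95
) -> list[str]:
    """Greedy longest-first redundancy reduction.

    Sequences are visited longest first; each joins the first existing
    representative it matches at >= ``identity_threshold`` global identity,
    otherwise it founds a new cluster. Returns representative ids, so the
    retained set is pairwise below the threshold.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    for sid in order:
        if not any(
            global_identity(sequences[sid], sequences[r]) >= identity_threshold
            for r in reps
        ):
            reps.append(sid)
    return reps
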