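"""Prohormone cleavage-site grammar and mature-peptide extraction.

Proneuropeptide precursors are processed by prohormone convertases at basic
cleavage sites and matured by carboxypeptidases and amidating enzymes. The
grammar implemented here covers:

* dibasic sites: maximal runs of >= 2 basic residues (K/R in any
  combination), removed entirely as linker material;
* monobasic sites: a lone R at the cut with a second basic R three
  positions upstream (the Rxx-R pattern); the supporting R must not itself
  belong to a dibasic site;
* acidic two-residue flanks (EE/DD/ED/DE), by default only accepted when the
  downstream peptide starts with Q or carries a proline in position 2 or 3;
* peptide-initial cues: an N-terminal Q, or a proline at position 2 (xP) or
  3 (xxP), supported by an acidic residue 1-2 positions upstream, which
  produce alternative N-terminal cuts of the same inter-site segment.

Maturation converts a trailing glycine followed by a basic residue (the
GR/GK amide-donor motif) into a C-terminal amide (the G is removed) and an
N-terminal glutamine into pyroglutamate (glutamate optionally, off by
default).

Coordinates are 0-based and half-open everywhere; a ``MaturePeptide``'s
(start, end) slice of the precursor reproduces the *raw* segment, i.e. the
sequence before the amide glycine is stripped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CleavageRuleSet",
    "CutSite",
    "Precursor",
    "MaturePeptide",
    "scan_cleavage_sites",
    "extract_peptides",
    "apply_maturation",
    "filter_repetitive",
    "consensus_motif",
    "peptides_to_table",
]

_BASIC = frozenset("KR")
_ACIDIC = frozenset("DE")
_VALID = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class CleavageRuleSet:
    """The cleavage grammar with its configurable switches."""

    nterm_flank_motifs: frozenset = frozenset({"KR", "RR", "RK", "KK", "EE", "DD", "ED", "DE"})
    cterm_flank_motifs: frozenset = frozenset({"KK", "KR", "RR", "RK"})
    amide_donor_motifs: frozenset = frozenset({"GR", "GK"})
    #: accept EE/DD/ED/DE flanks as cuts even without a Q/xP/xxP peptide start
    acidic_alone: bool = False
    #: allow N-terminal E (not only Q) to cyclize to pyroglutamate
    pyro_glu_E: bool = False
    #: require acidic support (D/E at -1/-2) for internal Q/xP/xxP starts
    require_acidic_support: bool = True

    def __post_init__(self):
        for motifs in (self.nterm_flank_motifs, self.cterm_flank_motifs, self.amide_donor_motifs):
            if not motifs or any(set(m) - (_VALID - {"X"}) for m in motifs):
                raise ValueError("motif sets must be non-empty standard-residue strings")


DEFAULT_RULES = CleavageRuleSet()


@dataclass(frozen=True)
class CutSite:
    """One justified cleavage site.

    ``start``/``end`` delimit the flank residues consumed by the cut
    (half-open; zero-width for peptide-initial Q/xP/xxP cues). ``kind`` is
    the confidence tier: dibasic, monobasic, acidic, qstart or proline.
    """

    start: int
    end: int
    motif: str
    kind: str

    @property
    def position(self) -> int:
        return self.start


@dataclass
class Precursor:
    """A candidate precursor with its signal boundary and discovered cuts."""

    id: str
    sequence: str
    signal_end: int = 0
    cut_sites: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.id}: non-residue characters {sorted(bad)}")
        if not 0 <= self.signal_end < len(self.sequence):
            raise ValueError(f"{self.id}: signal_end {self.signal_end} out of range")


@dataclass
class MaturePeptide:
    """A predicted processed peptide on its precursor.

    ``sequence`` is the matured sequence (amide glycine stripped);
    ``precursor[start:end]`` is the raw segment it derives from.
    """

    precursor_id: str
    start: int
    end: int
    sequence: str
    pyro_glu: str = ""  # "", "Q" or "E"
    amidated: bool = False
    nterm_motif: str = ""
    cterm_motif: str = ""
    confidence: str = ""
    copy_index: int = 0


def _dibasic_runs(seq: str, lo: int) -> list[tuple[int, int]]:
    """Maximal runs of >= 2 basic residues at or after position lo."""
    return [
        (m.start(), m.end())
        for m in re.finditer("[KR]{2,}", seq)
        if m.start() >= lo
    ]


def scan_cleavage_sites(
    precursor: Precursor, rules: CleavageRuleSet = DEFAULT_RULES
) -> list[CutSite]:
    """Locate every justified cleavage site downstream of the signal peptide.

    Dibasic runs take precedence over everything they overlap (leftmost
    longest run wins, so e.g. KRR is one site). 'X' placeholders are
    tolerated in the sequence but never participate in a motif match.
    """
    seq = precursor.sequence
    lo = precursor.signal_end
    sites: list[CutSite] = []

    runs = _dibasic_runs(seq, lo)
    in_dibasic = set()
    for s, e in runs:
        in_dibasic.update(range(s, e))
        sites.append(CutSite(s, e, seq[s : s + 2], "dibasic"))

    # monobasic Rxx-R: lone R at the cut, supporting R three positions
    # upstream that is not itself part of a dibasic site
    for p in range(max(lo, 3), len(seq)):
        if seq[p] != "R" or p in in_dibasic:
            continue
        if p - 1 >= 0 and seq[p - 1] in _BASIC:
            continue  # part of a run (handled above)
        if p + 1 < len(seq) and seq[p + 1] in _BASIC:
            continue
        if seq[p - 3] == "R" and (p - 3) not in in_dibasic and p - 3 >= lo:
            sites.append(CutSite(p, p + 1, "Rxx-R", "monobasic"))

    # acidic two-residue flanks
    acidic_motifs = {m for m in rules.nterm_flank_motifs if set(m) <= _ACIDIC}
    p = lo
    while p < len(seq) - 1:
        pair = seq[p : p + 2]
        if pair in acidic_motifs and not ({p, p + 1} & in_dibasic):
            nxt = p + 2
            ok = rules.acidic_alone or _is_peptide_start(seq, nxt)
            if ok:
                sites.append(CutSite(p, p + 2, pair, "acidic"))
                p += 2
                continue
        p += 1

    consumed = in_dibasic | {
        i for s in sites if s.kind in ("monobasic", "acidic") for i in range(s.start, s.end)
    }

    # zero-width peptide-initial cues (alternative N-terminal cuts)
    for p in range(lo + 1, len(seq)):
        if p in consumed or (p - 1) in consumed:
            continue  # segment boundary already provides this cut
        supported = (
            not rules.require_acidic_support
            or (seq[p - 1] in _ACIDIC)
            or (p - 2 >= 0 and seq[p - 2] in _ACIDIC)
        )
        if not supported:
            continue
        if seq[p] == "Q":
            sites.append(CutSite(p, p, "Q-start", "qstart"))
        elif p + 1 < len(seq) and seq[p + 1] == "P" and (p + 1) not in consumed:
            sites.append(CutSite(p, p, "xP-start", "proline"))
        elif p + 2 < len(seq) and seq[p + 2] == "P" and (p + 2) not in consumed:
            sites.append(CutSite(p, p, "xxP-start", "proline"))

    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def _is_peptide_start(seq: str, p: int) -> bool:
    if p >= len(seq):
        return False
    if seq[p] == "Q":
        return True
    if p + 1 < len(seq) and seq[p + 1] == "P":
        return True
    if p + 2 < len(seq) and seq[p + 2] == "P":
        return True
    return False


def apply_maturation(
    raw_segment: str,
    flanks: tuple[str, str],
    rules: CleavageRuleSet = DEFAULT_RULES,
) -> tuple[str, str, bool]:
    """Apply amidation and pyroglutamation to a raw inter-cut segment.

    ``flanks`` is (nterm_motif_label, cterm_flank_residues): the C-terminal
    flank string is the residue context immediately downstream of the
    segment. Returns (matured_sequence, pyro_glu, amidated).
    """
    if not raw_segment:
        raise ValueError("empty segment")
    seq = raw_segment
    amidated = False
    if (
        seq.endswith("G")
        and len(seq) > 1
        and flanks[1][:1] in ("R", "K")
        and ("G" + flanks[1][0]) in rules.amide_donor_motifs
    ):
        seq = seq[:-1]
        amidated = True
    pyro = ""
    if seq.startswith("Q"):
        pyro = "Q"
    elif rules.pyro_glu_E and seq.startswith("E"):
        pyro = "E"
    return seq, pyro, amidated


_CONFIDENCE = {
    "dibasic": "dibasic",
    "monobasic": "monobasic",
    "acidic": "acidic/Q",
    "qstart": "acidic/Q",
    "proline": "proline",
}


def extract_peptides(
    precursor: Precursor,
    rules: CleavageRuleSet = DEFAULT_RULES,
    min_len: int = 3,
    max_len: int = 50,
) -> list[MaturePeptide]:
    """Slice a precursor into candidate mature peptides.

    Segments between consecutive consuming cut sites (dibasic/monobasic/
    acidic) are the primary candidates; zero-width Q/xP/xxP cuts inside a
    segment add alternative, shorter N-terminal versions of the same
    peptide (as observed for stepwise processing). The length filter
    applies to the matured sequence.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = precursor.sequence
    sites = scan_cleavage_sites(precursor, rules)
    precursor.cut_sites = sites
    consuming = [s for s in sites if s.end > s.start]
    zero_width = [s for s in sites if s.end == s.start]

    # segment boundaries: (start, end, nterm_site, cterm_site)
    bounds = []
    prev_end, prev_site = precursor.signal_end, None
    for s in consuming:
        if s.start > prev_end:
            bounds.append((prev_end, s.start, prev_site, s))
        prev_end, prev_site = s.end, s
    if prev_end < len(seq):
        bounds.append((prev_end, len(seq), prev_site, None))

    peptides: list[MaturePeptide] = []
    copy_index = 0
    for seg_start, seg_end, nsite, csite in bounds:
        starts = [(seg_start, nsite.motif if nsite else "", nsite.kind if nsite else "")]
        for z in zero_width:
            if seg_start < z.start < seg_end:
                starts.append((z.start, z.motif, z.kind))
        cflank = seq[seg_end : seg_end + 2]
        cterm_motif = csite.motif if csite else ""
        for st, nmotif, nkind in sorted(set(starts)):
            raw = seq[st:seg_end]
            matured, pyro, amidated = apply_maturation(raw, (nmotif, cflank), rules)
            if not (min_len <= len(matured) <= max_len):
                continue
            peptides.append(
                MaturePeptide(
                    precursor_id=precursor.id,
                    start=st,
                    end=seg_end,
                    sequence=matured,
                    pyro_glu=pyro,
                    amidated=amidated,
                    nterm_motif=nmotif,
                    cterm_motif=cterm_motif,
                    confidence=_CONFIDENCE.get(nkind, "signal-edge"),
                    copy_index=copy_index,
                )
            )
            copy_index += 1
    return peptides


def filter_repetitive(
    precursors: list[Precursor],
    min_sites: int = 2,
    rules: CleavageRuleSet = DEFAULT_RULES,
) -> list[Precursor]:
    """Keep precursors with at least ``min_sites`` cleavage sites after the
    signal boundary — the repetitive-site filter used to enrich true
    multi-copy propeptides."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    kept = []
    for p in precursors:
        if len(scan_cleavage_sites(p, rules)) >= min_sites:
            kept.append(p)
    return kept


def consensus_motif(peptides: list[MaturePeptide], k: int = 4) -> str:
    """Shared C-terminal motif of the peptide copies of one precursor.

    Returns the longest common suffix of the matured sequences truncated to
    ``k`` residues, with an ``amide`` suffix when every copy is amidated
    (e.g. {GPRG*, APRG*} -> 'PRGamide').
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    seqs = [p.sequence for p in peptides]
    suffix = seqs[0]
    for s in seqs[1:]:
        while suffix and not s.endswith(suffix):
            suffix = suffix[1:]
    suffix = suffix[-k:]
    if suffix and all(p.amidated for p in peptides):
        suffix += "amide"
    return suffix


def peptides_to_table(peptides: list[MaturePeptide]) -> pd.DataFrame:
    cols = [
        "precursor_id", "start", "end", "sequence", "pyro_glu", "amidated",
        "nterm_motif", "cterm_motif", "confidence", "copy_index",
    ]
    return pd.DataFrame(
        [{c: getattr(p, c) for c in cols} for p in peptides], columns=cols
    )
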