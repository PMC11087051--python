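"""Modification-aware peptide masses, b/y ion ladders, and peak matching.

Neutral monoisotopic masses are the exchange currency throughout: upstream
deconvolution (charge-state collapse) is assumed to have happened already,
so peak lists carry neutral masses in Da. Matching uses a relative (ppm)
tolerance on the intact mass and an absolute (Da) tolerance on fragments,
mirroring common peptidomics search settings (5 ppm precursor / 0.02 Da
fragment).

Identifications are triaged into ``confident`` / ``uncertain`` / ``poor``
based on how completely the merged b/y ion ladders resolve consecutive
residue junctions: small gaps (<= 2) are confident, a gap of exactly 3 (or a
signal-peptide overlap, a disulfide, or an intermediate-processing suspicion)
is uncertain, and anything with a gap > 3 or flagged low-intensity evidence
is poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "RESIDUE_MASS",
    "WATER",
    "PROTON",
    "ModificationDeltas",
    "Modifications",
    "MatchResult",
    "monoisotopic_mass",
    "ppm_error",
    "fragment_ladder",
    "ladder_statistics",
    "match_peptides",
    "categorize_identification",
]

#: Monoisotopic residue (amino-acid minus water) masses for the 20 standard
#: residues, taken from pyteomics.
RESIDUE_MASS: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

WATER: float = 18.0105646837
PROTON: float = 1.00727646688


@dataclass(frozen=True)
class ModificationDeltas:
    """Monoisotopic mass deltas of the supported post-translational edits (Da).

    Values are kept at full precision; rounded to two decimals they equal the
    conventionally quoted -17.03, -18.01, -0.98, -1.01 and +15.99 Da.
    """

    pyro_glu_Q: float = -17.0265491015
    pyro_glu_E: float = -18.0105646837
    amidation: float = -0.9840155848
    half_cystine: float = -1.00782503207
    met_oxidation: float = +15.9949146221


DELTAS = ModificationDeltas()


@dataclass(frozen=True)
class Modifications:
    """Set of modifications applied to one peptide.

    pyro_glu is ``""`` (none), ``"Q"`` or ``"E"``; ``half_cystines`` counts
    cysteines engaged in disulfide bridges (each contributes half a bridge);
    ``met_oxidations`` counts oxidized methionines.
    """

    pyro_glu: str = ""
    amidated: bool = False
    half_cystines: int = 0
    met_oxidations: int = 0

    def delta(self) -> float:
        d = 0.0
        if self.pyro_glu == "Q":
            d += DELTAS.pyro_glu_Q
        elif self.pyro_glu == "E":
            d += DELTAS.pyro_glu_E
        elif self.pyro_glu:
            raise ValueError(f"pyro_glu must be '', 'Q' or 'E', got {self.pyro_glu!r}")
        if self.amidated:
            d += DELTAS.amidation
        d += self.half_cystines * DELTAS.half_cystine
        d += self.met_oxidations * DELTAS.met_oxidation
        return d


def _residue_masses(sequence: str) -> np.ndarray:
    try:
        return np.array([RESIDUE_MASS[aa] for aa in sequence])
    except KeyError:
        for i, aa in enumerate(sequence):
            if aa not in RESIDUE_MASS:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i} in {sequence!r}"
                ) from None
        raise  # pragma: no cover


def monoisotopic_mass(sequence: str, mods: Modifications | None = None) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide in Da."""
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    mods = mods or Modifications()
    return float(_residue_masses(sequence).sum()) + WATER + mods.delta()


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, (obs - theo) / theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def fragment_ladder(
    sequence: str, mods: Modifications | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Singly protonated b- and y-ion ladders of a peptide.

    b_i covers residues 1..i (N-terminal series, carries the pyroGlu delta),
    y_i covers the last i residues (C-terminal series, carries the amidation
    delta). Each series has n-1 entries. Internal modifications
    (disulfides, Met oxidation) shift only the intact mass, not the ladders.
    """
    if len(sequence) < 2:
        raise ValueError("fragment ladders require at least 2 residues")
    mods = mods or Modifications()
    res = _residue_masses(sequence)
    nterm_delta = DELTAS.pyro_glu_Q if mods.pyro_glu == "Q" else (
        DELTAS.pyro_glu_E if mods.pyro_glu == "E" else 0.0
    )
    cterm_delta = DELTAS.amidation if mods.amidated else 0.0
    b = np.cumsum(res[:-1]) + PROTON + nterm_delta
    y = np.cumsum(res[::-1][:-1]) + WATER + PROTON + cterm_delta
    return b, y


def ladder_statistics(
    sequence: str,
    observed_fragments: Sequence[float],
    mods: Modifications | None = None,
    frag_tol_da: float = 0.02,
) -> tuple[int, int, float]:
    """Score fragment evidence against the merged b/y ladder of a peptide.

    A residue junction j (1..n-1) counts as resolved when either b_j or
    y_(n-j) is observed within ``frag_tol_da``. Returns
    (matched_fragments, max_gap, coverage) where max_gap is the longest run
    of consecutive unresolved junctions and coverage the resolved fraction.
    """
    b, y = fragment_ladder(sequence, mods)
    obs = np.asarray(observed_fragments, dtype=float)
    n = len(sequence)

    def _hit(m: float) -> bool:
        return bool(obs.size) and bool(np.min(np.abs(obs - m)) <= frag_tol_da)

    matched = sum(_hit(m) for m in b) + sum(_hit(m) for m in y)
    resolved = [_hit(b[j - 1]) or _hit(y[n - j - 1]) for j in range(1, n)]
    max_gap = gap = 0
    for r in resolved:
        gap = 0 if r else gap + 1
        max_gap = max(max_gap, gap)
    coverage = sum(resolved) / len(resolved)
    return matched, max_gap, coverage


@dataclass
class MatchResult:
    """A peptide-to-peak assignment with its confidence evidence."""

    peptide_id: str
    peak_id: str
    theoretical_mass: float
    observed_mass: float
    ppm_error: float
    matched_fragments: int | None = None
    max_gap: int | None = None
    coverage: float | None = None
    overlaps_signal: bool = False
    has_disulfide: bool = False
    looks_intermediate: bool = False
    low_intensity: bool = False
    category: str | None = None


def categorize_identification(match: MatchResult) -> str:
    """Assign the confident/uncertain/poor triage category to a match.

    Requires ladder statistics (max_gap) to be present. The boundary is
    sharp: max_gap <= 2 with no caveats is confident, max_gap == 3 or any
    caveat flag (signal overlap, disulfide, intermediate processing) is
    uncertain, and max_gap > 3 or low-intensity evidence is poor.
    """
    if match.max_gap is None:
        raise ValueError("match has no ladder statistics; cannot categorize")
    if match.max_gap > 3 or match.low_intensity:
        return "poor"
    if (
        match.max_gap == 3
        or match.overlaps_signal
        or match.has_disulfide
        or match.looks_intermediate
    ):
        return "uncertain"
    return "confident"


def match_peptides(
    peptides: pd.DataFrame,
    peaklist: pd.DataFrame,
    tol_ppm: float = 5.0,
    frag_tol_da: float = 0.02,
) -> tuple[list[MatchResult], list[str], list[str]]:
    """Match predicted peptides to an observed neutral-mass peak list.

    Parameters
    ----------
    peptides
        Table with columns ``peptide_id``, ``sequence`` and optionally
        ``pyro_glu`` ('', 'Q' or 'E') and ``amidated`` (bool).
    peaklist
        Table with columns ``peak_id``, ``mass_da`` and optionally
        ``low_intensity`` (bool) and ``fragments`` (sequence of observed
        fragment masses used for ladder scoring).
    tol_ppm
        Intact-mass tolerance; every (peptide, peak) pair within it is
        reported, so one peptide may match several peaks and vice versa.

    Returns
    -------
    (matches, unmatched_peptide_ids, unmatched_peak_ids)
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if peaklist.empty:
        warnings.warn("empty peak list: no matches possible", stacklevel=2)
        return [], list(peptides.get("peptide_id", pd.Series(dtype=str))), []

    matches: list[MatchResult] = []
    matched_peps: set[str] = set()
    matched_peaks: set[str] = set()
    has_frag = "fragments" in peaklist.columns
    for prow in peptides.itertuples(index=False):
        mods = Modifications(
            pyro_glu=str(getattr(prow, "pyro_glu", "") or ""),
            amidated=bool(getattr(prow, "amidated", False)),
        )
        theo = monoisotopic_mass(prow.sequence, mods)
        for krow in peaklist.itertuples(index=False):
            err = ppm_error(float(krow.mass_da), theo)
            if abs(err) > tol_ppm:
                continue
            m = MatchResult(
                peptide_id=str(prow.peptide_id),
                peak_id=str(krow.peak_id),
                theoretical_mass=theo,
                observed_mass=float(krow.mass_da),
                ppm_error=err,
                low_intensity=bool(getattr(krow, "low_intensity", False)),
            )
            frags = getattr(krow, "fragments", None) if has_frag else None
            if frags is not None and not (
                isinstance(frags, float) and np.isnan(frags)
            ):
                m.matched_fragments, m.max_gap, m.coverage = ladder_statistics(
                    prow.sequence, frags, mods, frag_tol_da
                )
                m.category = categorize_identification(m)
            matches.append(m)
            matched_peps.add(m.peptide_id)
            matched_peaks.add(m.peak_id)

    unmatched_peps = [
        str(p) for p in peptides["peptide_id"] if str(p) not in matched_peps
    ]
    unmatched_peaks = [
        str(p) for p in peaklist["peak_id"] if str(p) not in matched_peaks
    ]
    return matches, unmatched_peps, unmatched_peaks


def matches_to_table(matches: Iterable[MatchResult]) -> pd.DataFrame:
    """Flatten MatchResult objects into a report table."""
    cols = [
        "peptide_id", "peak_id", "theoretical_mass", "observed_mass",
        "ppm_error", "matched_fragments", "max_gap", "coverage", "category",
    ]
    rows = [{c: getattr(m, c) for c in cols} for m in matches]
    return pd.DataFrame(rows, columns=cols)
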