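"""Cleavage grammar, maturation, repetitive-site filter, consensus motifs."""

import numpy as np
import pytest

import peptidergic as pg
from peptidergic.mining import (
    CleavageRuleSet,
    MaturePeptide,
    Precursor,
    apply_maturation,
    consensus_motif,
    extract_peptides,
    filter_repetitive,
    peptides_to_table,
    scan_cleavage_sites,
)

RULES = CleavageRuleSet()


def brute_force_sites(seq: str, lo: int, rules: CleavageRuleSet = RULES):
    """Position-by-position re-derivation of the grammar, independent of the
    scanner's run/region machinery. Returns {(start, end, kind)}."""
    basic = set("KR")
    acidic = set("DE")
    sites = set()
    dib_positions = set()
    # dibasic: any maximal stretch of >=2 basics
    i = 0
    while i < len(seq):
        if seq[i] in basic:
            j = i
            while j < len(seq) and seq[j] in basic:
                j += 1
            if j - i >= 2 and i >= lo:
                sites.add((i, j, "dibasic"))
                dib_positions.update(range(i, j))
            i = j
        else:
            i += 1
    # monobasic: lone R with a free supporting R three positions upstream
    for p in range(len(seq)):
        if seq[p] != "R" or p in dib_positions or p < max(lo, 3):
            continue
        if p - 1 >= 0 and seq[p - 1] in basic:
            continue
        if p + 1 < len(seq) and seq[p + 1] in basic:
            continue
        if seq[p - 3] == "R" and p - 3 not in dib_positions and p - 3 >= lo:
            sites.add((p, p + 1, "monobasic"))
    # acidic pairs, left-greedy, conditional on a Q/xP/xxP peptide start
    p = lo
    while p < len(seq) - 1:
        if (
            seq[p] in acidic
            and seq[p + 1] in acidic
            and p not in dib_positions
            and p + 1 not in dib_positions
        ):
            nxt = p + 2
            starts = nxt < len(seq) and (
                seq[nxt] == "Q"
                or (nxt + 1 < len(seq) and seq[nxt + 1] == "P")
                or (nxt + 2 < len(seq) and seq[nxt + 2] == "P")
            )
            if rules.acidic_alone or starts:
                sites.add((p, p + 2, "acidic"))
                p += 2
                continue
        p += 1
    consumed = dib_positions | {
        k for s, e, kind in sites if kind in ("monobasic", "acidic") for k in range(s, e)
    }
    # zero-width Q / xP / xxP cues with acidic support
    for p in range(lo + 1, len(seq)):
        if p in consumed or (p - 1) in consumed:
            continue
        if not (seq[p - 1] in acidic or (p - 2 >= 0 and seq[p - 2] in acidic)):
            continue
        if seq[p] == "Q":
            sites.add((p, p, "qstart"))
        elif p + 1 < len(seq) and seq[p + 1] == "P" and p + 1 not in consumed:
            sites.add((p, p, "proline"))
        elif p + 2 < len(seq) and seq[p + 2] == "P" and p + 2 not in consumed:
            sites.add((p, p, "proline"))
    return sites


def test_dibasic_cut_with_q_start():
    p = Precursor("t", "MAAAKRQGRFGKRAAA", signal_end=1)
    sites = scan_cleavage_sites(p)
    dib = [s for s in sites if s.kind == "dibasic"]
    assert dib[0].start == 4 and dib[0].end == 6 and dib[0].motif == "KR"
    peps = extract_peptides(p, min_len=3)
    starts = {x.sequence: x for x in peps}
    # peptide after the KR cut starts at Q, matures to pyroQGRF-amide
    assert "QGRF" in starts
    assert starts["QGRF"].pyro_glu == "Q" and starts["QGRF"].amidated


def test_no_motif_means_no_sites():
    p = Precursor("t", "MAAALLLVVVIIIFFFAAA", signal_end=1)
    assert scan_cleavage_sites(p) == []


def test_monobasic_rxx_r_cut():
    #        0123456789
    seq = "MAARAARWLTNF"
    p = Precursor("t", seq, signal_end=1)
    sites = scan_cleavage_sites(p)
    mono = [s for s in sites if s.kind == "monobasic"]
    assert len(mono) == 1 and mono[0].start == 6 and mono[0].motif == "Rxx-R"


def test_invalid_characters_rejected():
    with pytest.raises(ValueError):
        Precursor("t", "MAAB*AA", signal_end=1)


def test_x_never_matches_inside_motif():
    p = Precursor("t", "MAAAKXQGRF", signal_end=1)
    assert all(s.kind != "dibasic" for s in scan_cleavage_sites(p))


@pytest.mark.parametrize(
    "raw,cflank,expected",
    [
        ("GPRGG", "KR", ("GPRG", "", True)),   # trailing G + basic flank -> amide
        ("AILA", "KR", ("AILA", "", False)),   # no trailing G
        ("QITRFG", "RR", ("QITRF", "Q", True)),  # pyroQ + amide
        ("QGRFG", "RE", ("QGRF", "Q", True)),    # monobasic R as amide donor
    ],
)
def test_apply_maturation(raw, cflank, expected):
    assert apply_maturation(raw, ("KR", cflank)) == expected


def test_pyro_glu_E_is_opt_in():
    assert apply_maturation("EILA", ("KR", "KR"))[1] == ""
    rules = CleavageRuleSet(pyro_glu_E=True)
    assert apply_maturation("EILA", ("KR", "KR"), rules)[1] == "E"


def test_extract_on_toy_prg_precursor():
    # signal + KR GPRGG KR GPRGG KR
    seq = "MLLAVALLF" + "KR" + "GPRGG" + "KR" + "GPRGG" + "KR" + "AATN"
    p = Precursor("prg", seq, signal_end=9)
    peps = extract_peptides(p, min_len=3)
    prg = [x for x in peps if x.sequence == "GPRG"]
    assert len(prg) == 2
    assert all(x.amidated for x in prg)
    assert all(seq[x.start : x.end] == "GPRGG" for x in prg)


def test_signal_only_precursor_yields_nothing():
    p = Precursor("sig", "MLLAVALLFVVI", signal_end=11)
    assert extract_peptides(p) == []


def test_coordinates_round_trip(mined, precursor_set):
    records, _ = precursor_set
    seqs = dict(records)
    _, predictions = mined
    for p in predictions:
        raw = seqs[p.precursor_id][p.start : p.end]
        expected = p.sequence + ("G" if p.amidated else "")
        assert raw == expected


def test_scanner_agrees_with_brute_force_on_random_sequences():
    rng = np.random.default_rng(42)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(300):
        n = int(rng.integers(5, 200))
        seq = "M" + "".join(rng.choice(alphabet, size=n))
        lo = int(rng.integers(1, max(2, n // 4)))
        p = Precursor("r", seq, signal_end=lo)
        got = {(s.start, s.end, s.kind) for s in scan_cleavage_sites(p)}
        assert got == brute_force_sites(seq, lo), seq


def test_filter_repetitive_matches_recount(precursor_set):
    records, truth = precursor_set
    sig = dict(zip(truth.precursor_id, truth.signal_end))
    precs = [Precursor(r, s, signal_end=sig[r]) for r, s in records]
    for min_sites in (1, 2, 5):
        kept = {p.id for p in filter_repetitive(precs, min_sites=min_sites)}
        expected = {
            p.id
            for p in precs
            if len(brute_force_sites(p.sequence, p.signal_end)) >= min_sites
        }
        assert kept == expected
    assert filter_repetitive(precs, min_sites=1_000) == []


def test_filter_repetitive_rejects_bad_min_sites():
    with pytest.raises(ValueError):
        filter_repetitive([], min_sites=0)


def _mk(seq, amidated):
    return MaturePeptide("p", 0, len(seq), seq, amidated=amidated)


def test_consensus_motif():
    assert consensus_motif([_mk("GPRG", True), _mk("APRG", True)]) == "PRGamide"
    assert consensus_motif([_mk("QGRF", False)]) == "QGRF"
    assert consensus_motif([_mk("AAAA", False), _mk("TTTT", False)]) == ""


def test_peptides_table_shape(mined):
    _, predictions = mined
    tab = peptides_to_table(predictions)
    assert len(tab) == len(predictions)
    assert {"precursor_id", "start", "end", "sequence", "amidated", "confidence"} <= set(tab.columns)
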