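import numpy as np
import pandas as pd
import pytest

import peptidergic as pg
from peptidergic.mining import Precursor, extract_peptides


@pytest.fixture(scope="session")
def precursor_set():
    """A medium synthetic precursor set with its ground truth."""
    spec = pg.PrecursorSpec(n_precursors=60, seed=0)
    records, truth = pg.gen_precursors(spec)
    return records, truth


@pytest.fixture(scope="session")
def mined(precursor_set):
    """Peptides mined from the fixture precursors, keyed by coordinates."""
    records, truth = precursor_set
    sig = dict(zip(truth.precursor_id, truth.signal_end))
    out = {}
    predictions = []
    for rid, seq in records:
        for p in extract_peptides(Precursor(rid, seq, signal_end=sig[rid])):
            out[(rid, p.start, p.end)] = p
            predictions.append(p)
    return out, predictions


def mine_all(records, truth):
    sig = dict(zip(truth.precursor_id, truth.signal_end))
    found = {}
    preds = []
    for rid, seq in records:
        for p in extract_peptides(Precursor(rid, seq, signal_end=sig[rid])):
            found[(rid, p.start, p.end)] = p
            preds.append(p)
    return found, preds
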