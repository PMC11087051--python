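"""LL.4 curve, fitting, normalization and the screening cascade."""

import numpy as np
import pandas as pd
import pytest

import peptidergic as pg
from peptidergic.doseresponse import fit_4pl, four_pl, normalize_plate, screen_mixes, summarize_pairs


def four_pl_reference(x, b, c, d, e):
    """Independent re-coding of the LL.4 formula (scalar, math module)."""
    import math

    return c + (d - c) / (1.0 + math.exp(b * (math.log(x) - math.log(e))))


def test_midpoint_identity():
    assert four_pl(1e-8, b=-1.3, c=0.2, d=0.8, e=1e-8) == pytest.approx(0.5)


def test_steep_slope_steps_between_asymptotes():
    # large |b|, negative: increasing curve
    assert four_pl(1e-10, b=-40, c=0.0, d=1.0, e=1e-8) == pytest.approx(0.0, abs=1e-6)
    assert four_pl(1e-6, b=-40, c=0.0, d=1.0, e=1e-8) == pytest.approx(1.0, abs=1e-6)


def test_formula_matches_independent_recoding():
    rng = np.random.default_rng(3)
    for _ in range(50):
        x = 10 ** rng.uniform(-13, -4)
        b = rng.uniform(-3, 3) or 0.7
        c, d = rng.uniform(0, 0.3), rng.uniform(0.7, 1.5)
        e = 10 ** rng.uniform(-11, -6)
        assert four_pl(x, b, c, d, e) == pytest.approx(
            four_pl_reference(x, b, c, d, e), abs=1e-12
        )


def test_nonpositive_inputs_rejected():
    with pytest.raises(ValueError):
        four_pl(0.0, -1, 0, 1, 1e-8)
    with pytest.raises(ValueError):
        four_pl(1e-8, -1, 0, 1, 0.0)


def test_noise_free_fit_recovers_parameters_exactly():
    for b, c, d, e in [(1.75, 0.0, 1.0, 8.9e-9), (0.42, 0.1, 0.9, 2.3e-7)]:
        plate = pg.gen_dose_response(
            pg.PlateSpec(true_ec50=e, true_slope=b, lower=c, upper=d, noise_sd=0.0)
        )
        f = fit_4pl(plate)
        assert f.converged
        assert f.ec50 == pytest.approx(e, rel=1e-6)
        assert f.hill_slope == pytest.approx(b, rel=1e-6)
        assert f.lower == pytest.approx(c, abs=1e-6)
        assert f.upper == pytest.approx(d, abs=1e-6)


def test_fit_requires_four_distinct_concentrations():
    plate = pd.DataFrame(
        {"concentration_M": [1e-9, 1e-8, 1e-7] * 3, "response": np.arange(9.0)}
    )
    with pytest.raises(ValueError, match="4 distinct"):
        fit_4pl(plate)


def test_flat_plate_flags_nonconvergence():
    rng = np.random.default_rng(0)
    plate = pd.DataFrame(
        {
            "concentration_M": np.tile(np.logspace(-12, -5, 8), 3),
            "response": rng.normal(0.5, 0.01, 24),
        }
    )
    assert not fit_4pl(plate).converged


def test_fixed_params_are_honored_and_nested_sse():
    plate = pg.gen_dose_response(
        pg.PlateSpec(true_ec50=1e-8, true_slope=1.2, noise_sd=0.05, seed=4)
    )
    fixed = fit_4pl(plate, fixed_params={"c": 0.0})
    free = fit_4pl(plate)
    assert fixed.fixed_params == ("c",)
    assert fixed.lower == 0.0
    # releasing a pinned parameter can only improve the fit
    assert free.residual_sse <= fixed.residual_sse + 1e-9


def test_ec50_invariant_to_linear_rescaling():
    plate = pg.gen_dose_response(
        pg.PlateSpec(true_ec50=3e-9, true_slope=1.0, noise_sd=0.05, seed=8)
    )
    scaled = plate.copy()
    scaled["response"] = plate["response"] * 1500.0 + 40.0
    f1, f2 = fit_4pl(plate), fit_4pl(scaled)
    assert f2.ec50 == pytest.approx(f1.ec50, rel=1e-4)
    assert f2.hill_slope == pytest.approx(f1.hill_slope, rel=1e-4)


def test_normalize_minmax_idempotent_and_errors():
    plate = pg.gen_dose_response(pg.PlateSpec(noise_sd=0.05, seed=1))
    once = normalize_plate(plate, "minmax")
    twice = normalize_plate(once, "minmax")
    assert once.response.min() == 0.0 and once.response.max() == 1.0
    pd.testing.assert_series_equal(once.response, twice.response)
    flat = plate.copy()
    flat["response"] = 1.0
    with pytest.raises(ValueError, match="dynamic range"):
        normalize_plate(flat, "minmax")
    with pytest.raises(ValueError):
        normalize_plate(plate, "quantile")


def test_baseline_adjustment_recovers_shifted_ec50():
    """A constitutively active receptor adds a response floor. Under the
    assay convention that the lower asymptote is zero, fitting the raw data
    biases the EC50; subtracting the constitutive floor first recovers it."""
    true_e = 2.1e-9
    base = pg.gen_dose_response(
        pg.PlateSpec(true_ec50=true_e, true_slope=1.5, lower=0.0, upper=1.0,
                     noise_sd=0.02, seed=6)
    )
    shifted = base.copy()
    shifted["response"] = 0.6 + 0.4 * shifted["response"]  # strong base activation
    naive = fit_4pl(shifted, fixed_params={"c": 0.0})
    adjusted_data = shifted.copy()
    adjusted_data["response"] = np.clip(shifted["response"] - 0.6, 0.0, None)
    adjusted = fit_4pl(adjusted_data, fixed_params={"c": 0.0})
    err_naive = abs(np.log10(naive.ec50) - np.log10(true_e))
    err_adj = abs(np.log10(adjusted.ec50) - np.log10(true_e))
    assert err_adj < err_naive
    assert adjusted.ec50 == pytest.approx(true_e, rel=0.5)


def _mix_plate(seed=0, agonist=True, wells_per_mix=3, n_controls=60):
    rng = np.random.default_rng(seed)
    rows = []
    for mix in ("mix1", "mix2"):
        for _ in range(wells_per_mix):
            resp = rng.normal(100, 5)
            if agonist and mix == "mix1":
                resp += 400
            rows.append(dict(receptor="R1", mix=mix, response=resp))
    controls = pd.DataFrame(
        dict(receptor="R1", response=rng.normal(100, 5, n_controls))
    )
    return pd.DataFrame(rows), controls


def test_screen_mixes_finds_planted_agonist():
    plate, controls = _mix_plate()
    hits = screen_mixes(plate, controls, k=3)
    assert hits.set_index("mix").hit.to_dict() == {"mix1": True, "mix2": False}


def test_screen_all_buffer_rarely_hits_at_k3():
    """With 6 test wells and a well-estimated control distribution, the
    familywise null hit probability at k=3 is ~0.8%, so >= 99% of seeded
    all-buffer plates give zero hits."""
    false_pos = 0
    for seed in range(100):
        plate, controls = _mix_plate(seed=seed, agonist=False)
        hits = screen_mixes(plate, controls, k=3)
        false_pos += int(hits.hit.any())
    assert false_pos <= 1


def test_screen_missing_controls_is_error():
    plate, _ = _mix_plate()
    with pytest.raises(ValueError, match="control"):
        screen_mixes(plate, pd.DataFrame(columns=["receptor", "response"]))
    with pytest.raises(ValueError, match="R1"):
        screen_mixes(plate, pd.DataFrame(dict(receptor=["R9"], response=[100.0])))


def test_summarize_pairs_lowest_ec50_and_counts():
    pairs = pd.DataFrame(
        {
            "receptor": ["R1", "R1", "R2", "R3"],
            "peptide": ["a", "b", "a", "a"],
            "ec50": [1e-8, 1e-6, 5e-9, 2e-7],
        }
    )
    out = summarize_pairs(pairs)
    pr = out["per_receptor"].set_index("receptor")
    assert pr.loc["R1", "lowest_ec50"] == 1e-8
    assert pr.loc["R1", "best_ligand"] == "a"
    pp = out["per_peptide"].set_index("peptide")
    assert pp.loc["a", "n_receptors"] == 3 and pp.loc["b", "n_receptors"] == 1
    empty = summarize_pairs([])
    assert empty["pairs"].empty
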