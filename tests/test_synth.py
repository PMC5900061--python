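import numpy as np
import pytest

from hrvlandscape import synth
from hrvlandscape.entropy import entropy_profile
from hrvlandscape.fragmentation import pattern_profile
from hrvlandscape.hrv import time_domain
from hrvlandscape.io import RRSeries
from hrvlandscape.symbolize import symbolize, lgram_distribution


def test_seeds_are_mandatory():
    chain = synth.iid_chain([0.25, 0.5, 0.25], [-8.0, 0.0, 8.0])
    with pytest.raises(ValueError, match="seed"):
        synth.simulate_markov_rr(chain, 100)
    with pytest.raises(ValueError, match="seed"):
        synth.simulate_modulated_rr({}, 100)
    with pytest.raises(ValueError, match="seed"):
        synth.simulate_cohort(synth.default_cohort_design())


def test_determinism_bit_identical():
    chain = synth.antipersistent_chain()
    a = synth.simulate_markov_rr(chain, 5000, seed=3)
    b = synth.simulate_markov_rr(chain, 5000, seed=3)
    assert np.array_equal(a.rr, b.rr)
    c = synth.simulate_modulated_rr({"hf_amp": 20, "noise_sd": 2}, 1000, seed=4)
    d = synth.simulate_modulated_rr({"hf_amp": 20, "noise_sd": 2}, 1000, seed=4)
    assert np.array_equal(c.rr, d.rr)


def test_deterministic_zero_chain_constant():
    chain = synth.iid_chain([0.0, 1.0, 0.0], [-8.0, 0.0, 8.0])
    s = synth.simulate_markov_rr(chain, 500, mean_rr=800.0, seed=1)
    assert np.all(s.rr == 800.0)


def test_iid_chain_marginal_recovery():
    probs = np.array([0.25, 0.5, 0.25])
    chain = synth.iid_chain(probs, [-8.0, 0.0, 8.0])
    s = synth.simulate_markov_rr(chain, 20_000, mean_rr=1150.0, seed=2)
    d = lgram_distribution(symbolize(s, 8.0), 1, "full")
    for label, p_true in zip([-8, 0, 8], probs):
        se = np.sqrt(p_true * (1 - p_true) / d.n_windows)
        assert abs(d[label] - p_true) <= 3 * se


def test_drifting_chain_rejected():
    # strong positive drift runs into the physiologic bounds
    chain = synth.iid_chain([0.05, 0.05, 0.9], [-8.0, 0.0, 8.0])
    with pytest.raises(ValueError, match="balanced"):
        synth.simulate_markov_rr(chain, 20_000, seed=0)


def test_modulated_degenerate_constant():
    s = synth.simulate_modulated_rr({"mean_rr": 800.0}, 2000, seed=1)
    assert np.all(s.rr == 800.0)
    p = entropy_profile(symbolize(s, 8.0))
    assert p.H1 == p.H2 == p.H3 == 0.0


def test_modulated_rejects_nonpositive_rr():
    with pytest.raises(ValueError):
        synth.simulate_modulated_rr({"mean_rr": 10.0, "hf_amp": 50.0},
                                    500, seed=1)


def test_noise_only_alternation_heavy():
    # differenced white noise alternates in sign with asymptotic prob 2/3
    s = synth.simulate_modulated_rr({"noise_sd": 30.0}, 20_000, seed=6)
    p = pattern_profile(symbolize(s, 8.0))
    assert p.PIP > 0.5


def test_inject_erratic_identity_at_zero_rate():
    s = RRSeries(rr=np.full(5000, 800.0))
    out = synth.inject_erratic(s, 0.0, 8, 40.0, seed=1)
    assert np.array_equal(out.rr, s.rr)


def test_inject_erratic_monotone_in_rate():
    base = RRSeries(rr=np.full(30_000, 800.0))
    pips = []
    for rate in (2.0, 10.0, 40.0):
        out = synth.inject_erratic(base, rate, 10, 40.0, seed=7)
        pips.append(pattern_profile(symbolize(out, 8.0)).PIP)
    assert pips[0] < pips[1] < pips[2]


def test_inject_erratic_rmssd_accounting():
    base = RRSeries(rr=np.full(40_000, 800.0))
    out = synth.inject_erratic(base, 30.0, 10, 40.0, seed=8)
    frac = np.mean(out.rr != 800.0) * 2  # each offset beat yields 2 increments
    expected = 40.0 * np.sqrt(frac)
    assert time_domain(out).RMSSD == pytest.approx(expected, rel=0.15)


def test_level_noise_h1_mapping_is_inverse():
    for target in (0.8, 1.5, 2.5):
        sigma = synth.level_sigma_for_h1(target)
        assert synth.h1_of_level_sigma(sigma) == pytest.approx(target, abs=1e-5)


def test_level_noise_unreachable_target_names_bound():
    with pytest.raises(ValueError, match="bound"):
        synth.level_sigma_for_h1(50.0)


def test_cohort_design_recovery():
    from hrvlandscape import cohort as cs
    import pandas as pd
    design = synth.default_cohort_design()
    design.n_beats = 10_000
    signals, manifest = synth.simulate_cohort(design, seed=21)
    assert len(signals) == len(manifest) == 58
    rows = [{"subject_id": s.subject_id, "months_post_htx": s.months_post_htx,
             "group": s.group, "H1": entropy_profile(symbolize(s, 8.0)).H1}
            for s in signals]
    t = pd.DataFrame(rows)
    r_nf = cs.regress_time(t, "H1", "NF")
    assert abs(r_nf.slope - 0.15) <= 2.5 * r_nf.stderr


def test_cohort_empty_design():
    signals, manifest = synth.simulate_cohort(synth.CohortDesign(arms=[]),
                                              seed=1)
    assert signals == [] and len(manifest) == 0


def test_cohort_round_trips_through_files(tmp_path):
    from hrvlandscape.io import read_rr, read_manifest
    design = synth.CohortDesign(arms=[synth.ArmDesign(
        group="F", visits={"F1": [12, 24]}, intercept=1.4, slope_per_year=0.0)],
        n_beats=500)
    signals, manifest = synth.simulate_cohort(design, seed=2,
                                              out_dir=str(tmp_path))
    m = read_manifest(tmp_path / "manifest.csv")
    assert len(m) == 2
    s = read_rr(m.entries[0].path)
    assert np.array_equal(s.rr, signals[0].rr)
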