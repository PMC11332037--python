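import itertools

import numpy as np
import pytest

from dyadsynch import crqa
from dyadsynch.synthetic_data import (
    GeneratorConfig,
    _draw_participant,
    generate_trial_sequence,
    inject_missingness,
    simulate_chain_session,
    simulate_dyad_block,
    valid_trial_sequences,
)

from _oracles import sequence_rules_hold
from conftest import fast_generator_config


# ---------------------------------------------------------------------------
# trial sequences


def test_valid_sequence_set_matches_exhaustive_enumeration():
    oracle = set()
    for tx_pos in itertools.combinations(range(12), 6):
        seq = tuple("Tx" if i in tx_pos else "NT" for i in range(12))
        if sequence_rules_hold(seq):
            oracle.add(seq)
    assert set(valid_trial_sequences()) == oracle
    assert len(oracle) > 0


def test_generated_sequences_and_their_inversions_satisfy_rules(rng):
    for _ in range(50):
        seq = generate_trial_sequence(rng)
        assert sequence_rules_hold(seq)
        inverted = ["Tx" if c == "NT" else "NT" for c in seq]
        assert sequence_rules_hold(inverted)


def test_sequence_sampling_is_uniform_over_valid_set(rng):
    pool = valid_trial_sequences()
    counts = {s: 0 for s in pool}
    n = 200 * len(pool)
    for _ in range(n):
        counts[tuple(generate_trial_sequence(rng))] += 1
    freqs = np.array(list(counts.values())) / n
    # chi-square against the uniform distribution
    expected = n / len(pool)
    chi2 = float(((np.array(list(counts.values())) - expected) ** 2 / expected).sum())
    # mean chi2 = k-1; reject only if wildly off
    assert chi2 < 2.0 * len(pool)
    assert freqs.min() > 0


# ---------------------------------------------------------------------------
# determinism and structural invariants


def test_identical_seeds_give_bit_identical_sessions(fast_cfg):
    a = simulate_chain_session(fast_cfg, 7)
    b = simulate_chain_session(fast_cfg, 7)
    for blk_a, blk_b in zip(a.blocks, b.blocks):
        assert blk_a.trials == blk_b.trials
        for role in blk_a.eda:
            np.testing.assert_array_equal(
                blk_a.eda[role].samples, blk_b.eda[role].samples
            )
    assert a.ground_truth == b.ground_truth


def test_chain_temperature_schedule(fast_cfg):
    session = simulate_chain_session(fast_cfg, 3)
    for t in session.block(1).trials:
        assert t.temperature == (54.0 if t.cue == "Tx" else 45.0)
    for idx in (2, 3):
        assert all(t.temperature == 45.0 for t in session.block(idx).trials)


def test_full_coupling_without_noise_gives_affinely_identical_eda(rng):
    cfg = fast_generator_config(
        measurement_noise_sd=0.0,
        scr_amplitude_by_temperature={45.0: 0.0, 54.0: 0.0},
        anticipatory_scr_gain=0.0,
        vicarious_scr_gain=0.0,
    )
    dem = _draw_participant("d", "G1", cfg, rng)
    obs = _draw_participant("o", "G2", cfg, rng)
    blk = simulate_dyad_block(
        cfg, dem, obs, block_index=1,
        temperatures_by_cue={"Tx": 54.0, "NT": 45.0}, kappa=1.0, rng=rng,
    )
    x = blk.eda["demonstrator"].samples
    y = blk.eda["observer"].samples
    assert abs(np.corrcoef(x, y)[0, 1] - 1.0) < 1e-12


def test_non_responders_show_no_cue_effect():
    cfg = GeneratorConfig(
        generate_eda=False,
        generate_fau=False,
        synchrony_nocebo_slope=0.0,
        responder_mix={"responder": 0, "non_responder": 1, "reverse_responder": 0},
    )
    rng = np.random.default_rng(11)
    diffs = []
    for _ in range(150):
        s = simulate_chain_session(cfg, rng)
        for idx in (2, 3):
            blk = s.block(idx)
            tx = [t.pain_rating for t in blk.trials if t.cue == "Tx"]
            nt = [t.pain_rating for t in blk.trials if t.cue == "NT"]
            diffs.append(np.mean(tx) - np.mean(nt))
    # zero effect by construction, up to rating-noise Monte-Carlo error
    assert abs(np.mean(diffs)) < 3.0 * np.std(diffs) / np.sqrt(len(diffs)) + 0.1


def test_responder_mean_difference_matches_configured_effect():
    cfg = GeneratorConfig(
        generate_eda=False,
        generate_fau=False,
        synchrony_nocebo_slope=0.0,
        responder_mix={"responder": 1, "non_responder": 0, "reverse_responder": 0},
    )
    rng = np.random.default_rng(21)
    diffs = []
    for _ in range(500):
        s = simulate_chain_session(cfg, rng)
        for idx in (2, 3):
            blk = s.block(idx)
            tx = [t.pain_rating for t in blk.trials if t.cue == "Tx"]
            nt = [t.pain_rating for t in blk.trials if t.cue == "NT"]
            diffs.append(np.mean(tx) - np.mean(nt))
    se = np.std(diffs) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs) - cfg.nocebo_effect_size) < 4 * se + 0.05


def test_reverse_responders_show_negative_cue_effect():
    cfg = GeneratorConfig(
        generate_eda=False,
        generate_fau=False,
        synchrony_nocebo_slope=0.0,
        responder_mix={"responder": 0, "non_responder": 0, "reverse_responder": 1},
    )
    rng = np.random.default_rng(31)
    diffs = []
    for _ in range(200):
        s = simulate_chain_session(cfg, rng)
        blk = s.block(2)
        tx = [t.pain_rating for t in blk.trials if t.cue == "Tx"]
        nt = [t.pain_rating for t in blk.trials if t.cue == "NT"]
        diffs.append(np.mean(tx) - np.mean(nt))
    assert np.mean(diffs) < -5.0


# ---------------------------------------------------------------------------
# missingness


def test_missingness_rate_zero_and_one(fast_cfg):
    session = simulate_chain_session(fast_cfg, 9)
    same = inject_missingness(session, 0.0, 1)
    for b1, b2 in zip(session.blocks, same.blocks):
        assert b1.trials == b2.trials
    gone = inject_missingness(session, 1.0, 1)
    for blk in gone.blocks:
        assert all(t.demonstrator_expectancy is None for t in blk.trials)
        assert all(t.observer_expectancy is None for t in blk.trials)


def test_missingness_fraction_matches_binomial_oracle():
    cfg = GeneratorConfig(generate_eda=False, generate_fau=False)
    rng = np.random.default_rng(5)
    total = missing = 0
    for _ in range(150):
        s = simulate_chain_session(cfg, rng)
        s = inject_missingness(s, 0.082, rng)
        for blk in s.blocks:
            for t in blk.trials:
                for v in (t.demonstrator_expectancy, t.observer_expectancy):
                    total += 1
                    missing += v is None
    rate = missing / total
    tol = 4 * np.sqrt(0.082 * (1 - 0.082) / total)
    assert abs(rate - 0.082) < tol


def test_invalid_rates_and_mixes_rejected():
    with pytest.raises(ValueError):
        inject_missingness(None, 1.5, 0)
    with pytest.raises(ValueError):
        GeneratorConfig(responder_mix={"responder": 0.7, "non_responder": 0.7,
                                       "reverse_responder": 0.0}).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(kappa=1.2).validate()


# ---------------------------------------------------------------------------
# coupling is expressed in downstream cross-recurrence determinism


def _mean_det(kappa: float, n_dyads: int, seed: int) -> float:
    cfg = GeneratorConfig(sampling_rate=100.0, generate_fau=False)
    rng = np.random.default_rng(seed)
    dets = []
    for _ in range(n_dyads):
        dem = _draw_participant("d", "G1", cfg, rng)
        obs = _draw_participant("o", "G2", cfg, rng)
        blk = simulate_dyad_block(
            cfg, dem, obs, block_index=1,
            temperatures_by_cue={"Tx": 54.0, "NT": 45.0}, kappa=kappa, rng=rng,
        )
        _, result = crqa.dyad_synchrony(blk.eda["demonstrator"], blk.eda["observer"])
        dets.append(result.det)
    return float(np.mean(dets))


def test_mean_determinism_increases_with_dyadic_coupling():
    """Stronger arousal coupling must raise mean DET across dyads.

    The effect is small in absolute terms because 0.05-1 Hz content sampled
    at 8 Hz saturates diagonal-line structure, so the comparison uses 50
    dyads per coupling level.
    """
    low = _mean_det(0.15, 50, seed=101)
    high = _mean_det(0.85, 50, seed=202)
    assert high > low
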