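"""Simulation-based validation studies of the pipeline.

Each function runs a self-contained Monte-Carlo study against the synthetic
generator and returns summary numbers: recurrence-rate targeting of the CRQA
parameter fit, null calibration of the permutation responder classifier,
recovery of a coupling-linked nocebo effect by the synchrony regression, and
confidence-interval coverage of the mixed ANCOVA's adjusted cue difference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from dyadsynch.crqa import optimize_parameters, prepare_series
from dyadsynch.stats_models import fit_hierarchical_regression, fit_mixed_ancova
from dyadsynch.synchrony_responders import classify_responder
from dyadsynch.synthetic_data import GeneratorConfig, simulate_chain_session

__all__ = [
    "mean_achieved_recurrence_rate",
    "classifier_null_calibration",
    "synchrony_effect_recovery",
    "ancova_cue_coverage",
]


def _rng_stream(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), label]))


def mean_achieved_recurrence_rate(
    n_dyads: int = 50,
    seed: int = 1,
    config: GeneratorConfig | None = None,
) -> dict:
    """Mean cross-recurrence rate achieved by the parameter optimizer.

    Simulates chain sessions with the default generator, prepares each
    analysed dyad's EDA pair (0.05-1 Hz band, 8 Hz, z-score) and runs the
    radius/delay/dimension fit targeting a 2-4% recurrence band.
    """
    config = config or GeneratorConfig(generate_fau=False)
    rng = _rng_stream(seed, 31)
    rates = []
    n_sessions = (n_dyads + 1) // 2
    for i in range(n_sessions):
        session = simulate_chain_session(config, rng, session_id=f"V{i:03d}")
        for blk_index in (1, 2):
            if len(rates) >= n_dyads:
                break
            blk = session.block(blk_index)
            x = prepare_series(blk.eda["demonstrator"])
            y = prepare_series(blk.eda["observer"])
            params = optimize_parameters(x, y)
            rates.append(params.achieved_rr)
    rates = np.asarray(rates[:n_dyads])
    return {"mean_rr": float(rates.mean()), "rates": rates, "n": int(rates.size)}


def classifier_null_calibration(
    n_subjects: int = 2000,
    n_perm: int = 10_000,
    seed: int = 7,
    exact: bool = False,
) -> dict:
    """Type-I behaviour of the responder classifier on exchangeable ratings.

    Every subject's 12 pain ratings are i.i.d. draws from one distribution,
    so no subject truly responds; the classifier should call ~5% responders
    at the 0.05 one-sided level.
    """
    rng = _rng_stream(seed, 47)
    labels = np.array(["Tx"] * 6 + ["NT"] * 6)
    p_upper = np.empty(n_subjects)
    classes = []
    for i in range(n_subjects):
        ratings = rng.normal(50.0, 15.0, size=12)
        res = classify_responder(ratings, labels, n_perm=n_perm, seed=rng, exact=exact)
        p_upper[i] = res.p_upper
        classes.append(res.responder_class)
    classes = np.asarray(classes)
    return {
        "pct_not_responder": float(100.0 * (classes != "responder").mean()),
        "type1": {a: float((p_upper <= a).mean()) for a in (0.01, 0.05, 0.1)},
        "n": n_subjects,
    }


def _ratings_only(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    base = config or GeneratorConfig()
    return dataclasses.replace(base, generate_eda=False, generate_fau=False, **overrides)


def synchrony_effect_recovery(
    n_replicates: int = 200,
    n_dyads: int = 60,
    seed: int = 1,
) -> dict:
    """Sign recovery of a coupling-linked nocebo effect.

    The generator ties each subject's nocebo shift to the arousal coupling of
    the dyad they observed in; regressing the classifier statistic (mean
    Tx-NT pain when demonstrating) on that coupling must recover a positive
    coefficient.
    """
    config = _ratings_only(
        responder_mix={"responder": 1.0, "non_responder": 0.0, "reverse_responder": 0.0},
    )
    rng = _rng_stream(seed, 59)
    n_sessions = (n_dyads + 1) // 2
    positive = 0
    for _ in range(n_replicates):
        rows = []
        for i in range(n_sessions):
            session = simulate_chain_session(config, rng, session_id=f"R{i:03d}")
            gt = session.ground_truth
            for blk_index, gen in ((2, "G2"), (3, "G3")):
                blk = session.block(blk_index)
                tx = [t.pain_rating for t in blk.trials if t.cue == "Tx"]
                nt = [t.pain_rating for t in blk.trials if t.cue == "NT"]
                rows.append({
                    "nocebo": float(np.mean(tx) - np.mean(nt)),
                    "kappa": gt["kappa"][blk_index - 1],
                })
        df = pd.DataFrame(rows[: n_dyads])
        df["synchrony"] = (df["kappa"] - df["kappa"].mean()) / df["kappa"].std(ddof=1)
        (stage,) = fit_hierarchical_regression(df, "nocebo", [["synchrony"]])
        positive += stage.table.loc["synchrony", "B"] > 0
    return {"fraction_positive": positive / n_replicates, "n": n_replicates}


def ancova_cue_coverage(
    n_replicates: int = 500,
    n_subjects: int = 66,
    effect: float = 7.0,
    seed: int = 1,
) -> dict:
    """95% CI coverage for an injected cue effect in the mixed ANCOVA.

    Every demonstrator is a responder with a fixed ``effect``-point Tx-NT
    shift and no coupling dependence; the ANCOVA's adjusted cue-difference
    interval should cover the injected value at its nominal rate.
    """
    config = _ratings_only(
        nocebo_effect_size=effect,
        synchrony_nocebo_slope=0.0,
        responder_mix={"responder": 1.0, "non_responder": 0.0, "reverse_responder": 0.0},
    )
    rng = _rng_stream(seed, 83)
    n_sessions = (n_subjects + 1) // 2
    covered = 0
    for _ in range(n_replicates):
        rows = []
        for i in range(n_sessions):
            session = simulate_chain_session(config, rng, session_id=f"C{i:03d}")
            for blk_index, gen in ((2, "G2"), (3, "G3")):
                blk = session.block(blk_index)
                per_cue = {"Tx": 0, "NT": 0}
                for t in blk.trials:
                    per_cue[t.cue] += 1
                    rows.append({
                        "subject": blk.demonstrator, "generation": gen,
                        "gender_match": 0.5 if blk.gender_match else -0.5,
                        "cue": t.cue, "trial": per_cue[t.cue],
                        "value": t.pain_rating,
                    })
        out = fit_mixed_ancova(pd.DataFrame(rows))
        lo, hi = out.adjusted_difference.ci
        covered += lo <= effect <= hi
    return {"coverage": covered / n_replicates, "n": n_replicates}
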