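"""End-to-end orchestration: simulate → score → synchrony → responders → analyze.

Each stage reads the previous stage's table from the results directory and
writes its own, so deleting a downstream table and re-running regenerates it
identically from upstream outputs. All randomness flows from one root seed
through per-session derived streams; a fully specified configuration hashes
to a stable run identifier recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dyadsynch import crqa as crqa_mod
from dyadsynch.io_formats import Session, load_session, write_session
from dyadsynch.phasic_scoring import average_trial_pairs, score_session
from dyadsynch.stats_models import (
    fit_hierarchical_regression,
    fit_mixed_ancova,
    simple_slopes,
)
from dyadsynch.synchrony_responders import (
    classify_responder,
    responder_proportions_test,
    session_psychological_synchrony,
)
from dyadsynch.synthetic_data import (
    GeneratorConfig,
    inject_missingness,
    simulate_chain_session,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    simulate: bool = True
    n_sessions: int = 10
    data_dir: str | None = None  # used when simulate is False
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    n_perm: int = 10_000
    exact_permutations: bool = False
    responder_alpha: float = 0.05
    target_rr_range: tuple = (0.02, 0.04)
    crqa_max_delay: int = 40
    crqa_max_dim: int = 10
    synchrony_metric: str = "psych"  # metric driving the reported simple slopes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "target_rr_range" in raw:
            raw["target_rr_range"] = tuple(raw["target_rr_range"])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(**self.generator)

    def run_id(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> list[Path]:
    gen = config.generator_config()
    out = Path(config.out_dir) / "sessions"
    streams = np.random.SeedSequence(config.seed).spawn(config.n_sessions)
    paths = []
    for i, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        session = simulate_chain_session(gen, rng, session_id=f"S{i:03d}")
        if gen.missing_expectancy_rate > 0:
            session = inject_missingness(session, gen, rng)
        write_session(session, out / f"S{i:03d}")
        paths.append(out / f"S{i:03d}")
    return paths


def _session_dirs(config: PipelineConfig) -> list[Path]:
    base = (
        Path(config.out_dir) / "sessions"
        if config.simulate
        else Path(config.data_dir)
    )
    dirs = sorted(p for p in base.iterdir() if (p / "manifest.yaml").exists())
    if not dirs:
        raise FileNotFoundError(f"no sessions under {base}")
    return dirs


def _load_sessions(config: PipelineConfig) -> list[Session]:
    return [load_session(d) for d in _session_dirs(config)]


def stage_score(config: PipelineConfig, sessions: list[Session]) -> pd.DataFrame:
    scores = pd.concat([score_session(s) for s in sessions], ignore_index=True)
    scores.to_csv(Path(config.out_dir) / "scores.csv", index=False)
    return scores


def stage_synchrony(config: PipelineConfig, sessions: list[Session]) -> pd.DataFrame:
    rows = []
    for session in sessions:
        for blk in session.blocks:
            if blk.index not in (1, 2) or len(blk.eda) < 2:
                continue
            params, result = crqa_mod.dyad_synchrony(
                blk.eda["demonstrator"],
                blk.eda["observer"],
                target_rr_range=config.target_rr_range,
                max_delay=config.crqa_max_delay,
                max_dim=config.crqa_max_dim,
            )
            rows.append(
                {
                    "session": session.manifest.session_id,
                    "block": blk.index,
                    "dyad": f"{session.manifest.session_id}_b{blk.index}",
                    "observer": blk.observer,
                    "rr": result.rr,
                    "det": result.det,
                    "lam": result.lam,
                    "delay": params.delay,
                    "embedding_dim": params.embedding_dim,
                    "radius": params.radius,
                    "achieved_rr": params.achieved_rr,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        df["det_z"] = crqa_mod.transform_synchrony_metrics(df["det"].to_numpy())
        df["lam_z"] = crqa_mod.transform_synchrony_metrics(df["lam"].to_numpy())
    df.to_csv(Path(config.out_dir) / "synchrony.csv", index=False)
    return df


def stage_psych_sync(config: PipelineConfig, sessions: list[Session]) -> pd.DataFrame:
    df = session_psychological_synchrony(sessions)
    df.to_csv(Path(config.out_dir) / "psync.csv", index=False)
    return df


def stage_responders(config: PipelineConfig, sessions: list[Session]) -> pd.DataFrame:
    rows = []
    streams = np.random.SeedSequence([config.seed, 9173]).spawn(len(sessions) * 3)
    k = 0
    for session in sessions:
        for blk in session.blocks:
            rng = np.random.default_rng(streams[k])
            k += 1
            ratings = [t.pain_rating for t in blk.trials]
            cues = [t.cue for t in blk.trials]
            res = classify_responder(
                ratings,
                cues,
                n_perm=config.n_perm,
                seed=rng,
                alpha=config.responder_alpha,
                exact=config.exact_permutations,
                participant_id=blk.demonstrator,
            )
            rows.append(
                {
                    "session": session.manifest.session_id,
                    "block": blk.index,
                    "participant": blk.demonstrator,
                    "generation": session.manifest.generation_of(blk.demonstrator),
                    "observed_diff": res.observed_diff,
                    "p_upper": res.p_upper,
                    "p_lower": res.p_lower,
                    "responder_class": res.responder_class,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(Path(config.out_dir) / "responders.csv", index=False)
    return df


def _demonstrator_pain_table(sessions: list[Session]) -> pd.DataFrame:
    """Tidy per-trial pain ratings for G2/G3 demonstration blocks."""
    rows = []
    for session in sessions:
        for blk in session.blocks:
            gen = session.manifest.generation_of(blk.demonstrator)
            if gen not in ("G2", "G3"):
                continue
            per_cue = {"Tx": 0, "NT": 0}
            for t in blk.trials:
                per_cue[t.cue] += 1
                rows.append(
                    {
                        "subject": blk.demonstrator,
                        "generation": gen,
                        "gender_match": 0.5 if blk.gender_match else -0.5,
                        "cue": t.cue,
                        "trial": per_cue[t.cue],
                        "value": t.pain_rating,
                    }
                )
    return pd.DataFrame(rows)


def _phasic_pair_table(scores: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Trial-pair-averaged transformed scores for G2/G3 demonstrators."""
    sel = scores[
        (scores["outcome"] == outcome)
        & (scores["role"] == "demonstrator")
        & (scores["generation"].isin(["G2", "G3"]))
    ]
    rows = []
    for (subject, gen, cue), grp in sel.groupby(["participant", "generation", "cue"]):
        grp = grp.sort_values("trial")
        vals = grp["transformed"].to_numpy()
        excl = grp["excluded"].to_numpy(dtype=bool)
        if vals.size != 6:
            continue
        levels = average_trial_pairs(vals, excl)
        for lv, v in enumerate(levels, start=1):
            rows.append(
                {
                    "subject": subject,
                    "generation": gen,
                    "cue": cue,
                    "trial": lv,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def _nocebo_magnitude(sessions: list[Session]) -> pd.DataFrame:
    """Tx−NT mean pain per G2/G3 demonstrator, with the dyad they observed in."""
    rows = []
    for session in sessions:
        gen_of = session.manifest.generation_of
        for blk in session.blocks:
            gen = gen_of(blk.demonstrator)
            if gen not in ("G2", "G3"):
                continue
            tx = [t.pain_rating for t in blk.trials if t.cue == "Tx"]
            nt = [t.pain_rating for t in blk.trials if t.cue == "NT"]
            rows.append(
                {
                    "subject": blk.demonstrator,
                    "generation": gen,
                    "generation_code": 1.0 if gen == "G2" else -1.0,
                    "nocebo": float(np.mean(tx) - np.mean(nt)),
                    # the dyad in which this subject was the observer
                    "observed_dyad": f"{session.manifest.session_id}_b{blk.index - 1}",
                }
            )
    return pd.DataFrame(rows)


def stage_analyze(
    config: PipelineConfig,
    sessions: list[Session],
    scores: pd.DataFrame,
    synchrony: pd.DataFrame,
    psync: pd.DataFrame,
    responders: pd.DataFrame,
) -> dict:
    out_dir = Path(config.out_dir)
    results: dict = {}

    # primary ANCOVA: pain ratings, Cue x Trial x Generation + gender match
    pain = _demonstrator_pain_table(sessions)
    ancova_rows = []
    adjusted_rows = []
    primary = fit_mixed_ancova(pain)
    results["ancova_pain"] = primary
    for eff in primary.effects.values():
        ancova_rows.append(
            {"outcome": "pain", "effect": eff.name, "F": eff.F, "df_num": eff.df_num,
             "df_den": eff.df_den, "p": eff.p, "eta_p2": eff.eta_p2,
             "eta_ci_low": eff.eta_p2_ci[0], "eta_ci_high": eff.eta_p2_ci[1]}
        )
    for lv, am in primary.adjusted_means.items():
        adjusted_rows.append(
            {"outcome": "pain", "level": lv, "m_adj": am.mean, "se": am.se,
             "ci_low": am.ci[0], "ci_high": am.ci[1]}
        )

    # secondary ANCOVAs on trial-pair-averaged phasic outcomes
    for outcome in ("EDA_cue", "EDA_heat", "FAU_cue", "FAU_heat"):
        tab = _phasic_pair_table(scores, outcome)
        if tab.empty:
            continue
        meta = pain.drop_duplicates("subject")[["subject", "gender_match"]]
        tab = tab.merge(meta, on="subject", how="left")
        try:
            fit = fit_mixed_ancova(tab)
        except ValueError:
            continue
        results[f"ancova_{outcome}"] = fit
        for eff in fit.effects.values():
            ancova_rows.append(
                {"outcome": outcome, "effect": eff.name, "F": eff.F,
                 "df_num": eff.df_num, "df_den": eff.df_den, "p": eff.p,
                 "eta_p2": eff.eta_p2, "eta_ci_low": eff.eta_p2_ci[0],
                 "eta_ci_high": eff.eta_p2_ci[1]}
            )
    pd.DataFrame(ancova_rows).to_csv(out_dir / "ancova_effects.csv", index=False)
    pd.DataFrame(adjusted_rows).to_csv(out_dir / "adjusted_means.csv", index=False)

    # hierarchical regressions: synchrony -> + generation -> + interaction
    nocebo = _nocebo_magnitude(sessions)
    metrics = {}
    if not psync.empty:
        metrics["psych"] = psync.set_index("dyad")["z"]
    if not synchrony.empty and "det_z" in synchrony:
        metrics["det"] = synchrony.set_index("dyad")["det_z"]
        metrics["lam"] = synchrony.set_index("dyad")["lam_z"]
    regression_rows = []
    slope_rows = []
    for name, series in metrics.items():
        df = nocebo.copy()
        df["synchrony"] = df["observed_dyad"].map(series)
        df["generation_eff"] = df["generation_code"]
        df["synchrony:generation_eff"] = df["synchrony"] * df["generation_eff"]
        df = df.dropna(subset=["synchrony"])
        if len(df) < 6:
            continue
        stages = fit_hierarchical_regression(
            df,
            "nocebo",
            [["synchrony"], ["generation_eff"], ["synchrony:generation_eff"]],
        )
        results[f"regression_{name}"] = stages
        for st in stages:
            for term, row in st.table.iterrows():
                regression_rows.append(
                    {"metric": name, "stage": st.stage, "term": term,
                     "B": row["B"], "SE": row["SE"], "beta": row["beta"],
                     "t": row["t"], "p": row["p"], "ci_low": row["ci_low"],
                     "ci_high": row["ci_high"], "r2_adj": st.r2_adj,
                     "F": st.F, "f_p": st.f_p}
                )
        slopes = simple_slopes(
            stages[-1], "synchrony", "generation_eff", {"G2": 1.0, "G3": -1.0}
        )
        results[f"slopes_{name}"] = slopes
        for label, est, se, ci in slopes.slopes:
            slope_rows.append(
                {"metric": name, "level": label, "B": est, "se": se,
                 "ci_low": ci[0], "ci_high": ci[1]}
            )
    pd.DataFrame(regression_rows).to_csv(out_dir / "regressions.csv", index=False)
    pd.DataFrame(slope_rows).to_csv(out_dir / "simple_slopes.csv", index=False)

    # responder proportions across G2/G3 demonstration blocks
    sub = responders[responders["generation"].isin(["G2", "G3"])]
    if not sub.empty:
        tab = np.zeros((2, 2), dtype=int)
        for i, gen in enumerate(["G2", "G3"]):
            grp = sub[sub["generation"] == gen]
            tab[i, 0] = int((grp["responder_class"] == "responder").sum())
            tab[i, 1] = int((grp["responder_class"] != "responder").sum())
        try:
            chi2, p, v = responder_proportions_test(tab)
            pd.DataFrame(
                [{"chi2": chi2, "p": p, "cramers_v": v, "n": int(tab.sum())}]
            ).to_csv(out_dir / "responder_proportions.csv", index=False)
            results["responder_proportions"] = (chi2, p, v)
        except ValueError:
            pass
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the in-memory stage results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        stage_simulate(config)
    sessions = _load_sessions(config)
    scores = stage_score(config, sessions)
    gen = config.generator_config() if config.simulate else None
    if config.simulate and not gen.generate_eda:
        synchrony = pd.DataFrame()
        synchrony.to_csv(out_dir / "synchrony.csv", index=False)
    else:
        synchrony = stage_synchrony(config, sessions)
    psync = stage_psych_sync(config, sessions)
    responders = stage_responders(config, sessions)
    results = stage_analyze(config, sessions, scores, synchrony, psync, responders)
    manifest = {
        "run_id": config.run_id(),
        "config": dataclasses.asdict(config),
        "n_sessions": len(sessions),
        "tables": sorted(p.name for p in out_dir.glob("*.csv")),
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
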