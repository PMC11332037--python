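"""Psychological synchrony, permutation responder classification, proportions.

*Psychological synchrony* is the per-dyad product-moment correlation between
the demonstrator's and the observer's trial-level pain-expectancy ratings —
how well the observer tracked what the demonstrator expected to feel.

*Responder classification* asks whether a subject's mean Tx−NT pain-rating
difference exceeds what random relabelling of their 12 trials could produce:
a Monte-Carlo permutation test (10,000 relabellings by default, or the exact
C(12,6) = 924 enumeration) with the add-one p-value estimator. Subjects in
the upper 5% tail are responders, in the lower tail reverse-responders, all
others non-responders.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynchronyScore",
    "ResponderResult",
    "psychological_synchrony",
    "classify_responder",
    "responder_proportions_test",
    "session_psychological_synchrony",
]

RESPONDER_ALPHA = 0.05
MIN_PAIRS = 3


@dataclass
class SynchronyScore:
    dyad_id: str
    r: float  # NaN when the dyad is unusable
    n_trials_used: int
    z: float | None = None  # filled after standardising across dyads


@dataclass
class ResponderResult:
    participant_id: str
    observed_diff: float  # mean Tx pain − mean NT pain, VAS points
    p_upper: float
    p_lower: float
    responder_class: str  # responder | non_responder | reverse_responder
    n_perm: int


def psychological_synchrony(
    dem_expectancies,
    obs_expectancies,
    *,
    dyad_id: str = "",
    method: str = "pearson",
) -> SynchronyScore:
    """Trial-level expectancy correlation for one dyad.

    Trials where either rating is missing are dropped pairwise. Dyads with
    fewer than 3 usable pairs, or zero variance in either member, get a NaN
    score (and are excluded from downstream synchrony analyses).
    """
    d = np.array([np.nan if v is None else v for v in dem_expectancies], dtype=float)
    o = np.array([np.nan if v is None else v for v in obs_expectancies], dtype=float)
    if d.size != o.size:
        raise ValueError("dyad rating vectors must have equal length")
    ok = ~(np.isnan(d) | np.isnan(o))
    n = int(ok.sum())
    if n < MIN_PAIRS or d[ok].std() == 0 or o[ok].std() == 0:
        return SynchronyScore(dyad_id, float("nan"), n)
    if method == "pearson":
        r = float(np.corrcoef(d[ok], o[ok])[0, 1])
    elif method == "spearman":
        r = float(stats.spearmanr(d[ok], o[ok]).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return SynchronyScore(dyad_id, r, n)


def _null_distribution(
    ratings: np.ndarray,
    n_tx: int,
    n_perm: int,
    rng: np.random.Generator,
    exact: bool,
) -> np.ndarray:
    """Mean(Tx) − mean(NT) under random relabellings preserving group sizes."""
    n = ratings.size
    n_nt = n - n_tx
    total = ratings.sum()

    def diff_from_tx_sum(tx_sum):
        return tx_sum / n_tx - (total - tx_sum) / n_nt

    if exact:
        tx_sums = np.array(
            [ratings[list(c)].sum() for c in combinations(range(n), n_tx)]
        )
        return diff_from_tx_sum(tx_sums)
    # random permutations: argsort of uniforms gives uniform random subsets
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_tx]
    tx_sums = ratings[order].sum(axis=1)
    return diff_from_tx_sum(tx_sums)


def classify_responder(
    pain_ratings,
    cue_labels,
    *,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    alpha: float = RESPONDER_ALPHA,
    exact: bool = False,
    participant_id: str = "",
) -> ResponderResult:
    """Permutation-classify one subject's Tx−NT pain difference.

    ``p_upper`` uses the add-one estimator (1 + #{null >= observed}) /
    (1 + n_perm), with ties counted toward the null. A subject is a responder
    if ``p_upper <= alpha``, a reverse-responder if ``p_lower <= alpha``, and
    a non-responder otherwise; identical ratings are non-responders by
    construction (degenerate null).
    """
    ratings = np.asarray(pain_ratings, dtype=float)
    labels = np.asarray(cue_labels)
    if ratings.size != labels.size:
        raise ValueError("ratings and labels must have equal length")
    tx = labels == "Tx"
    n_tx, n_nt = int(tx.sum()), int((~tx).sum())
    if n_tx == 0 or n_nt == 0:
        raise ValueError("need at least one trial of each cue")
    if not (n_tx == n_nt == 6):
        import warnings

        warnings.warn(f"unbalanced or short design: {n_tx} Tx / {n_nt} NT trials")
    observed = float(ratings[tx].mean() - ratings[~tx].mean())
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    null = _null_distribution(ratings, n_tx, n_perm, rng, exact)
    m = null.size
    eps = 1e-12 * max(1.0, np.abs(null).max())  # tolerate float roundoff in ties
    p_upper = (1 + int((null >= observed - eps).sum())) / (1 + m)
    p_lower = (1 + int((null <= observed + eps).sum())) / (1 + m)
    if p_upper <= alpha:
        cls = "responder"
    elif p_lower <= alpha:
        cls = "reverse_responder"
    else:
        cls = "non_responder"
    return ResponderResult(participant_id, observed, p_upper, p_lower, cls, m)


def responder_proportions_test(counts_2x2) -> tuple[float, float, float]:
    """Pearson χ² (no continuity correction) and Cramér's V on a 2×2 table.

    Returns ``(chi2, p, V)`` with ``V = sqrt(chi2 / N)``.
    """
    table = np.asarray(counts_2x2)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    v = float(np.sqrt(chi2 / table.sum()))
    return float(chi2), float(p), v


# ---------------------------------------------------------------------------
# session-level helpers


def session_psychological_synchrony(sessions, *, method: str = "pearson") -> pd.DataFrame:
    """Per-dyad expectancy synchrony for the two analysed blocks per session.

    Blocks 1 (G1→G2) and 2 (G2→G3) carry the transmission-relevant dyads; the
    resulting table has one row per dyad with the raw r and, across all
    usable dyads, its z-standardised value.
    """
    rows = []
    for session in sessions:
        for blk in session.blocks:
            if blk.index not in (1, 2):
                continue
            score = psychological_synchrony(
                [t.demonstrator_expectancy for t in blk.trials],
                [t.observer_expectancy for t in blk.trials],
                dyad_id=f"{session.manifest.session_id}_b{blk.index}",
                method=method,
            )
            rows.append(
                {
                    "session": session.manifest.session_id,
                    "block": blk.index,
                    "dyad": score.dyad_id,
                    "observer": blk.observer,
                    "r": score.r,
                    "n_trials_used": score.n_trials_used,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        ok = df["r"].notna()
        mu, sd = df.loc[ok, "r"].mean(), df.loc[ok, "r"].std(ddof=1)
        df["z"] = (df["r"] - mu) / sd if sd > 0 else np.nan
    return df
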