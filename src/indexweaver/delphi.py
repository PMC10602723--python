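"""Delphi panel-quality and per-indicator statistics.

A Delphi consultation sends the same indicator questionnaire to an expert
panel over successive anonymous rounds.  Its credibility is conventionally
reported through three panel-level quantities:

* the effective response rate (returned / distributed questionnaires);
* the authority coefficient Cr = (Ca + Cs) / 2, averaging each expert's
  judgment-basis coefficient Ca and self-rated familiarity Cs, with
  Cr >= 0.7 read as an authoritative panel;
* Kendall's coefficient of concordance W across experts' implied rankings
  of the indicators, tested via chi-square = m(n-1)W.

Per indicator, screening uses the arithmetic mean of the 1-5 Likert scores,
the full-mark rate (share of experts awarding the maximum score), and the
coefficient of variation sd/mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import round_half_away

LIKERT_MIN, LIKERT_MAX = 1, 5

#: Cr at or above this marks the panel as authoritative
AUTHORITY_CUTOFF = 0.7

# Judgment-basis scoring: each information source contributes a score by the
# degree it influenced the expert's judgment; Ca is the sum over sources.
# Published Delphi studies rarely print their table; this default follows
# common practice (practical experience weighted most, literature and
# intuition least) and is fully overridable.
DEFAULT_JUDGMENT_TABLE: dict[str, dict[str, float]] = {
    "practical_experience": {"high": 0.5, "medium": 0.4, "low": 0.3},
    "theoretical_analysis": {"high": 0.3, "medium": 0.2, "low": 0.1},
    "literature": {"high": 0.1, "medium": 0.1, "low": 0.1},
    "intuition": {"high": 0.1, "medium": 0.1, "low": 0.1},
}

# Familiarity self-rating -> Cs, six ordinal levels.
DEFAULT_FAMILIARITY_TABLE: dict[str, float] = {
    "very_familiar": 1.0,
    "familiar": 0.8,
    "somewhat_familiar": 0.6,
    "neutral": 0.4,
    "unfamiliar": 0.2,
    "very_unfamiliar": 0.0,
}

RATINGS_COLUMNS = ["round", "expert_id", "indicator_id", "score"]


class DegeneratePanelError(ValueError):
    """Raised when concordance is undefined (every expert scored flat)."""


@dataclass(frozen=True)
class ExpertProfile:
    """Authority attributes of one panel member."""

    expert_id: str
    ca: float
    cs: float

    @property
    def cr(self) -> float:
        return (self.ca + self.cs) / 2.0

    @property
    def authoritative(self) -> bool:
        return self.cr >= AUTHORITY_CUTOFF


@dataclass(frozen=True)
class IndicatorStats:
    """Summary of one indicator's scores in one round.

    ``sd`` is the sample standard deviation (n-1 denominator; defined as 0
    for a single rater), ``full_mark_rate`` the fraction of raters who gave
    the maximum score, and ``cv`` the coefficient of variation sd/mean.
    """

    indicator_id: str
    n_raters: int
    mean: float
    sd: float
    full_mark_rate: float
    cv: float


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its chi-square significance test."""

    w: float
    chi2: float
    df: int
    p: float


def response_rate(returned: int, distributed: int) -> float:
    """Effective response rate as a percentage, 2 decimal places.

    Rates above 70% are conventionally read as very good panel engagement,
    50% as the minimum acceptable for a Delphi round.
    """
    if distributed <= 0:
        raise ValueError("distributed must be positive")
    if not 0 <= returned <= distributed:
        raise ValueError("returned must be between 0 and distributed")
    return round_half_away(100.0 * returned / distributed, 2)


def authority_coefficient(ca: float, cs: float) -> ExpertProfile:
    """Combine judgment and familiarity coefficients into Cr = (Ca+Cs)/2."""
    for name, v in (("Ca", ca), ("Cs", cs)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return ExpertProfile(expert_id="", ca=ca, cs=cs)


def _normalise(label: str) -> str:
    return label.strip().lower().replace(" ", "_").replace("-", "_")


def judgment_coefficient(
    basis_levels: Mapping[str, str],
    table: Mapping[str, Mapping[str, float]] = DEFAULT_JUDGMENT_TABLE,
) -> float:
    """Ca: sum of per-source influence scores, clipped to [0, 1].

    ``basis_levels`` maps each judgment source (e.g. ``practical_experience``)
    to the influence grade the expert ticked (e.g. ``high``).
    """
    total = 0.0
    for source, grade in basis_levels.items():
        src, grd = _normalise(source), _normalise(grade)
        if src not in table:
            raise KeyError(f"unknown judgment source {source!r}")
        if grd not in table[src]:
            raise KeyError(f"unknown grade {grade!r} for source {source!r}")
        total += table[src][grd]
    return min(1.0, max(0.0, total))


def familiarity_coefficient(
    level: str,
    table: Mapping[str, float] = DEFAULT_FAMILIARITY_TABLE,
) -> float:
    """Cs: table lookup of the expert's familiarity self-rating."""
    key = _normalise(level)
    if key not in table:
        raise KeyError(f"unknown familiarity level {level!r}")
    return min(1.0, max(0.0, table[key]))


def indicator_stats(
    scores: Sequence[int | float],
    indicator_id: str = "",
    *,
    likert: bool = True,
) -> IndicatorStats:
    """Per-indicator summary of one round's scores.

    With ``likert=True`` (default) scores must be integers in 1-5 and the
    full-mark rate counts scores equal to 5.  ``likert=False`` admits
    arbitrary positive scores (the full-mark rate then counts the observed
    maximum) and exists for scale-invariance checks, not for real panels.
    """
    if len(scores) == 0:
        raise ValueError("no scores given")
    arr = np.asarray(scores, dtype=float)
    if likert:
        if not np.all((arr >= LIKERT_MIN) & (arr <= LIKERT_MAX)):
            raise ValueError(f"scores must lie in {LIKERT_MIN}..{LIKERT_MAX}")
        if not np.all(arr == np.round(arr)):
            raise ValueError("Likert scores must be integers")
        full = float(np.mean(arr == LIKERT_MAX))
    else:
        full = float(np.mean(arr == arr.max()))
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cv = sd / mean if mean != 0 else math.nan
    return IndicatorStats(
        indicator_id=indicator_id,
        n_raters=int(arr.size),
        mean=mean,
        sd=sd,
        full_mark_rate=full,
        cv=cv,
    )


def kendalls_w(
    score_matrix: np.ndarray | Sequence[Sequence[float]],
    *,
    n_permutations: int | None = None,
    seed: int = 0,
) -> ConcordanceResult:
    """Kendall's coefficient of concordance with midrank tie correction.

    ``score_matrix`` has one row per expert and one column per indicator;
    each row is ranked independently (ties get midranks).  With rank sums
    R_j and S the sum of squared deviations of R_j from their mean,

        W = 12 S / (m^2 (n^3 - n) - m * sum_e T_e),
        T_e = sum over tie groups of expert e of (t^3 - t),

    and the significance test uses chi-square = m (n-1) W on n-1 degrees
    of freedom.  With ``n_permutations`` set, the p-value instead comes
    from a seeded permutation test (each expert's scores shuffled across
    indicators independently), which is preferable for small panels where
    the chi-square approximation is weak.  Raises
    :class:`DegeneratePanelError` when every expert scored every
    indicator identically (denominator zero, W undefined).
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score_matrix must be 2-D (experts × indicators)")
    m, n = scores.shape
    if m < 2:
        raise ValueError("need at least 2 experts")
    if n < 2:
        raise ValueError("need at least 2 indicators")
    if np.isnan(scores).any():
        raise ValueError("missing cells must be handled upstream")

    ranks = np.apply_along_axis(sps.rankdata, 1, scores)
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))

    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))

    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise DegeneratePanelError(
            "degenerate panel: every expert gave a constant score vector"
        )
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    if n_permutations is None:
        p = float(sps.chi2.sf(chi2, df))
    else:
        # permutation null: shuffle each expert's row independently; ties
        # (and hence the denominator) are preserved within rows
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm_ranks = np.array([rng.permutation(row) for row in ranks])
            sums = perm_ranks.sum(axis=0)
            s_perm = float(np.sum((sums - sums.mean()) ** 2))
            hits += (12.0 * s_perm / denom) >= w - 1e-12
        p = (1 + hits) / (1 + n_permutations)
    return ConcordanceResult(w=float(w), chi2=float(chi2), df=df, p=p)


# ---- tabular interface -------------------------------------------------


def read_ratings(path) -> pd.DataFrame:
    """Read a ratings CSV (``round,expert_id,indicator_id,score``, extra
    columns preserved) and validate types and Likert range."""
    df = pd.read_csv(path, dtype={"expert_id": str, "indicator_id": str})
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings file missing columns: {missing}")
    bad = df[~df["score"].isin(range(LIKERT_MIN, LIKERT_MAX + 1))]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"ratings row {row}: score {bad.loc[row, 'score']!r} "
            f"outside {LIKERT_MIN}..{LIKERT_MAX}"
        )
    dup = df.duplicated(subset=["round", "expert_id", "indicator_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate rating for round={row['round']} "
            f"expert={row['expert_id']} indicator={row['indicator_id']}"
        )
    return df


def stats_by_indicator(
    ratings: pd.DataFrame, round_no: int
) -> dict[str, IndicatorStats]:
    """Per-indicator stats for one round.  Experts who skipped an indicator
    simply do not appear in its score list (complete-case per indicator)."""
    sub = ratings[ratings["round"] == round_no]
    if sub.empty:
        raise ValueError(f"no ratings for round {round_no}")
    out: dict[str, IndicatorStats] = {}
    for ind, grp in sub.groupby("indicator_id", sort=False):
        out[str(ind)] = indicator_stats(grp["score"].tolist(), str(ind))
    return out


def score_matrix(ratings: pd.DataFrame, round_no: int) -> pd.DataFrame:
    """Experts × indicators score matrix for concordance; drops experts with
    any missing indicator (complete-case for the W computation)."""
    sub = ratings[ratings["round"] == round_no]
    if sub.empty:
        raise ValueError(f"no ratings for round {round_no}")
    wide = sub.pivot(index="expert_id", columns="indicator_id", values="score")
    return wide.dropna(axis=0, how="any")


def stats_to_json_dict(stats: Mapping[str, IndicatorStats]) -> dict:
    """JSON-ready export keyed by indicator id."""
    return {
        ind: {
            "n_raters": s.n_raters,
            "mean": s.mean,
            "sd": s.sd,
            "full_mark_rate": s.full_mark_rate,
            "cv": s.cv,
        }
        for ind, s in stats.items()
    }
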