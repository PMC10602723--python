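"""Synthetic expert panels and judgment matrices.

Real Delphi data are rarely published beyond summary tables, so the
toolkit ships a generator that emulates the structure such a study
assumes: a panel of experts, each with an idiosyncratic leniency bias,
scoring indicators whose "true" importance is a latent 1–5 value; a second
round in which opinions drift toward the round-1 panel mean and scatter
shrinks (consensus); reciprocal pairwise-comparison matrices scattered
log-normally around the ratios of latent weights; and Bernoulli
keep/exclude votes on inquiry items.

Every generator draws from a single seeded :class:`numpy.random.Generator`,
so outputs are bit-reproducible given the seed.

The packaged fixture — a published three-level doctor-evaluation index
system for online medical platforms (3 dimensions, 8 sub-dimensions, 60
leaf indicators with AHP local weights) and its panel metadata (23 experts
invited, 19 and 21 questionnaires returned over two rounds) — provides a
real-world hierarchy against which aggregation is verified.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import SAATY_MAX, SAATY_MIN, JudgmentMatrix
from .delphi import (
    DEFAULT_FAMILIARITY_TABLE,
    DEFAULT_JUDGMENT_TABLE,
    ExpertProfile,
    LIKERT_MAX,
    LIKERT_MIN,
)
from .hierarchy import IndexHierarchy

log = logging.getLogger(__name__)


@dataclass
class PanelSimConfig:
    """Study conditions for a synthetic two-round Delphi panel.

    Defaults emulate the panel the packaged fixture documents: 23 invited
    experts, 69 candidate indicators, 19 respondents in round 1 and 21 in
    round 2.  ``expert_bias_sd`` is the spread of per-expert leniency (in
    score units), ``rating_noise_sd`` the per-rating scatter in round 1,
    ``consensus_factor`` the multiplier applied to that scatter per later
    round, and ``drift`` the fraction by which round-2 latent importances
    move toward the round-1 panel mean.
    """

    latent_importance: dict[str, float]
    n_experts: int = 23
    respondents_per_round: tuple[int, int] = (19, 21)
    expert_bias_sd: float = 0.3
    rating_noise_sd: float = 0.6
    consensus_factor: float = 0.7
    drift: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts")
        if any(r < 2 or r > self.n_experts for r in self.respondents_per_round):
            raise ValueError("respondents must be between 2 and n_experts")
        if self.expert_bias_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.consensus_factor <= 1:
            raise ValueError("consensus_factor must lie in (0, 1]")
        if not 0 <= self.drift <= 1:
            raise ValueError("drift must lie in [0, 1]")
        for ind, v in self.latent_importance.items():
            if not LIKERT_MIN <= v <= LIKERT_MAX:
                raise ValueError(
                    f"latent importance of {ind!r} outside "
                    f"[{LIKERT_MIN}, {LIKERT_MAX}]"
                )


def default_panel_config(
    n_indicators: int = 69, seed: int = 0, **overrides
) -> PanelSimConfig:
    """Panel config with latent importances spread over the upper scale
    (uniform on [2.5, 5.0] — candidate indicators pre-screened by design
    are rarely rated unimportant on average)."""
    rng = np.random.default_rng(seed)
    latent = {
        f"I{k + 1}": float(rng.uniform(2.5, 5.0)) for k in range(n_indicators)
    }
    return PanelSimConfig(latent_importance=latent, seed=seed, **overrides)


def _half_up_int(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_ratings(
    config: PanelSimConfig,
) -> tuple[pd.DataFrame, list[ExpertProfile]]:
    """Two rounds of Likert ratings plus expert authority profiles.

    A rating is ``clamp(round(latent + bias_e + eps), 1, 5)`` with
    ``bias_e ~ N(0, expert_bias_sd)`` fixed per expert and
    ``eps ~ N(0, rating_noise_sd * consensus_factor**(round-1))``.
    Between rounds each latent importance is pulled ``drift`` of the way
    toward the indicator's observed round-1 panel mean.  Respondent
    subsets per round are drawn from the invited pool.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    experts = [f"E{k + 1:02d}" for k in range(config.n_experts)]
    indicators = list(config.latent_importance)
    bias = {e: rng.normal(0.0, config.expert_bias_sd) for e in experts}

    profiles = []
    sources = list(DEFAULT_JUDGMENT_TABLE)
    grades = ["high", "medium", "low"]
    fam_levels = list(DEFAULT_FAMILIARITY_TABLE)[:4]
    for e in experts:
        ca = sum(
            DEFAULT_JUDGMENT_TABLE[src][rng.choice(grades, p=[0.5, 0.35, 0.15])]
            for src in sources
        )
        cs = DEFAULT_FAMILIARITY_TABLE[
            rng.choice(fam_levels, p=[0.35, 0.35, 0.2, 0.1])
        ]
        profiles.append(ExpertProfile(expert_id=e, ca=min(1.0, ca), cs=cs))

    latent = dict(config.latent_importance)
    records: list[dict] = []
    for rnd in (1, 2):
        n_resp = config.respondents_per_round[rnd - 1]
        respondents = sorted(rng.choice(experts, size=n_resp, replace=False))
        noise_sd = config.rating_noise_sd * config.consensus_factor ** (rnd - 1)
        round_scores: dict[str, list[int]] = {i: [] for i in indicators}
        for e in respondents:
            eps = rng.normal(0.0, noise_sd, size=len(indicators))
            raw = np.array([latent[i] for i in indicators]) + bias[e] + eps
            scores = np.clip(_half_up_int(raw), LIKERT_MIN, LIKERT_MAX)
            for i, s in zip(indicators, scores):
                records.append(
                    {"round": rnd, "expert_id": e,
                     "indicator_id": i, "score": int(s)}
                )
                round_scores[i].append(int(s))
        if rnd == 1:
            # consensus drift: latent opinion moves toward the panel mean
            for i in indicators:
                panel_mean = float(np.mean(round_scores[i]))
                latent[i] = latent[i] + config.drift * (panel_mean - latent[i])

    return pd.DataFrame(records), profiles


def simulate_judgment_matrix(
    latent_weights: Mapping[str, float] | Sequence[float],
    pairwise_noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> JudgmentMatrix:
    """Reciprocal matrix scattered around the latent weight ratios.

    Upper-triangle entries are ``(w_i / w_j) * exp(eps)`` with
    ``eps ~ N(0, pairwise_noise_sd)``; lower triangle set reciprocal;
    entries clipped into the Saaty range [1/9, 9] (clips are logged).
    Zero noise yields the exactly consistent matrix of the weights.
    """
    if isinstance(latent_weights, Mapping):
        ids = tuple(latent_weights)
        w = np.array([latent_weights[i] for i in ids], dtype=float)
    else:
        w = np.asarray(latent_weights, dtype=float)
        ids = tuple(f"W{k + 1}" for k in range(w.size))
    if np.any(w <= 0):
        raise ValueError("latent weights must be positive")
    if pairwise_noise_sd < 0:
        raise ValueError("pairwise_noise_sd must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = w.size
    a = np.ones((n, n))
    clipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            entry = (w[i] / w[j]) * np.exp(rng.normal(0.0, pairwise_noise_sd))
            if entry < SAATY_MIN or entry > SAATY_MAX:
                clipped += 1
                entry = float(np.clip(entry, SAATY_MIN, SAATY_MAX))
            a[i, j] = entry
            a[j, i] = 1.0 / entry
    if clipped:
        log.info("simulate_judgment_matrix: clipped %d entries into [1/9, 9]",
                 clipped)
    return JudgmentMatrix(ids=ids, values=a)


def simulate_inquiry_votes(
    exclusion_propensity: Mapping[str, float],
    n_voters: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Independent Bernoulli keep/exclude votes per inquiry item.

    Columns ``indicator_id, expert_id, vote`` with vote in
    {``exclude``, ``keep``}; deterministic given the seed.
    """
    if n_voters < 1:
        raise ValueError("need at least one voter")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    records = []
    for ind, p in exclusion_propensity.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"propensity for {ind!r} outside [0, 1]")
        draws = rng.random(n_voters) < p
        for k, vote in enumerate(draws):
            records.append(
                {"indicator_id": ind, "expert_id": f"E{k + 1:02d}",
                 "vote": "exclude" if vote else "keep"}
            )
    return pd.DataFrame(records, columns=["indicator_id", "expert_id", "vote"])


def published_screening_scenario() -> tuple[
    dict[str, "IndicatorStats"], dict[str, "IndicatorStats"],
    dict[str, tuple[int, int]],
]:
    """Reconstruct the documented two-round screening bookkeeping.

    The consultation behind the packaged fixture published its screening
    *counts* but not the raw scores: 69 candidate items, of which 1 failed
    all three round-1 critical values, 5 failed exactly two (inquiry
    items), two inquiry items drew agreed exclusion rates of 52.4% (11/21)
    and 71.4% (15/21) and were dropped, 66 items were evaluated in round 2
    and 6 failed the fixed thresholds, leaving 60.  This helper builds
    per-indicator statistics that realise exactly that pattern under the
    engine's own critical values, so the workflow can be exercised and
    audited end to end.

    Returns ``(stats_round1, stats_round2, inquiry_votes)`` ready for
    :func:`indexweaver.screening.screen_from_stats`.
    """
    from .delphi import IndicatorStats

    def make(ind: str, mean: float, full: float, cv: float) -> IndicatorStats:
        return IndicatorStats(
            indicator_id=ind, n_raters=19, mean=mean,
            sd=cv * mean, full_mark_rate=full, cv=cv,
        )

    stats1: dict[str, IndicatorStats] = {}
    for k in range(1, 64):  # consensual items: pass all three criteria
        stats1[f"G{k:02d}"] = make(f"G{k:02d}", 4.5, 0.6, 1.0 / 9.0)
    for k in range(1, 6):  # inquiry items: fail mean and CV, pass full-mark
        stats1[f"Q{k}"] = make(f"Q{k}", 3.0, 0.6, 0.5)
    stats1["X1"] = make("X1", 3.0, 0.0, 0.5)  # fails all three

    votes = {"Q1": (11, 21), "Q2": (15, 21),
             "Q3": (10, 21), "Q4": (10, 21), "Q5": (10, 21)}

    # round 2: the 63 direct entrants plus re-entered Q3-Q5; six items
    # (the re-entered three and three others) slip under the mean > 3.5
    # threshold and are rejected
    stats2: dict[str, IndicatorStats] = {}
    for k in range(1, 61):
        stats2[f"G{k:02d}"] = make(f"G{k:02d}", 4.5, 0.6, 0.1)
    for ind in ("G61", "G62", "G63", "Q3", "Q4", "Q5"):
        stats2[ind] = make(ind, 3.2, 0.3, 0.1)
    return stats1, stats2, votes


@dataclass(frozen=True)
class FixtureData:
    """The packaged doctor-evaluation hierarchy and its panel metadata."""

    hierarchy: IndexHierarchy
    panel: dict
    printed_combination_weights: dict[str, float]
    name: str = ""
    description: str = ""


def reference_fixture() -> FixtureData:
    """Load the packaged doctor-evaluation index system.

    Three first-level dimensions (system, service and information quality),
    8 second-level and 60 third-level indicators, each with its published
    AHP local weight, plus the published combination weights for
    comparison and the consultation panel's response metadata.
    """
    resource = importlib.resources.files("indexweaver.data").joinpath(
        "doctor_evaluation_hierarchy.json"
    )
    doc = json.loads(resource.read_text(encoding="utf-8"))
    return FixtureData(
        hierarchy=IndexHierarchy.from_dict(doc),
        panel=doc["panel"],
        printed_combination_weights={
            k: float(v) for k, v in doc["printed_combination_weights"].items()
        },
        name=doc.get("name", ""),
        description=doc.get("description", ""),
    )
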