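"""Two-round critical-value screening of candidate indicators.

Round 1 scores every candidate indicator on three criteria derived from the
panel's own score distribution at each hierarchy level:

* mean criterion — retain if the indicator's mean score is at least
  (mean of means) − (SD of means) across the level's indicators;
* full-mark criterion — retain if its full-mark rate is at least
  (mean rate) − (SD of rates);
* CV criterion — retain if its coefficient of variation is at most
  (mean CV) + (SD of CVs).

An indicator failing **all three** is excluded outright; failing **exactly
two** makes it an *inquiry item*, put to an explicit keep/exclude vote in
the next round and excluded when the agreed exclusion rate exceeds 50%;
otherwise it advances.  Round 2 re-evaluates the advancing set against
fixed thresholds (mean > 3.5 and CV < 0.25) combined, by default, with the
recomputed critical values; there is no inquiry status in round 2.

Every decision, threshold, and count is recorded in a
:class:`ScreeningLedger` so the screening trail can be audited end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .delphi import IndicatorStats, stats_by_indicator

log = logging.getLogger(__name__)

RETAINED = "retained"
EXCLUDED = "excluded"
INQUIRY = "inquiry"

#: round-2 fixed retention thresholds (strict inequalities)
ROUND2_MEAN_GT = 3.5
ROUND2_CV_LT = 0.25

#: agreed exclusion rate (percent) strictly above which an inquiry item is
#: dropped
EXCLUSION_RATE_CUTOFF = 50.0

POLICY_THRESHOLD_AND_CRITICAL = "threshold_and_critical"
POLICY_THRESHOLD_ONLY = "threshold_only"


@dataclass(frozen=True)
class ScreeningThresholds:
    """Level-wide critical values for one round.

    Retention requires mean >= ``crit_mean``, full-mark rate >=
    ``crit_full`` and CV <= ``crit_cv`` (boundary equality passes).
    """

    crit_mean: float
    crit_full: float
    crit_cv: float


@dataclass(frozen=True)
class ScreeningDecision:
    indicator_id: str
    status: str  # retained | excluded | inquiry
    failed_criteria: frozenset[str]
    round: int


@dataclass(frozen=True)
class InquiryResolution:
    """Outcome of the keep/exclude vote on one inquiry item."""

    indicator_id: str
    votes_exclude: int
    votes_total: int
    agreed_exclusion_rate: float  # percent, 1 dp
    outcome: str  # excluded | re_entered


@dataclass
class RoundCounts:
    evaluated: int = 0
    retained: int = 0
    excluded: int = 0
    inquiry: int = 0
    re_entered: int = 0

    def conserved(self) -> bool:
        return self.evaluated == self.retained + self.excluded + self.inquiry


@dataclass
class ScreeningLedger:
    """Full audit trail of a two-round screening run."""

    counts: dict[int, RoundCounts] = field(default_factory=dict)
    decisions: dict[int, dict[str, ScreeningDecision]] = field(default_factory=dict)
    thresholds: dict[str, ScreeningThresholds] = field(default_factory=dict)
    resolutions: dict[str, InquiryResolution] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    manual_edits: dict | None = None
    final_indicators: list[str] = field(default_factory=list)

    def note(self, indicator_id: str, event: str) -> None:
        self.provenance.setdefault(indicator_id, []).append(event)

    def to_json_dict(self) -> dict:
        return {
            "counts": {
                str(r): vars(c).copy() for r, c in sorted(self.counts.items())
            },
            "thresholds": {
                key: vars(t).copy() for key, t in self.thresholds.items()
            },
            "decisions": {
                str(r): {
                    ind: {
                        "status": d.status,
                        "failed_criteria": sorted(d.failed_criteria),
                    }
                    for ind, d in decs.items()
                }
                for r, decs in sorted(self.decisions.items())
            },
            "inquiry_resolutions": {
                ind: {
                    "votes_exclude": res.votes_exclude,
                    "votes_total": res.votes_total,
                    "agreed_exclusion_rate": res.agreed_exclusion_rate,
                    "outcome": res.outcome,
                }
                for ind, res in self.resolutions.items()
            },
            "provenance": self.provenance,
            "manual_edits": self.manual_edits,
            "final_indicators": list(self.final_indicators),
        }

    def flow_summary(self) -> str:
        """Human-readable mirror of the screening flow chart."""
        lines = []
        for rnd in sorted(self.counts):
            c = self.counts[rnd]
            lines.append(
                f"Round {rnd}: {c.evaluated} evaluated -> "
                f"{c.retained} retained, {c.excluded} excluded"
                + (f", {c.inquiry} inquiry items" if rnd == 1 else "")
                + (f" (incl. {c.re_entered} re-entered inquiry items)"
                   if rnd == 2 and c.re_entered else "")
            )
        for ind, res in self.resolutions.items():
            lines.append(
                f"  inquiry {ind}: {res.votes_exclude}/{res.votes_total} "
                f"exclusion votes = {res.agreed_exclusion_rate}% -> {res.outcome}"
            )
        if self.manual_edits:
            removed = self.manual_edits.get("remove", [])
            lines.append(
                f"Manual edits: removed {len(removed)} item(s) "
                f"({self.manual_edits.get('note', 'no note')})"
            )
        lines.append(f"Final list: {len(self.final_indicators)} indicators")
        return "\n".join(lines)


def critical_values(
    stats: Iterable[IndicatorStats] | Mapping[str, IndicatorStats],
) -> ScreeningThresholds:
    """Level-wide critical values from one round's indicator stats.

    Each threshold pairs the across-indicator mean of a statistic with its
    across-indicator sample SD: mean − SD for means and full-mark rates
    (screen out the low tail), mean + SD for CVs (screen out the
    high-dispersion tail).  Needs at least two indicators, otherwise the
    across-indicator SD is undefined.
    """
    pool = list(stats.values()) if isinstance(stats, Mapping) else list(stats)
    if len(pool) < 2:
        raise ValueError("critical values need at least 2 indicators")
    means = np.array([s.mean for s in pool])
    fulls = np.array([s.full_mark_rate for s in pool])
    cvs = np.array([s.cv for s in pool])
    return ScreeningThresholds(
        crit_mean=float(means.mean() - means.std(ddof=1)),
        crit_full=float(fulls.mean() - fulls.std(ddof=1)),
        crit_cv=float(cvs.mean() + cvs.std(ddof=1)),
    )


def _critical_failures(
    s: IndicatorStats, t: ScreeningThresholds
) -> frozenset[str]:
    failed = set()
    if s.mean < t.crit_mean:
        failed.add("mean")
    if s.full_mark_rate < t.crit_full:
        failed.add("full_mark")
    if s.cv > t.crit_cv:
        failed.add("cv")
    return frozenset(failed)


def classify_round1(
    stats: Mapping[str, IndicatorStats],
    thresholds: ScreeningThresholds,
) -> dict[str, ScreeningDecision]:
    """Round-1 rule: fail all three criteria → excluded; fail exactly two →
    inquiry item; otherwise retained (boundary equality passes)."""
    decisions = {}
    for ind, s in stats.items():
        failed = _critical_failures(s, thresholds)
        if len(failed) == 3:
            status = EXCLUDED
        elif len(failed) == 2:
            status = INQUIRY
        else:
            status = RETAINED
        decisions[ind] = ScreeningDecision(ind, status, failed, round=1)
        log.debug("round1 %s: failed=%s -> %s", ind, sorted(failed), status)
    return decisions


def resolve_inquiry(
    votes_exclude: int, votes_total: int, indicator_id: str = ""
) -> InquiryResolution:
    """Agreed-exclusion-rate vote: excluded iff the rate (1 dp, ties away
    from zero) strictly exceeds 50%."""
    if votes_total <= 0:
        raise ValueError("votes_total must be positive")
    if not 0 <= votes_exclude <= votes_total:
        raise ValueError("votes_exclude must be between 0 and votes_total")
    rate = round_half_away(100.0 * votes_exclude / votes_total, 1)
    outcome = EXCLUDED if rate > EXCLUSION_RATE_CUTOFF else "re_entered"
    return InquiryResolution(indicator_id, votes_exclude, votes_total, rate, outcome)


def classify_round2(
    stats: Mapping[str, IndicatorStats],
    thresholds: ScreeningThresholds | None,
    policy: str = POLICY_THRESHOLD_AND_CRITICAL,
) -> dict[str, ScreeningDecision]:
    """Round-2 rule: retain iff mean > 3.5 and CV < 0.25 (strict), and —
    under the default policy — the indicator does not fail all three
    recomputed critical values.  No inquiry status in round 2."""
    if policy not in (POLICY_THRESHOLD_AND_CRITICAL, POLICY_THRESHOLD_ONLY):
        raise ValueError(f"unknown round-2 policy {policy!r}")
    if policy == POLICY_THRESHOLD_AND_CRITICAL and thresholds is None:
        raise ValueError("default policy needs critical-value thresholds")
    decisions = {}
    for ind, s in stats.items():
        failed = set()
        if not s.mean > ROUND2_MEAN_GT:
            failed.add("threshold_mean")
        if not s.cv < ROUND2_CV_LT:
            failed.add("threshold_cv")
        if policy == POLICY_THRESHOLD_AND_CRITICAL:
            crit_failed = _critical_failures(s, thresholds)  # type: ignore[arg-type]
            if len(crit_failed) == 3:
                failed |= crit_failed
        status = RETAINED if not failed else EXCLUDED
        decisions[ind] = ScreeningDecision(ind, status, frozenset(failed), round=2)
        log.debug("round2 %s: failed=%s -> %s", ind, sorted(failed), status)
    return decisions


def screen_from_stats(
    stats_round1: Mapping[str, IndicatorStats],
    stats_round2: Mapping[str, IndicatorStats],
    inquiry_votes: Mapping[str, tuple[int, int]],
    *,
    level_of: Mapping[str, int] | None = None,
    round2_policy: str = POLICY_THRESHOLD_AND_CRITICAL,
) -> ScreeningLedger:
    """Run the full two-round workflow on precomputed per-indicator stats.

    ``inquiry_votes`` maps each round-1 inquiry item to
    ``(votes_exclude, votes_total)``.  ``level_of`` scopes critical values
    to hierarchy levels (default: one pool for the whole questionnaire).
    ``stats_round2`` must cover every advancing indicator; extra items are
    ignored.  Critical values are recomputed on the round-2 population.
    """
    ledger = ScreeningLedger()

    def groups(ids: Sequence[str]) -> dict[object, list[str]]:
        if level_of is None:
            return {"all": list(ids)}
        out: dict[object, list[str]] = {}
        for ind in ids:
            out.setdefault(level_of.get(ind, "all"), []).append(ind)
        return out

    # ---- round 1 -------------------------------------------------------
    decisions1: dict[str, ScreeningDecision] = {}
    for key, members in groups(list(stats_round1)).items():
        pool = {ind: stats_round1[ind] for ind in members}
        thr = critical_values(pool)
        ledger.thresholds[f"round1/{key}"] = thr
        log.info("round 1 critical values [%s]: mean>=%.4f full>=%.4f cv<=%.4f",
                 key, thr.crit_mean, thr.crit_full, thr.crit_cv)
        decisions1.update(classify_round1(pool, thr))
    ledger.decisions[1] = decisions1

    c1 = RoundCounts(evaluated=len(decisions1))
    advancing: list[str] = []
    inquiry_items: list[str] = []
    for ind, d in decisions1.items():
        ledger.note(ind, f"round1:{d.status}")
        if d.status == RETAINED:
            c1.retained += 1
            advancing.append(ind)
        elif d.status == EXCLUDED:
            c1.excluded += 1
        else:
            c1.inquiry += 1
            inquiry_items.append(ind)
    ledger.counts[1] = c1

    # ---- inquiry resolution -------------------------------------------
    re_entered: list[str] = []
    for ind in inquiry_items:
        if ind not in inquiry_votes:
            raise ValueError(f"no inquiry votes for inquiry item {ind!r}")
        res = resolve_inquiry(*inquiry_votes[ind], indicator_id=ind)
        ledger.resolutions[ind] = res
        ledger.note(ind, f"inquiry:{res.agreed_exclusion_rate}%:{res.outcome}")
        if res.outcome == "re_entered":
            re_entered.append(ind)

    # ---- round 2 -------------------------------------------------------
    evaluated2 = advancing + re_entered
    missing = [ind for ind in evaluated2 if ind not in stats_round2]
    if missing:
        raise ValueError(f"round-2 stats missing for advancing items: {missing}")
    pool2_all = {ind: stats_round2[ind] for ind in evaluated2}

    decisions2: dict[str, ScreeningDecision] = {}
    for key, members in groups(evaluated2).items():
        pool = {ind: pool2_all[ind] for ind in members}
        thr2 = (critical_values(pool)
                if round2_policy == POLICY_THRESHOLD_AND_CRITICAL else None)
        if thr2 is not None:
            ledger.thresholds[f"round2/{key}"] = thr2
        decisions2.update(classify_round2(pool, thr2, round2_policy))
    ledger.decisions[2] = decisions2

    c2 = RoundCounts(evaluated=len(evaluated2), re_entered=len(re_entered))
    for ind in evaluated2:
        d = decisions2[ind]
        ledger.note(ind, f"round2:{d.status}")
        if d.status == RETAINED:
            c2.retained += 1
            ledger.final_indicators.append(ind)
        else:
            c2.excluded += 1
    ledger.counts[2] = c2
    return ledger


def run_two_round_screening(
    ratings: pd.DataFrame,
    inquiry_votes: Mapping[str, tuple[int, int]] | pd.DataFrame,
    *,
    level_of: Mapping[str, int] | None = None,
    round2_policy: str = POLICY_THRESHOLD_AND_CRITICAL,
    manual_edits: Mapping | None = None,
) -> ScreeningLedger:
    """Two-round workflow straight from rating records.

    ``ratings`` holds both rounds (columns ``round, expert_id,
    indicator_id, score``).  ``inquiry_votes`` is either a mapping
    ``indicator_id -> (votes_exclude, votes_total)`` or a votes table with
    columns ``indicator_id, expert_id, vote`` (vote ∈ {exclude, keep}).
    ``manual_edits`` (optional) is an explicit post-screening edit record
    ``{"remove": [...ids], "note": str}`` applied to the final list and
    logged — it models editorial consolidation, which is never automated.
    """
    if isinstance(inquiry_votes, pd.DataFrame):
        votes_map: dict[str, tuple[int, int]] = {}
        for ind, grp in inquiry_votes.groupby("indicator_id", sort=False):
            n_excl = int((grp["vote"] == "exclude").sum())
            votes_map[str(ind)] = (n_excl, len(grp))
    else:
        votes_map = dict(inquiry_votes)

    stats1 = stats_by_indicator(ratings, round_no=1)
    stats2 = stats_by_indicator(ratings, round_no=2)
    ledger = screen_from_stats(
        stats1, stats2, votes_map,
        level_of=level_of, round2_policy=round2_policy,
    )
    if manual_edits:
        removed = [i for i in manual_edits.get("remove", [])
                   if i in ledger.final_indicators]
        ledger.final_indicators = [
            i for i in ledger.final_indicators if i not in removed
        ]
        for ind in removed:
            ledger.note(ind, "manual-edit:removed")
        ledger.manual_edits = dict(manual_edits)
    return ledger
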