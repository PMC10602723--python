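"""Assemble stage outputs into a single evaluation report.

The report is a faithful collation: every number is taken verbatim from a
stage output (panel-quality statistics, screening ledger, weight table,
AHP consistency results) — nothing is recomputed at render time, so the
report can be audited against the stage artifacts line by line.
Weights are displayed to 4 decimals and percentages to the precision the
stages computed them at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

from ._util import round_half_away

STAGES = ("panel_quality", "screening", "weights", "consistency")


@dataclass
class EvaluationReport:
    """Collated pipeline outputs, renderable as JSON or plain text."""

    panel_quality: Any
    screening: Any
    weights: Any
    consistency: Any

    def to_json_dict(self) -> dict:
        return {
            "panel_quality": self.panel_quality,
            "screening": self.screening,
            "weights": self.weights,
            "consistency": self.consistency,
        }

    def to_text(self) -> str:
        lines: list[str] = ["Evaluation report", "================="]

        lines.append("")
        lines.append("Panel quality")
        lines.append("-------------")
        pq = self.panel_quality
        if not pq:
            lines.append("no panel statistics recorded")
        else:
            for rnd, rate in sorted(pq.get("response_rates", {}).items()):
                lines.append(f"round {rnd} response rate: {rate}%")
            if "mean_cr" in pq:
                lines.append(f"mean authority coefficient Cr: {pq['mean_cr']:.3f}")
            for key, c in sorted(pq.get("concordance", {}).items()):
                lines.append(
                    f"Kendall W [{key}]: W={c['w']:.3f} chi2={c['chi2']:.3f} "
                    f"df={c['df']} p={c['p']:.4g}"
                )

        lines.append("")
        lines.append("Screening")
        lines.append("---------")
        if not self.screening:
            lines.append("no screening performed")
        else:
            lines.append(self.screening["flow_summary"])

        lines.append("")
        lines.append("Weights")
        lines.append("-------")
        if not self.weights:
            lines.append("no weights computed")
        else:
            lines.append("id\tlevel\tlocal\tcombination\tlabel")
            for row in self.weights["rows"]:
                lines.append(
                    f"{row['id']}\t{row['level']}"
                    f"\t{round_half_away(row['local_weight'], 4):.4f}"
                    f"\t{round_half_away(row['combination_weight'], 4):.4f}"
                    f"\t{row['label']}"
                )

        lines.append("")
        lines.append("Judgment-matrix consistency")
        lines.append("---------------------------")
        if not self.consistency:
            lines.append("no judgment matrices evaluated")
        else:
            for key, res in sorted(self.consistency.items()):
                verdict = "consistent" if res["consistent"] else "INCONSISTENT"
                lines.append(
                    f"{key}: lambda_max={res['lambda_max']:.4f} "
                    f"CI={res['CI']:.4f} RI={res['RI']:.2f} "
                    f"CR={res['CR']:.4f} -> {verdict}"
                )
        lines.append("")
        return "\n".join(lines)


def render_report(stage_outputs: Mapping[str, Any]) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from a stage-output mapping.

    ``stage_outputs`` must contain every key in :data:`STAGES`
    (``panel_quality``, ``screening``, ``weights``, ``consistency``); a
    stage that was not run is passed explicitly as ``None`` and rendered
    as such, while an absent key raises an error naming the stage.
    """
    missing = [s for s in STAGES if s not in stage_outputs]
    if missing:
        raise KeyError(f"missing stage output(s): {', '.join(missing)}")
    return EvaluationReport(
        panel_quality=stage_outputs["panel_quality"],
        screening=stage_outputs["screening"],
        weights=stage_outputs["weights"],
        consistency=stage_outputs["consistency"],
    )


def weight_table_payload(table) -> dict:
    """Stage payload for the weights section from a leaf_weight_table frame."""
    return {"rows": table.to_dict(orient="records")}
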