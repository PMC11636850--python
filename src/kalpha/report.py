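"""Interpretation bands and the assembled report.

Krippendorff's reporting conventions band the coefficient as:
satisfactory agreement at alpha >= 0.80, tentative conclusions at
0.67 <= alpha < 0.80, poor agreement below 0.67, with exact-value
annotations for perfect agreement (alpha = 1), chance-level agreement
(alpha = 0) and systematic disagreement (alpha < 0).  Banding is done
on the unrounded coefficient with half-open intervals so every value in
[-1, 1] maps to exactly one label.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

from .bootstrap import ConfidenceInterval
from .core import AlphaResult
from .io import DataSummary

BAND_PERFECT = "perfect"
BAND_SATISFACTORY = "satisfactory"
BAND_TENTATIVE = "tentative"
BAND_POOR = "poor"
BAND_CHANCE = "chance"
BAND_SYSTEMATIC = "systematic-disagreement"


def interpret_alpha(alpha: float) -> str:
    """Map an alpha value to its conventional interpretation band."""
    if alpha > 1.0:
        raise ValueError(f"alpha cannot exceed 1, got {alpha}")
    if alpha == 1.0:
        return BAND_PERFECT
    if alpha >= 0.80:
        return BAND_SATISFACTORY
    if alpha >= 0.67:
        return BAND_TENTATIVE
    if alpha == 0.0:
        return BAND_CHANCE
    if alpha < 0.0:
        return BAND_SYSTEMATIC
    return BAND_POOR


@dataclass(frozen=True)
class AlphaReport:
    """Everything the result display shows, in one structure."""

    summary: DataSummary
    result: AlphaResult
    ci: Optional[ConfidenceInterval]
    band: str

    @classmethod
    def from_result(
        cls, result: AlphaResult, ci: Optional[ConfidenceInterval] = None
    ) -> "AlphaReport":
        return cls(
            summary=result.summary,
            result=result,
            ci=ci,
            band=interpret_alpha(result.alpha),
        )

    def to_dict(self) -> dict:
        """Machine-readable form; every number equals the report field."""
        doc = {
            "summary": asdict(self.summary),
            "alpha": self.result.alpha,
            "metric": self.result.metric,
            "do": self.result.do_term,
            "de": self.result.de_term,
            "band": self.band,
        }
        if self.ci is not None:
            doc["ci"] = {
                "level": self.ci.level,
                "n_boot": self.ci.n_boot,
                "lower": self.ci.lower,
                "upper": self.ci.upper,
                "seed": self.ci.seed,
                "n_degenerate": self.ci.n_degenerate,
            }
        return doc


def render_report(report: AlphaReport, verbose: bool = False) -> str:
    """Plain-text rendering: data summary, then the coefficient.

    Alpha is shown to exactly three decimal places with the metric named
    in brackets; full precision stays in :class:`AlphaResult`.
    """
    s = report.summary
    lines = [
        "Data summary",
        f"  Raters:            {s.n_raters}",
        f"  Items:             {s.n_items}",
        f"  Missing values:    {s.n_missing}",
        f"  Min / max rate:    {_num(s.min_rate)} / {_num(s.max_rate)}",
        f"  Valid items:       {s.n_valid_items}",
        f"  Pairable ratings:  {s.n_pairable}",
        "",
        f"Krippendorff's alpha: {report.result.alpha:.3f} ({report.result.metric})",
        f"  Interpretation:    {report.band}",
    ]
    if report.ci is not None:
        ci = report.ci
        lines += [
            f"  {ci.level:.0%} CI:            [{ci.lower:.3f}, {ci.upper:.3f}] "
            f"({ci.n_boot} bootstrap iterations, seed {ci.seed})",
        ]
        if ci.n_degenerate:
            lines.append(
                f"  Degenerate replicates scored as 1: {ci.n_degenerate}"
            )
    if verbose:
        rbu = report.result.rates_by_units
        lines += ["", "Rates-by-units matrix (rows = units, columns = categories)"]
        header = "  unit | " + " ".join(f"{_num(v):>5}" for v in rbu.categories.values)
        lines.append(header + " | n_u")
        for u, row in enumerate(rbu.n_uc):
            cells = " ".join(f"{int(c):>5}" for c in row)
            lines.append(f"  {u + 1:>4} | {cells} | {int(rbu.n_u[u])}")
        marg = " ".join(f"{int(c):>5}" for c in rbu.n_c)
        lines.append(f"   n_c | {marg} | {rbu.n_total}")
        lines += [
            "",
            f"Observed disagreement (Do): {report.result.do_term:.6f}",
            f"Expected disagreement (De): {report.result.de_term:.6f}",
        ]
    return "\n".join(lines)


def _num(v: float) -> str:
    if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
        return str(int(v))
    return f"{v:g}"
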