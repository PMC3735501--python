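"""Posterior reporting: condition estimates, credible intervals, contrasts.

Each condition's expected log response (its cell-mean coefficient) is
exponentiated draw by draw; the point estimate is the posterior median and
the 95% Bayesian credible interval (BCI) the 2.5%/97.5% percentiles, both on
the response scale.  Because percentiles commute with monotone maps, the
bounds equal the exponential of the log-scale percentile bounds exactly.

A contrast between two conditions is the per-draw ratio of their exponentiated
cell means, summarised as a signed integer percent change with the 95% BCI of
the ratio; the difference is called significant when that interval excludes 1
(equivalently, when the log-ratio interval excludes 0).  No multiplicity
adjustment is applied beyond this interval-exclusion rule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .mcmc import ConvergenceReport, MCMCConfig, PosteriorDraws

__all__ = [
    "ConditionSummary",
    "Contrast",
    "summarize_condition",
    "percent_change",
    "compare",
    "viability_relative",
    "default_contrasts",
    "build_report",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Point estimate and 95% BCI for one condition, on the response scale."""

    condition: str
    analyte: str
    point_estimate: float
    lower: float
    upper: float
    significant_increase: bool | None = None  # set for blank-relative summaries

    def __post_init__(self) -> None:
        if not (self.lower <= self.point_estimate <= self.upper):
            raise ValueError(
                f"{self.condition}: bounds must bracket the point estimate"
            )
        if self.lower <= 0:
            raise ValueError(f"{self.condition}: response-scale bounds must be > 0")


@dataclass(frozen=True)
class Contrast:
    """A condition-pair comparison: percent change, ratio BCI, significance."""

    numerator: str
    denominator: str
    analyte: str
    percent_change: int
    ratio_bci: tuple[float, float]
    significant: bool

    def __post_init__(self) -> None:
        low, high = self.ratio_bci
        excludes_one = not (low <= 1.0 <= high)
        if self.significant != excludes_one:
            raise ValueError(
                f"{self.numerator} vs {self.denominator}: significance flag "
                "inconsistent with the ratio interval"
            )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_change(a: float, b: float) -> int:
    """Signed integer percent change of `a` relative to reference `b`.

    round-to-nearest of 100 * (a/b - 1); negative values are reductions.
    """
    if a <= 0 or b <= 0:
        raise ValueError("percent change needs positive point estimates")
    return _round_half_away(100.0 * (a / b - 1.0))


def summarize_condition(
    draws: PosteriorDraws,
    condition: str,
    analyte: str | None = None,
    ndigits: int = 1,
) -> ConditionSummary:
    """Median and 2.5/97.5 percentiles of one condition's response-scale mean."""
    if analyte is not None and analyte != draws.analyte:
        raise ValueError(
            f"draws are for {draws.analyte!r}, not {analyte!r}"
        )
    try:
        log_draws = draws.beta_draws(condition)
    except KeyError:
        raise KeyError(
            f"condition {condition!r} has no cell-mean parameter in these draws"
        ) from None
    # percentiles on the log scale, exponentiated: interpolation then commutes
    # exactly with the monotone back-transformation
    point, lo, hi = np.exp(np.percentile(log_draws, [50.0, 2.5, 97.5]))
    return ConditionSummary(
        condition=condition,
        analyte=draws.analyte,
        point_estimate=float(round(point, ndigits)),
        lower=float(round(lo, ndigits)),
        upper=float(round(hi, ndigits)),
    )


def compare(
    draws: PosteriorDraws,
    cond_a: str,
    cond_b: str,
    analyte: str | None = None,
) -> Contrast:
    """Contrast condition A against reference B via the per-draw ratio."""
    if cond_a == cond_b:
        raise ValueError("cannot contrast a condition against itself")
    if analyte is not None and analyte != draws.analyte:
        raise ValueError(f"draws are for {draws.analyte!r}, not {analyte!r}")
    log_ratio = draws.beta_draws(cond_a) - draws.beta_draws(cond_b)
    lo, hi = np.exp(np.percentile(log_ratio, [2.5, 97.5]))
    summary_a = summarize_condition(draws, cond_a)
    summary_b = summarize_condition(draws, cond_b)
    return Contrast(
        numerator=cond_a,
        denominator=cond_b,
        analyte=draws.analyte,
        percent_change=percent_change(summary_a.point_estimate, summary_b.point_estimate),
        ratio_bci=(float(lo), float(hi)),
        significant=not (lo <= 1.0 <= hi),
    )


def viability_relative(
    draws: PosteriorDraws, condition: str, ndigits: int = 2
) -> ConditionSummary:
    """A condition's viability relative to blank controls, with 95% BCI.

    The increase is flagged significant when the interval's lower bound
    exceeds 1.
    """
    if "blank" not in draws.condition_labels:
        raise ValueError("viability model draws must include the blank condition")
    log_ratio = draws.beta_draws(condition) - draws.beta_draws("blank")
    point, lo, hi = np.exp(np.percentile(log_ratio, [50.0, 2.5, 97.5]))
    point, lo, hi = (float(round(point, ndigits)), float(round(lo, ndigits)),
                     float(round(hi, ndigits)))
    return ConditionSummary(
        condition=condition,
        analyte=draws.analyte,
        point_estimate=point,
        lower=lo,
        upper=hi,
        significant_increase=lo > 1.0,
    )


# ---------------------------------------------------------------------------
# report assembly

_LABEL_RE = re.compile(r"^(LPS \+ )?(.+) (\d\.\d)%$")


def _parse_label(label: str) -> tuple[bool, str, float] | None:
    """(has LPS, fraction, concentration %) for dosed conditions, else None."""
    m = _LABEL_RE.match(label)
    if m is None:
        return None
    return m.group(1) is not None, m.group(2), float(m.group(3))


def reference_condition(label: str) -> str | None:
    """The Table-style reference: LPS-alone for challenged conditions, blank
    for unchallenged ones, nothing for the references themselves."""
    if label in ("blank", "LPS"):
        return None
    parsed = _parse_label(label)
    if parsed is None:
        return None
    return "LPS" if parsed[0] else "blank"


def next_lower_dose(label: str, available: list[str]) -> str | None:
    """The same fraction one concentration step down, if present."""
    parsed = _parse_label(label)
    if parsed is None:
        return None
    lps, fraction, conc = parsed
    lower = {2.0: 1.0, 1.0: 0.5}.get(conc)
    if lower is None:
        return None
    candidate = f"{'LPS + ' if lps else ''}{fraction} {lower:.1f}%"
    return candidate if candidate in available else None


def matched_sugar_control(label: str, available: list[str]) -> str | None:
    """The glucose/lactose control at the same concentration and challenge."""
    parsed = _parse_label(label)
    if parsed is None or parsed[1] == "glucose/lactose":
        return None
    lps, _, conc = parsed
    candidate = f"{'LPS + ' if lps else ''}glucose/lactose {conc:.1f}%"
    return candidate if candidate in available else None


def default_contrasts(draws: PosteriorDraws) -> list[Contrast]:
    """The conventional contrast set: each dosed condition against its
    reference (blank or LPS-alone), against the next-lower dose of the same
    fraction, and against its matched sugar control; plus LPS-alone vs blank
    when both are present."""
    labels = draws.condition_labels
    contrasts: list[Contrast] = []
    seen: set[tuple[str, str]] = set()

    def add(a: str, b: str | None) -> None:
        if b is None or (a, b) in seen:
            return
        seen.add((a, b))
        contrasts.append(compare(draws, a, b))

    if "LPS" in labels and "blank" in labels:
        add("LPS", "blank")
    for label in labels:
        add(label, reference_condition(label))
        add(label, next_lower_dose(label, labels))
        add(label, matched_sugar_control(label, labels))
    return contrasts


def build_report(
    summaries: list[ConditionSummary],
    contrasts: list[Contrast],
    convergence: ConvergenceReport | None,
    config: MCMCConfig | None = None,
) -> dict:
    """Assemble a machine-readable report with table-style significance marks.

    A condition is marked ``*`` when significantly different from its
    reference (blank or LPS-alone) and ``#`` when significantly different
    from the next-lower concentration of the same fraction.  Refuses to build
    without a convergence report.
    """
    if convergence is None:
        raise ValueError(
            "no convergence report: run check_convergence on the draws first"
        )
    sig = {(c.numerator, c.denominator): c.significant for c in contrasts}
    labels = [s.condition for s in summaries]
    rows = []
    for s in summaries:
        marks = ""
        ref = reference_condition(s.condition)
        if ref is not None and sig.get((s.condition, ref)):
            marks += "*"
        lower_dose = next_lower_dose(s.condition, labels)
        if lower_dose is not None and sig.get((s.condition, lower_dose)):
            marks += "#"
        row = {
            "condition": s.condition,
            "analyte": s.analyte,
            "point_estimate": s.point_estimate,
            "lower": s.lower,
            "upper": s.upper,
            "marks": marks,
        }
        if s.significant_increase is not None:
            row["significant_increase"] = s.significant_increase
        rows.append(row)
    report = {
        "convergence": {
            "passed": convergence.passed,
            "threshold": convergence.threshold,
            "psrf": dict(convergence.psrf),
        },
        "summaries": rows,
        "contrasts": [
            {
                "numerator": c.numerator,
                "denominator": c.denominator,
                "analyte": c.analyte,
                "percent_change": c.percent_change,
                "ratio_bci": list(c.ratio_bci),
                "significant": c.significant,
            }
            for c in contrasts
        ],
    }
    if config is not None:
        report["mcmc_config"] = {
            "n_chains": config.n_chains,
            "n_iterations": config.n_iterations,
            "thin": config.thin,
            "burn_in_fraction": config.burn_in_fraction,
            "seed": config.seed,
        }
    return report
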