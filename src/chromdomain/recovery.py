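"""Purification-recovery accounting and related normalizations.

Implements the bookkeeping used to describe a chromatin-domain affinity
purification: recovery of the domain in an elution as a percentage of the
cellular extract, fold-excess of the domain over the unrelated single-copy
PDC1 reference locus, recombination efficiency of ring excision, an
advisory mass-balance check over the extraction fractions, normalization
of restriction-accessibility titrations, and ChIP percent-of-input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import AnalysisError
from .io import FractionAmounts

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class RecoveryReport:
    domain_name: str
    recovery_pct: dict[str, int] = field(default_factory=dict)
    recovery_pct_unrounded: dict[str, float] = field(default_factory=dict)
    fold_excess_by_fraction: dict[str, float] = field(default_factory=dict)
    efficiency_pct: float | None = None
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class AccessibilitySeries:
    """A restriction-enzyme titration: cut fraction per enzyme amount,
    normalized to the highest-amount point (= 100%)."""

    enzyme: str
    points: list[tuple[float, float]]  # (enzyme_amount, cut_fraction)
    normalized_pct: list[float] = field(default_factory=list)


def recovery_percent(amounts: FractionAmounts,
                     elution_label: str = "E_igg") -> tuple[int, float]:
    """Recovery = elution amount / cellular-extract amount.

    Returns (integer percent, round-half-up, as conventionally reported;
    unrounded percent).
    """
    ce = amounts.amounts.get("CE", 0.0)
    if ce <= 0:
        raise AnalysisError(f"{amounts.domain_name}: CE amount is zero; "
                            "recovery undefined")
    if elution_label not in amounts.amounts:
        raise AnalysisError(f"{amounts.domain_name}: no fraction "
                            f"{elution_label!r}")
    pct = 100.0 * amounts.amounts[elution_label] / ce
    return _round_half_up(pct), pct


def fold_excess(domain_amount: float, reference_amount: float) -> float:
    """Molar excess of the purified domain over a reference locus."""
    if reference_amount <= 0:
        raise AnalysisError("reference amount must be > 0")
    return domain_amount / reference_amount


def recombination_efficiency(recombined: float, nonrecombined: float,
                             mode: str = "fraction_of_total") -> float:
    """Percentage of loci excised as rings.

    ``fraction_of_total`` (default): 100 * rec / (rec + nonrec), bounded by
    100.  ``literal``: 100 * rec / nonrec, the uncapped quotient of
    recombined over non-recombined.
    """
    if mode == "fraction_of_total":
        total = recombined + nonrecombined
        if total <= 0:
            raise AnalysisError("recombined + nonrecombined must be > 0")
        return 100.0 * recombined / total
    if mode == "literal":
        if nonrecombined <= 0:
            raise AnalysisError("nonrecombined must be > 0 in literal mode")
        return 100.0 * recombined / nonrecombined
    raise ValueError(f"unknown mode {mode!r}")


def mass_balance_qc(amounts: FractionAmounts,
                    tolerance: float = 0.25) -> list[str]:
    """Advisory check: pellet + supernatant should roughly equal the
    cellular extract.  Never fatal — blot quantification is noisy."""
    flags = []
    a = amounts.amounts
    if all(k in a for k in ("CE", "P", "SUP")) and a["CE"] > 0:
        rel = abs((a["P"] + a["SUP"]) - a["CE"]) / a["CE"]
        if rel > tolerance:
            flags.append(
                f"mass_balance: |P+SUP - CE|/CE = {rel:.2f} > {tolerance}")
    return flags


def normalized_cut_percent(series: AccessibilitySeries) -> AccessibilitySeries:
    """Express each cut fraction as a percentage of the cut fraction at the
    highest enzyme amount (which becomes 100%)."""
    if not series.points:
        raise AnalysisError("empty accessibility series")
    max_amount = max(a for a, _ in series.points)
    at_max = next(c for a, c in series.points if a == max_amount)
    if at_max <= 0:
        raise AnalysisError("cut fraction at the highest enzyme amount is 0")
    series.normalized_pct = [100.0 * c / at_max for _, c in series.points]
    return series


def percent_of_input(ip_signal: float, input_signal: float,
                     input_dilution_factor: float = 1.0) -> float:
    """ChIP retention as a percentage of total input DNA."""
    if input_signal <= 0:
        raise AnalysisError("input signal must be > 0")
    return 100.0 * ip_signal / (input_signal * input_dilution_factor)


def report(amounts: FractionAmounts,
           efficiency_mode: str = "fraction_of_total",
           qc_tolerance: float = 0.25) -> RecoveryReport:
    """Build a full recovery report for one domain."""
    rep = RecoveryReport(domain_name=amounts.domain_name)
    for label, v in amounts.amounts.items():
        if label.startswith("E_"):
            pct, raw = recovery_percent(amounts, label)
            rep.recovery_pct[label] = pct
            rep.recovery_pct_unrounded[label] = raw
    for label, ref in amounts.pdc1_amounts.items():
        if label in amounts.amounts:
            rep.fold_excess_by_fraction[label] = fold_excess(
                amounts.amounts[label], ref)
    if amounts.recombined is not None and amounts.nonrecombined is not None:
        rep.efficiency_pct = recombination_efficiency(
            amounts.recombined, amounts.nonrecombined, efficiency_mode)
        if efficiency_mode == "literal":
            rep.qc_flags.append("efficiency computed in literal "
                                "(rec/nonrec) mode; may exceed 100%")
    rep.qc_flags.extend(mass_balance_qc(amounts, qc_tolerance))
    logger.info("recovery report %s: %s", amounts.domain_name,
                rep.recovery_pct)
    return rep
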