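"""Comparative iTRAQ enrichment analysis for chromatin-domain purifications.

A domain purification and a mock (control) purification are labeled with two
different iTRAQ reporters; per-peptide reporter ratios (domain / control)
quantify co-purification.  Because abundant housekeeping and ribosomal
proteins contaminate both purifications equally, the per-replicate
background factor — the mean raw ratio over those proteins — is divided out
of every protein's ratio.  Corrected ratios are then averaged over the
biological replicates in which a protein was identified, and enrichment is
called from the averaged ratio together with the summed peptide count:

* STRICT     avg ratio >= 1.5 and >= 2 peptides (the headline criterion)
* RELAXED_A  avg ratio >= 1.5 and >= 1 peptide
* RELAXED_B  avg ratio >  1.0 and >= 2 peptides
* NONE       otherwise

A multiprotein complex is depicted when at least half of its annotated
subunits reach RELAXED_B or better; complex-level averages are taken over
the identified subunits only.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .io import AnnotationTable, QuantTable

logger = logging.getLogger(__name__)


class Tier(enum.IntEnum):
    """Enrichment call, ordered so that higher is stronger."""

    NONE = 0
    RELAXED_B = 1
    RELAXED_A = 2
    STRICT = 3


@dataclass(frozen=True)
class Thresholds:
    ratio_strict: float = 1.5
    peptides_strict: int = 2
    peptides_relaxed: int = 1
    ratio_relaxed: float = 1.0
    qualifying_tier: Tier = Tier.RELAXED_B
    complex_coverage: float = 0.5


@dataclass
class ProteinRatio:
    protein_id: str
    replicate_id: str
    raw_ratio: float
    n_peptides: int

    def __post_init__(self) -> None:
        if self.raw_ratio <= 0:
            raise AnalysisError(
                f"{self.protein_id}/{self.replicate_id}: ratio must be > 0")
        if self.n_peptides < 1:
            raise AnalysisError("n_peptides must be >= 1")


@dataclass
class EnrichmentSummary:
    protein_id: str
    avg_ratio: float
    total_peptides: int
    tier: Tier = Tier.NONE


@dataclass
class ComplexSummary:
    complex_name: str
    n_annotated: int
    n_passing: int
    coverage: float
    avg_ratio: float | None
    avg_peptides: float | None
    depicted: bool


def protein_ratio_from_peptides(
    quant: QuantTable,
    domain_channel: str,
    control_channel: str,
    aggregation: str = "median",
) -> list[ProteinRatio]:
    """Aggregate peptide-level reporter ratios to one ratio per protein
    and replicate.

    The per-peptide ratio is domain intensity / control intensity; peptides
    with zero control intensity are dropped.  The protein ratio is the
    median (default) or mean of its peptide ratios.
    """
    if aggregation not in ("median", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    for ch in (domain_channel, control_channel):
        if ch not in quant.channels:
            raise AnalysisError(f"channel {ch!r} not present in quant table")
    agg = np.median if aggregation == "median" else np.mean
    out: list[ProteinRatio] = []
    grouped = quant.data.groupby(["replicate_id", "protein_id"], sort=True)
    for (rep, pid), grp in grouped:
        dom = grp[domain_channel].to_numpy(float)
        ctl = grp[control_channel].to_numpy(float)
        ok = ctl > 0
        if not ok.any():
            logger.warning("protein %s in replicate %s: all control "
                           "intensities zero; excluded", pid, rep)
            continue
        ratios = dom[ok] / ctl[ok]
        out.append(ProteinRatio(str(pid), str(rep),
                                float(agg(ratios)), int(ok.sum())))
    logger.info("protein_ratio_from_peptides: %d (protein, replicate) ratios",
                len(out))
    return out


def background_factor(
    ratios: list[ProteinRatio],
    annotation: AnnotationTable,
    replicate_id: str,
) -> float:
    """Mean raw ratio over housekeeping/ribosomal proteins in one replicate."""
    vals = [r.raw_ratio for r in ratios
            if r.replicate_id == replicate_id
            and annotation.is_background(r.protein_id)]
    if not vals:
        raise AnalysisError(
            f"replicate {replicate_id!r}: no background (housekeeping or "
            "ribosomal) protein identified; provide an annotation table "
            "covering the background set")
    return float(np.mean(vals))


def correct_and_summarize(
    ratios: list[ProteinRatio],
    annotation: AnnotationTable,
    average: str = "arithmetic",
) -> list[EnrichmentSummary]:
    """Background-correct per-replicate ratios and average over replicates.

    Each raw ratio is divided by its replicate's background factor; the
    protein's summary ratio is the arithmetic (default) or geometric mean
    over the replicates in which it was identified, and total_peptides sums
    over the same replicates.  Tier is left unset (NONE).
    """
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown average {average!r}")
    replicates = sorted({r.replicate_id for r in ratios})
    factors = {rep: background_factor(ratios, annotation, rep)
               for rep in replicates}
    logger.info("correct_and_summarize: background factors %s",
                {k: round(v, 4) for k, v in factors.items()})
    per_protein: dict[str, list[ProteinRatio]] = {}
    for r in ratios:
        per_protein.setdefault(r.protein_id, []).append(r)
    out = []
    for pid in sorted(per_protein):
        rs = per_protein[pid]
        corrected = np.array([r.raw_ratio / factors[r.replicate_id]
                              for r in rs])
        if average == "arithmetic":
            avg = float(np.mean(corrected))
        else:
            avg = float(np.exp(np.mean(np.log(corrected))))
        out.append(EnrichmentSummary(
            protein_id=pid,
            avg_ratio=avg,
            total_peptides=int(sum(r.n_peptides for r in rs)),
        ))
    return out


def call_enrichment_tier(
    summary: EnrichmentSummary,
    thresholds: Thresholds = Thresholds(),
) -> Tier:
    """Tier a protein from its averaged corrected ratio and peptide count.

    Boundary conventions: >= for the 1.5 ratio threshold, strictly > for
    the 1.0 relaxed threshold.
    """
    r, n = summary.avg_ratio, summary.total_peptides
    t = thresholds
    if r >= t.ratio_strict and n >= t.peptides_strict:
        return Tier.STRICT
    if r >= t.ratio_strict and n >= t.peptides_relaxed:
        return Tier.RELAXED_A
    if r > t.ratio_relaxed and n >= t.peptides_strict:
        return Tier.RELAXED_B
    return Tier.NONE


def call_all_tiers(
    summaries: list[EnrichmentSummary],
    thresholds: Thresholds = Thresholds(),
) -> list[EnrichmentSummary]:
    for s in summaries:
        s.tier = call_enrichment_tier(s, thresholds)
    return summaries


def summarize_complex(
    complex_name: str,
    members: set[str],
    summaries: list[EnrichmentSummary],
    thresholds: Thresholds = Thresholds(),
) -> ComplexSummary:
    """Coverage and averages for one annotated multiprotein complex.

    Coverage counts annotated members whose tier reaches the qualifying
    tier; ratio/peptide averages run over identified members only.  The
    complex is depicted when coverage >= the coverage threshold (default
    one half).
    """
    if len(members) < 2:
        raise AnalysisError(f"complex {complex_name!r} has fewer than 2 "
                            "annotated members")
    by_id = {s.protein_id: s for s in summaries}
    identified = [by_id[m] for m in sorted(members) if m in by_id]
    n_passing = sum(1 for s in identified
                    if s.tier >= thresholds.qualifying_tier)
    coverage = n_passing / len(members)
    if identified:
        avg_ratio = float(np.mean([s.avg_ratio for s in identified]))
        avg_peptides = float(np.mean([s.total_peptides for s in identified]))
    else:
        avg_ratio = avg_peptides = None
        logger.warning("complex %s: no identified member", complex_name)
    return ComplexSummary(
        complex_name=complex_name,
        n_annotated=len(members),
        n_passing=n_passing,
        coverage=coverage,
        avg_ratio=avg_ratio,
        avg_peptides=avg_peptides,
        depicted=bool(identified) and coverage >= thresholds.complex_coverage,
    )


def functional_composition(
    summaries: list[EnrichmentSummary],
    annotation: AnnotationTable,
) -> dict[str, float]:
    """Fraction of identified proteins per functional class (sums to 1)."""
    if not summaries:
        return {}
    counts: dict[str, int] = {}
    for s in summaries:
        cls = annotation.functional_class(s.protein_id)
        counts[cls] = counts.get(cls, 0) + 1
    total = len(summaries)
    return {cls: n / total for cls, n in sorted(counts.items())}


def run_enrichment(
    quant: QuantTable,
    annotation: AnnotationTable,
    domain_channel: str,
    control_channel: str,
    thresholds: Thresholds = Thresholds(),
    aggregation: str = "median",
    average: str = "arithmetic",
) -> tuple[list[EnrichmentSummary], list[ComplexSummary], dict[str, float]]:
    """Full pipeline: ratios -> correction -> tiers -> complexes -> classes."""
    ratios = protein_ratio_from_peptides(quant, domain_channel,
                                         control_channel, aggregation)
    summaries = call_all_tiers(
        correct_and_summarize(ratios, annotation, average), thresholds)
    complexes = [
        summarize_complex(name, members, summaries, thresholds)
        for name, members in sorted(annotation.complex_members().items())
        if len(members) >= 2
    ]
    composition = functional_composition(summaries, annotation)
    return summaries, complexes, composition
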