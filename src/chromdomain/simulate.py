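"""Synthetic-data generators with known ground truth for every analysis
stage.

Each generator emulates the statistical structure its analysis assumes:

* ``gen_itraq`` — peptide-level reporter intensities for a population of
  background proteins (true corrected ratio 1) plus spiked enriched
  proteins, under multiplicative log-normal ratio noise and a per-replicate
  global bias factor that the background correction must remove.
* ``gen_maldi`` — centroided peak lists for one derivatized histone
  peptide, with peaks at theoretical m/z under a linear calibration drift
  and log-normal intensity noise, plus the unmodified anchor peptides.
* ``gen_molecules`` — psoralen-EM molecule populations drawn from a
  catalog of nucleosome configurations: each nucleosome protects a 147-bp
  footprint, footprints separated by linkers shorter than a merge
  threshold coalesce into one bubble, and bubble boundaries carry Gaussian
  sizing noise.
* ``gen_amounts`` — fraction-amount tables with a known true recovery,
  extraction loss, fold-excess and recombination efficiency.

A single root seed expands into fixed per-generator substreams, so outputs
are bit-for-bit reproducible and adding a generator never perturbs the
others.  With all noise terms zero every analysis stage returns the ground
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .histone_ptm import HistoneSequence, anchor_mz_for, enumerate_modforms
from .io import (AnnotationTable, FeatureMap, FractionAmounts, Molecule,
                 MoleculeTable, PeakList, QuantTable)

_SUBSTREAM = {"itraq": 0, "maldi": 1, "molecules": 2, "amounts": 3}


def _rng(seed: int, generator: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAM))
    return np.random.default_rng(children[_SUBSTREAM[generator]])


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      size: int | tuple = 1) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV; exactly 1
    when cv == 0."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def _lognormal_scalar(rng: np.random.Generator, cv: float) -> float:
    return float(_lognormal_factor(rng, cv, 1)[0])


@dataclass
class GroundTruth:
    """Simulation truth sufficient to score any stage's output."""

    kind: str
    records: dict[str, Any]

    def to_json(self) -> dict:
        return {"kind": self.kind, "records": self.records}


# ---------------------------------------------------------------------------
# iTRAQ


@dataclass
class ItraqSimConfig:
    seed: int = 0
    n_background: int = 200
    n_spiked: int = 20
    spiked_ratio: float = 3.0
    n_replicates: int = 3
    ratio_cv: float = 0.25
    peptide_lambda: float = 2.0
    base_intensity: float = 1e4
    intensity_cv: float = 0.5
    replicate_bias: tuple[float, ...] | None = None
    bias_sigma: float = 0.2
    domain_channel: str = "115"
    control_channel: str = "114"

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise AnalysisError("need at least one background protein; "
                                "background correction is undefined without")


def gen_itraq(config: ItraqSimConfig = ItraqSimConfig()
              ) -> tuple[QuantTable, AnnotationTable, GroundTruth]:
    """Simulate peptide-level reporter intensities over replicates."""
    rng = _rng(config.seed, "itraq")
    proteins = (
        [(f"BG{i:04d}", 1.0, False) for i in range(config.n_background)]
        + [(f"SPK{i:04d}", config.spiked_ratio, True)
           for i in range(config.n_spiked)]
    )
    if config.replicate_bias is not None:
        biases = np.asarray(config.replicate_bias, dtype=float)
        if len(biases) != config.n_replicates:
            raise AnalysisError("replicate_bias length must equal "
                                "n_replicates")
    else:
        biases = _lognormal_factor(rng, np.expm1(config.bias_sigma ** 2) ** 0.5
                                   if config.bias_sigma > 0 else 0.0,
                                   config.n_replicates)
    rows = []
    for r in range(config.n_replicates):
        rep = f"rep{r + 1}"
        g = biases[r]
        for pid, true_ratio, _ in proteins:
            n_pep = 1 + rng.poisson(config.peptide_lambda)
            ctl = config.base_intensity * _lognormal_factor(
                rng, config.intensity_cv, n_pep)
            noise = _lognormal_factor(rng, config.ratio_cv, n_pep)
            dom = ctl * true_ratio * g * noise
            for k in range(n_pep):
                rows.append({
                    "replicate_id": rep,
                    "protein_id": pid,
                    "peptide_seq": f"{pid}_PEP{k:02d}",
                    config.control_channel: ctl[k],
                    config.domain_channel: dom[k],
                })
    quant = QuantTable(pd.DataFrame(rows),
                       (config.control_channel, config.domain_channel))
    classes = {}
    for i, (pid, _, spiked) in enumerate(proteins):
        if spiked:
            classes[pid] = "chromatin-associated"
        else:
            classes[pid] = ("housekeeping" if i % 2 == 0
                            else "ribosomal protein")
    annot = AnnotationTable(classes)
    truth = GroundTruth("itraq", {
        "true_corrected_ratio": {p: r for p, r, _ in proteins},
        "enriched": {p: s for p, _, s in proteins},
        "replicate_bias": [float(b) for b in biases],
    })
    return quant, annot, truth


def score_itraq(truth: GroundTruth, summaries, tier_name: str = "STRICT"
                ) -> dict[str, float]:
    """Sensitivity/specificity of enrichment calls against simulation truth."""
    from .itraq import Tier

    threshold = Tier[tier_name]
    enriched = truth.records["enriched"]
    tp = fp = tn = fn = 0
    for s in summaries:
        called = s.tier >= threshold
        if enriched.get(s.protein_id, False):
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


# ---------------------------------------------------------------------------
# MALDI


@dataclass
class MaldiSimConfig:
    seed: int = 0
    n_spots: int = 3
    total_intensity: float = 1e5
    intensity_cv: float = 0.1
    drift_slope: float = 1.0
    drift_offset: float = 0.0
    anchor_intensity: float = 5e4
    n_background_peaks: int = 0
    background_intensity: float = 1e3
    window: tuple[float, float] = (700.0, 2000.0)


def gen_maldi(
    config: MaldiSimConfig,
    seq: HistoneSequence,
    peptide: tuple[int, int],
    true_proportions: dict[str, float],
    alphabet: tuple[str, ...] = ("prop", "ac"),
) -> tuple[list[PeakList], GroundTruth]:
    """Simulate centroided spot replicas for one histone peptide.

    ``true_proportions`` maps modform bin labels (as produced by
    ``enumerate_modforms``) to ground-truth proportions summing to 1.
    """
    if abs(sum(true_proportions.values()) - 1.0) > 1e-9:
        raise AnalysisError("true proportions must sum to 1")
    rng = _rng(config.seed, "maldi")
    modforms = enumerate_modforms(seq, peptide, alphabet)
    by_label = {f.label: f for f in modforms}
    unknown = set(true_proportions) - set(by_label)
    if unknown:
        raise AnalysisError(f"unknown modform labels {unknown}; available: "
                            f"{sorted(by_label)}")
    anchors = anchor_mz_for(seq)
    peaklists = []
    for spot in range(config.n_spots):
        mzs, intens = [], []
        for label, prop in true_proportions.items():
            if prop <= 0:
                continue
            mzs.append(config.drift_slope * by_label[label].mz_mh
                       + config.drift_offset)
            intens.append(config.total_intensity * prop
                          * _lognormal_scalar(rng, config.intensity_cv))
        for theo in anchors.values():
            mzs.append(config.drift_slope * theo + config.drift_offset)
            intens.append(config.anchor_intensity
                          * _lognormal_scalar(rng, config.intensity_cv))
        for _ in range(config.n_background_peaks):
            mzs.append(rng.uniform(*config.window))
            intens.append(config.background_intensity * rng.uniform(0.1, 1.0))
        order = np.argsort(mzs)
        peaklists.append(PeakList(
            spot_id=f"spot{spot + 1}",
            mz=np.asarray(mzs)[order],
            intensity=np.asarray(intens)[order],
            acquisition_window=config.window,
        ))
    truth = GroundTruth("maldi", {
        "peptide": list(peptide),
        "true_proportions": dict(true_proportions),
        "drift": [config.drift_slope, config.drift_offset],
    })
    return peaklists, truth


def score_maldi(truth: GroundTruth,
                proportions: dict[str, float] | None) -> float:
    """Mean absolute error of recovered vs true proportions."""
    if proportions is None:
        raise AnalysisError("peptide not detected")
    true = truth.records["true_proportions"]
    err = []
    for label, p in true.items():
        est = 0.0
        for out_label, v in proportions.items():
            # an ambiguity-group label contains its member labels
            if label == out_label or label in out_label.split("|"):
                est = v
                break
        err.append(abs(est - p))
    return float(np.mean(err))


# ---------------------------------------------------------------------------
# EM molecules


@dataclass
class MoleculeSimConfig:
    seed: int = 0
    n_molecules: int = 500
    footprint_bp: int = 147
    merge_threshold_bp: float = 30.0
    sizing_noise_sd_bp: float = 0.0
    unit: str = "bp"  # or "nm"
    bp_per_nm: float = 3.0


#: a catalog entry: (name, tuple of nucleosome start positions on the ring,
#: probability)
CatalogEntry = tuple[str, tuple[int, ...], float]


def occupancy_catalog(feature_map: FeatureMap, feature_name: str,
                      p_occupied: float,
                      flanking: tuple[int, ...] = ()) -> list[CatalogEntry]:
    """Two-state catalog: a nucleosome centered on the feature with
    probability ``p_occupied``, plus optional always-present flanking
    nucleosomes (given by their start positions)."""
    fs, fe = feature_map.features[feature_name]
    center = (fs + (fe - fs) // 2) % feature_map.ring_length
    occupied_start = (center - 73) % feature_map.ring_length
    return [
        ("occupied", tuple(flanking) + (occupied_start,), p_occupied),
        ("free", tuple(flanking), 1.0 - p_occupied),
    ]


def _merge_circular(intervals: list[tuple[float, float]], ring: float,
                    gap: float) -> list[tuple[float, float]]:
    """Merge footprints separated by linkers shorter than ``gap`` into one
    bubble, on the circle."""
    if not intervals:
        return []
    ivs = sorted((s % ring, (s % ring) + ln) for s, ln in
                 ((s, (e - s) % ring or (e - s)) for s, e in intervals))
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # wrap-around: gap between the last interval's end and the first's start
    if len(merged) > 1 and (merged[0][0] + ring) - merged[-1][1] < gap:
        first = merged.pop(0)
        merged[-1][1] = first[1] + ring
    return [(s % ring, e % ring if e % ring else ring) for s, e in merged]


def gen_molecules(
    config: MoleculeSimConfig,
    feature_map: FeatureMap,
    catalog: list[CatalogEntry],
) -> tuple[MoleculeTable, GroundTruth]:
    """Draw molecules from a nucleosome-configuration catalog.

    Each nucleosome protects ``footprint_bp`` of DNA from crosslinking;
    footprints whose linkers are below the merge threshold coalesce into
    one bubble; bubble boundaries are jittered by Gaussian sizing noise.
    Coordinates are circular, in bp or nm per config.
    """
    probs = np.array([p for _, _, p in catalog], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise AnalysisError("catalog probabilities must sum to 1")
    L = feature_map.ring_length
    for name, starts, _ in catalog:
        for s in starts:
            if not 0 <= s < L:
                raise AnalysisError(
                    f"catalog {name!r}: nucleosome start {s} outside ring")
    rng = _rng(config.seed, "molecules")
    cut = feature_map.cut_site
    mols, truth_rows = [], []
    for i in range(config.n_molecules):
        idx = int(rng.choice(len(catalog), p=probs))
        name, starts, _ = catalog[idx]
        feet = [(s, s + config.footprint_bp) for s in starts]
        bubbles = _merge_circular(feet, L, config.merge_threshold_bp)
        if config.sizing_noise_sd_bp > 0:
            jittered = []
            for s, e in bubbles:
                js = s + rng.normal(0, config.sizing_noise_sd_bp)
                je = e + rng.normal(0, config.sizing_noise_sd_bp)
                if je <= js:  # keep at least a visible bubble
                    je = js + 1.0
                jittered.append((js % L, je % L or L))
            bubbles = jittered
        # the restriction site must stay crosslinkable: nudge any bubble
        # that drifted over the cut site
        safe = []
        for s, e in bubbles:
            ln = (e - s) % L or (e - s)
            if _wraps_point(s, e, cut, L):
                s = (cut + 1.0) % L
                e = s + ln
                s, e = s % L, e % L or L
            safe.append((s, e))
        scale = 1.0 if config.unit == "bp" else 1.0 / config.bp_per_nm
        mols.append(Molecule(
            molecule_id=f"mol{i + 1:05d}",
            total_length=L * scale,
            unit=config.unit,
            topology="circular",
            bubbles=[(s * scale, e * scale) for s, e in safe],
        ))
        truth_rows.append({"molecule_id": f"mol{i + 1:05d}",
                           "configuration": name})
    counts: dict[str, int] = {}
    for row in truth_rows:
        counts[row["configuration"]] = counts.get(row["configuration"], 0) + 1
    truth = GroundTruth("molecules", {
        "catalog": [{"name": n, "starts": list(s), "probability": p}
                    for n, s, p in catalog],
        "per_molecule": truth_rows,
        "configuration_counts": counts,
    })
    return MoleculeTable(mols), truth


def _wraps_point(s: float, e: float, point: float, ring: float) -> bool:
    if s < e:
        return s <= point < e
    return point >= s or point < e


# ---------------------------------------------------------------------------
# amounts


@dataclass
class AmountsSimConfig:
    seed: int = 0
    domain_name: str = "sim-domain"
    ce_fmoles: float = 1000.0
    true_recovery: float = 0.13
    extraction_loss: float = 0.0
    pellet_fraction: float = 0.5
    true_fold_excess: float = 10000.0
    true_efficiency_pct: float = 60.0


def gen_amounts(config: AmountsSimConfig = AmountsSimConfig()
                ) -> tuple[FractionAmounts, GroundTruth]:
    """Deterministic fraction-amount table with known recovery/fold-excess."""
    ce = config.ce_fmoles
    retained = ce * (1.0 - config.extraction_loss)
    p = retained * config.pellet_fraction
    sup = retained - p
    e = ce * config.true_recovery
    ft = max(ce - e, 0.0) * 0.2
    b = max(ce - e - ft, 0.0) * 0.05
    eff = config.true_efficiency_pct
    amounts = FractionAmounts(
        domain_name=config.domain_name,
        amounts={"CE": ce, "P": p, "SUP": sup,
                 "FT_igg": ft, "E_igg": e, "B_igg": b},
        pdc1_amounts={"E_igg": e / config.true_fold_excess},
        recombined=eff,
        nonrecombined=100.0 - eff,
    )
    truth = GroundTruth("amounts", {
        "true_recovery": config.true_recovery,
        "true_fold_excess": config.true_fold_excess,
        "true_efficiency_pct": config.true_efficiency_pct,
    })
    return amounts, truth
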