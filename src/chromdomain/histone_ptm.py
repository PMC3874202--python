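"""Propionylation-aware relative quantification of histone modifications
from centroided MALDI peak lists.

Chemistry.  Before digestion, histones are acylated with propionic
anhydride: every unmodified or monomethylated lysine epsilon-amine and
every peptide N-terminus gains a propionyl group (+56.02621 Da).  Acetylated,
dimethylated and trimethylated lysines are not derivatized.  Trypsin then
cleaves after arginine only (all lysines are blocked), i.e. an Arg-C-like
digest, and never before proline.

Quantification.  For a peptide of interest, all mass-distinct combinations
of lysine states are enumerated with theoretical [M+H]+ values; spectra are
recalibrated against unmodified anchor peptides of the same histone, each
modform mass bin receives the intensity of the nearest peak within a
tolerance, and the relative proportion of a modform is its intensity
divided by the summed intensity over all modforms of that peptide.
Proportions are averaged over MALDI spot replicas.

Only MS1-level information is used: positional isomers collapse into one
mass bin (e.g. "2ac" regardless of which lysine pair) and near-isobaric
bins such as acetyl vs trimethyl (delta 0.03638 Da) are reported jointly as
an ambiguity group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mass as _pmass

from .errors import AnalysisError, ValidationError
from .io import PeakList

logger = logging.getLogger(__name__)

# monoisotopic constants (Da)
WATER = 18.010565
PROTON = 1.007276
RESIDUE_MASS = dict(_pmass.std_aa_mass)

#: mass deltas of lysine side-chain states after propionylation chemistry.
#: me1 is still propionylatable, me2/me3 are not.
STATE_DELTA = {
    "prop": 56.026215,
    "ac": 42.010565,
    "me1+prop": 14.015650 + 56.026215,
    "me2": 2 * 14.015650,
    "me3": 3 * 14.015650,
}
NTERM_PROP = 56.026215

FULL_ALPHABET = ("prop", "ac", "me1+prop", "me2", "me3")

# mature yeast core histones (initiator Met removed); numbering is 1-based
# on these strings, matching the conventional residue numbers (H4 K5/K8/
# K12/K16, H3 K9/K14 etc.)
YEAST_H4 = (
    "SGRGKGGKGLGKGGAKRHRKILRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAV"
    "TYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
)
YEAST_H3 = (
    "ARTKQTARKSTGGKAPRKQLASKAARKSAPSTGGVKKPHRYKPGTVALREIRRFQKSTELLIRKLPFQRL"
    "VREIAQDFKTDLRFQSSAIGALQESVEAYLVSLFEDTNLAAIHAKRVTIQKKDIKLARRLRGERS"
)

#: unmodified (fully propionylated) peptides used for recalibration
DEFAULT_ANCHORS = {"H4": ((46, 55), (79, 92)), "H3": ((64, 69), (27, 40))}


@dataclass(frozen=True)
class HistoneSequence:
    """A mature histone sequence with 1-based conventional numbering."""

    name: str
    residues: str
    numbering_offset: int = 0  # residue number = index + 1 + offset

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(RESIDUE_MASS)
        if bad:
            raise ValidationError(f"{self.name}: unknown residues {bad}")

    def peptide(self, start: int, end: int) -> str:
        """Residues start..end, 1-based inclusive in histone numbering."""
        i0 = start - 1 - self.numbering_offset
        i1 = end - self.numbering_offset
        if i0 < 0 or i1 > len(self.residues):
            raise ValidationError(
                f"{self.name}: peptide {start}-{end} outside sequence")
        return self.residues[i0:i1]


H4 = HistoneSequence("H4", YEAST_H4)
H3 = HistoneSequence("H3", YEAST_H3)


def read_histone_fasta(path: str | Path) -> dict[str, HistoneSequence]:
    """Read histone sequences from FASTA (record id becomes the name)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = HistoneSequence(rec.id, str(rec.seq).upper())
    return out


@dataclass(frozen=True)
class ModForm:
    """One mass-distinct modification form (bin) of a derivatized peptide.

    ``composition`` counts lysine states over the peptide's K positions;
    which particular lysine carries which state is not resolved at MS1.
    """

    peptide: tuple[int, int]
    composition: tuple[tuple[str, int], ...]  # sorted (state, count)
    nterm_state: str
    mono_mass: float
    mz_mh: float
    label: str


def derivatized_digest(seq: HistoneSequence, max_missed: int = 0
                       ) -> list[tuple[int, int]]:
    """Arg-C-like digest of a propionylated histone.

    Cleaves after R only (K is blocked by propionylation or endogenous
    modification), never before P.  Returns 1-based inclusive residue
    ranges in histone numbering, including ``max_missed`` missed-cleavage
    variants.
    """
    res = seq.residues
    cuts = [0]
    for i, aa in enumerate(res[:-1]):
        if aa == "R" and res[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(res))
    base = 1 + seq.numbering_offset
    ranges = []
    for miss in range(max_missed + 1):
        for a, b in zip(cuts, cuts[1 + miss:]):
            ranges.append((a + base, b + base - 1))
    return sorted(ranges)


def theoretical_mz(peptide_seq: str,
                   composition: dict[str, int] | None = None,
                   nterm_state: str = "prop") -> float:
    """[M+H]+ of a derivatized peptide: residue masses + water + proton +
    N-terminal propionyl (if any) + lysine-state deltas."""
    try:
        m = sum(RESIDUE_MASS[aa] for aa in peptide_seq)
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}") from exc
    m += WATER + PROTON
    if nterm_state == "prop":
        m += NTERM_PROP
    elif nterm_state != "free":
        raise ValidationError(f"unknown N-terminal state {nterm_state!r}")
    if composition:
        n_k = peptide_seq.count("K")
        if sum(composition.values()) != n_k:
            raise ValidationError(
                f"composition covers {sum(composition.values())} sites but "
                f"peptide has {n_k} lysines")
        for state, count in composition.items():
            if state not in STATE_DELTA:
                raise ValidationError(f"unknown lysine state {state!r}")
            m += count * STATE_DELTA[state]
    return m


def _composition_label(composition: tuple[tuple[str, int], ...]) -> str:
    parts = [f"{n}{state}" for state, n in composition
             if state != "prop" and n > 0]
    return "+".join(parts) if parts else "unmod"


def enumerate_modforms(
    seq: HistoneSequence,
    peptide: tuple[int, int],
    alphabet: tuple[str, ...] = ("prop", "ac"),
    nterm_state: str = "prop",
    mass_decimals: int = 4,
) -> list[ModForm]:
    """All mass-distinct lysine-state combinations of one peptide.

    Site-state combinations that differ only in which lysine carries a
    state are mass-degenerate and collapse into one multiset; multisets
    whose masses still coincide at ``mass_decimals`` rounding are merged
    into a single bin with a joint label.  Returned sorted by mass.
    """
    unknown = set(alphabet) - set(STATE_DELTA)
    if unknown:
        raise ValidationError(f"unknown lysine states {unknown}")
    pep_seq = seq.peptide(*peptide)
    n_k = pep_seq.count("K")
    by_mass: dict[float, list[tuple[tuple[tuple[str, int], ...], float]]] = {}
    for combo in itertools.combinations_with_replacement(sorted(alphabet), n_k):
        comp = {s: combo.count(s) for s in sorted(set(combo))}
        m = theoretical_mz(pep_seq, comp if n_k else None, nterm_state)
        key = round(m, mass_decimals)
        comp_t = tuple(sorted(comp.items()))
        by_mass.setdefault(key, []).append((comp_t, m))
    forms = []
    for key in sorted(by_mass):
        entries = by_mass[key]
        label = "|".join(sorted(_composition_label(c) for c, _ in entries))
        mz = float(np.mean([m for _, m in entries]))
        forms.append(ModForm(
            peptide=peptide,
            composition=entries[0][0],
            nterm_state=nterm_state,
            mono_mass=mz - PROTON,
            mz_mh=mz,
            label=label,
        ))
    return forms


# ---------------------------------------------------------------------------
# recalibration and assignment


def find_anchors(
    peaklist: PeakList,
    anchor_mz: dict[str, float],
    coarse_tolerance: float = 0.5,
) -> list[tuple[float, float]]:
    """Match theoretical anchor masses to observed peaks within a coarse
    tolerance; returns (theoretical, observed) pairs."""
    pairs = []
    for label, theo in sorted(anchor_mz.items()):
        if len(peaklist) == 0:
            break
        i = int(np.argmin(np.abs(peaklist.mz - theo)))
        if abs(peaklist.mz[i] - theo) <= coarse_tolerance:
            pairs.append((theo, float(peaklist.mz[i])))
        else:
            logger.warning("spot %s: anchor %s (%.4f) not found",
                           peaklist.spot_id, label, theo)
    return pairs


def anchor_mz_for(seq: HistoneSequence,
                  anchors: tuple[tuple[int, int], ...] | None = None
                  ) -> dict[str, float]:
    """Theoretical [M+H]+ of the fully propionylated anchor peptides."""
    if anchors is None:
        anchors = DEFAULT_ANCHORS.get(seq.name, ())
    out = {}
    for start, end in anchors:
        pep = seq.peptide(start, end)
        comp = {"prop": pep.count("K")} if "K" in pep else None
        out[f"{seq.name}:{start}-{end}"] = theoretical_mz(pep, comp)
    return out


def recalibrate(peaklist: PeakList,
                anchors: list[tuple[float, float]]) -> PeakList:
    """Linear (>=2 anchors) or offset-only (1 anchor) mass recalibration.

    The map observed -> theoretical is least-squares fit on the anchor
    pairs and applied to every peak.  With no anchors the list is returned
    unchanged with a warning.
    """
    if not anchors:
        logger.warning("spot %s: no anchors; recalibration skipped",
                       peaklist.spot_id)
        return peaklist
    theo = np.array([t for t, _ in anchors])
    obs = np.array([o for _, o in anchors])
    if len(anchors) >= 2:
        slope, offset = np.polyfit(obs, theo, 1)
    else:
        slope, offset = 1.0, float(theo[0] - obs[0])
    logger.info("spot %s: recalibration slope=%.8f offset=%+.5f (%d anchors)",
                peaklist.spot_id, slope, offset, len(anchors))
    return PeakList(
        spot_id=peaklist.spot_id,
        mz=slope * peaklist.mz + offset,
        intensity=peaklist.intensity.copy(),
        acquisition_window=peaklist.acquisition_window,
    )


@dataclass
class BinGroup:
    """One assignable unit: a modform bin, or several near-isobaric bins
    merged into an ambiguity group."""

    label: str
    mz: float
    members: tuple[ModForm, ...] = field(default_factory=tuple)


def merge_ambiguous_bins(modforms: list[ModForm],
                         tolerance_da: float = 0.15) -> list[BinGroup]:
    """Merge bins whose theoretical masses lie within 2x tolerance.

    Such bins (e.g. acetyl vs trimethyl, delta 0.036 Da) cannot be told
    apart at MS1 and are quantified jointly.
    """
    forms = sorted(modforms, key=lambda f: f.mz_mh)
    groups: list[list[ModForm]] = []
    for f in forms:
        if groups and f.mz_mh - groups[-1][-1].mz_mh < 2 * tolerance_da:
            groups[-1].append(f)
        else:
            groups.append([f])
    return [
        BinGroup(
            label="|".join(sorted(m.label for m in grp)),
            mz=float(np.mean([m.mz_mh for m in grp])),
            members=tuple(grp),
        )
        for grp in groups
    ]


def assign_peaks(
    peaklist: PeakList,
    modforms: list[ModForm],
    tolerance_da: float = 0.15,
) -> dict[str, float]:
    """Intensity of the nearest peak within tolerance for each bin group.

    Bins without a matching peak get 0.  A peak claimed by two distinct
    groups goes to the nearer one; an exact tie raises an error.
    """
    groups = merge_ambiguous_bins(modforms, tolerance_da)
    out: dict[str, float] = {}
    claims: dict[int, tuple[str, float]] = {}
    for g in groups:
        if len(peaklist) == 0:
            out[g.label] = 0.0
            continue
        dist = np.min(np.abs(peaklist.mz[:, None]
                             - np.array([m.mz_mh for m in g.members])[None, :]),
                      axis=1)
        i = int(np.argmin(dist))
        if dist[i] > tolerance_da:
            out[g.label] = 0.0
            continue
        if i in claims:
            prev_label, prev_dist = claims[i]
            if dist[i] == prev_dist:
                raise AnalysisError(
                    f"peak {peaklist.mz[i]:.4f} equidistant from bins "
                    f"{prev_label!r} and {g.label!r}")
            if dist[i] < prev_dist:
                out[prev_label] = 0.0
            else:
                out[g.label] = 0.0
                continue
        claims[i] = (g.label, float(dist[i]))
        out[g.label] = float(peaklist.intensity[i])
    return out


def modification_proportions(assignments: dict[str, float]
                             ) -> dict[str, float] | None:
    """Normalize assigned intensities to proportions summing to 1.

    Returns None (peptide not detected) when every bin is zero.
    """
    total = sum(assignments.values())
    if total <= 0:
        return None
    return {label: inten / total for label, inten in assignments.items()}


def average_replicas(tables: list[dict[str, float] | None]
                     ) -> dict[str, float] | None:
    """Unweighted per-bin mean over replicas where the peptide was
    detected, renormalized to sum 1."""
    detected = [t for t in tables if t is not None]
    if not detected:
        return None
    labels = sorted({label for t in detected for label in t})
    means = {label: float(np.mean([t.get(label, 0.0) for t in detected]))
             for label in labels}
    total = sum(means.values())
    return {label: v / total for label, v in means.items()}


def quantify_peptide(
    peaklists: list[PeakList],
    seq: HistoneSequence,
    peptide: tuple[int, int],
    alphabet: tuple[str, ...] = ("prop", "ac"),
    tolerance_da: float = 0.15,
    anchors: tuple[tuple[int, int], ...] | None = None,
    recalibration: bool = True,
) -> tuple[dict[str, float] | None, list[dict[str, float] | None]]:
    """Full per-peptide pipeline over all spot replicas.

    Returns (averaged proportions, per-replica proportions).
    """
    modforms = enumerate_modforms(seq, peptide, alphabet)
    anchor_masses = anchor_mz_for(seq, anchors)
    per_spot: list[dict[str, float] | None] = []
    for pl in peaklists:
        if recalibration:
            pl = recalibrate(pl, find_anchors(pl, anchor_masses))
        per_spot.append(
            modification_proportions(assign_peaks(pl, modforms, tolerance_da)))
    return average_replicas(per_spot), per_spot
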