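"""Typed containers and TSV readers/writers for all analysis inputs.

Every tabular format is TSV with a one-line header.  Column dictionaries:

``quant``        replicate_id, protein_id, peptide_seq, <one column per
                 reporter channel, header = channel label, e.g. "114">
``annotation``   protein_id, functional_class, complexes
                 (comma-separated complex names, may be empty)
``peaks``        spot_id, mz, intensity  (long format, one row per peak)
``molecules``    molecule_id, total_length, unit (nm|bp),
                 topology (circular|linear), bubbles
                 ("start:end" pairs joined by ";", empty for none)
``amounts``      domain, measure (domain|pdc1|recombined|nonrecombined),
                 fraction (CE|P|SUP|FT_igg|E_igg|B_igg|FT_cam|E_cam|B_cam,
                 empty for recombined/nonrecombined rows), fmoles

Coordinates are 0-based half-open throughout; on circular molecules a
bubble with start > end wraps through the origin and all interval
arithmetic is taken modulo the ring length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: functional classes that count as purification background
BACKGROUND_CLASSES = frozenset({"housekeeping", "ribosomal protein"})

FRACTION_LABELS = (
    "CE", "P", "SUP", "FT_igg", "E_igg", "B_igg", "FT_cam", "E_cam", "B_cam",
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class QuantTable:
    """Peptide-level reporter-ion intensities.

    ``data`` holds one row per (replicate, protein, peptide) with the fixed
    key columns followed by one intensity column per reporter channel.
    """

    data: pd.DataFrame
    channels: tuple[str, ...]

    KEY_COLUMNS = ("replicate_id", "protein_id", "peptide_seq")

    def __post_init__(self) -> None:
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) < 2:
            raise ValidationError("a quant table needs at least 2 channels")
        missing = [c for c in (*self.KEY_COLUMNS, *self.channels)
                   if c not in self.data.columns]
        if missing:
            raise FormatError(f"quant table missing columns: {missing}")
        for ch in self.channels:
            col = pd.to_numeric(self.data[ch], errors="coerce")
            bad = self.data.index[col.isna() | (col < 0)]
            if len(bad):
                raise ValidationError(
                    f"negative or non-numeric intensity in channel {ch!r}, "
                    f"row {int(bad[0])}"
                )
            self.data[ch] = col.astype(float)
        dup = self.data.duplicated(subset=list(self.KEY_COLUMNS))
        if dup.any():
            raise ValidationError(
                "duplicate (replicate, protein, peptide) row at index "
                f"{int(self.data.index[dup][0])}"
            )

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["replicate_id"]))

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantTable):
            return NotImplemented
        if self.channels != other.channels:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in self.KEY_COLUMNS:
            if not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        for c in self.channels:
            if not np.allclose(a[c], b[c], rtol=0, atol=1e-9):
                return False
        return True


@dataclass
class AnnotationTable:
    """Protein annotations: functional class, complex membership, background flag.

    The background flag is derived, not stored: a protein is background iff
    its functional class is "housekeeping" or "ribosomal protein".
    """

    classes: dict[str, str]
    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, cxs in self.complexes.items():
            if any(not name for name in cxs):
                raise ValidationError(f"empty complex name for protein {pid!r}")

    def functional_class(self, protein_id: str) -> str:
        return self.classes.get(protein_id, "other")

    def is_background(self, protein_id: str) -> bool:
        return self.functional_class(protein_id) in BACKGROUND_CLASSES

    def complex_members(self) -> dict[str, set[str]]:
        """Invert protein -> complexes into complex -> member proteins."""
        out: dict[str, set[str]] = {}
        for pid, cxs in self.complexes.items():
            for name in cxs:
                out.setdefault(name, set()).add(pid)
        return out


@dataclass
class PeakList:
    """A centroided MALDI peak list for one target-plate spot."""

    spot_id: str
    mz: np.ndarray
    intensity: np.ndarray
    acquisition_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValidationError(f"negative intensity in spot {self.spot_id!r}")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            logger.warning("spot %s: m/z not strictly increasing; sorting",
                           self.spot_id)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.acquisition_window is not None:
            lo, hi = self.acquisition_window
            if not (0 < lo < hi):
                raise ValidationError("acquisition window bounds must be "
                                      "positive with min < max")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Molecule:
    """One EM-traced molecule with single-stranded bubble intervals.

    Bubbles are half-open ``(start, end)`` intervals in the molecule's unit.
    On a circular molecule ``start > end`` denotes a bubble wrapping through
    the origin.
    """

    molecule_id: str
    total_length: float
    unit: str  # "nm" | "bp"
    topology: str  # "circular" | "linear"
    bubbles: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "bp"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if self.total_length <= 0:
            raise ValidationError("total_length must be positive")
        L = self.total_length
        for s, e in self.bubbles:
            if not (0 <= s < L) or not (0 <= e <= L):
                raise ValidationError(
                    f"molecule {self.molecule_id}: bubble ({s}, {e}) outside "
                    f"[0, {L})")
            if self.topology == "linear" and e <= s:
                raise ValidationError(
                    f"molecule {self.molecule_id}: empty/reversed bubble on a "
                    "linear molecule")
        self._check_overlap()

    def bubble_length(self, bubble: tuple[float, float]) -> float:
        s, e = bubble
        if self.topology == "circular":
            return (e - s) % self.total_length
        return e - s

    def _cover(self, bubble: tuple[float, float]) -> list[tuple[float, float]]:
        """Bubble as non-wrapping segment(s)."""
        s, e = bubble
        if self.topology == "circular" and e <= s:
            return [(s, self.total_length), (0.0, e)]
        return [(s, e)]

    def _check_overlap(self) -> None:
        segs: list[tuple[float, float]] = []
        for b in self.bubbles:
            segs.extend(self._cover(b))
        segs.sort()
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"molecule {self.molecule_id}: overlapping bubbles "
                    f"({s1}, {e1}) and ({s2}, {e2})")


@dataclass
class MoleculeTable:
    molecules: list[Molecule]

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)


@dataclass
class FeatureMap:
    """Named intervals on the chromatin ring plus the linearizing cut site."""

    ring_length: int
    features: dict[str, tuple[int, int]]
    cut_site: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cut_site < self.ring_length):
            raise ValidationError("cut_site outside ring")
        for name, (s, e) in self.features.items():
            if not (0 <= s < self.ring_length and 0 <= e <= self.ring_length):
                raise ValidationError(f"feature {name!r} outside ring")
            if s == e:
                raise ValidationError(f"feature {name!r} is empty")


@dataclass
class FractionAmounts:
    """fmole DNA amounts per purification fraction for one domain."""

    domain_name: str
    amounts: dict[str, float]
    pdc1_amounts: dict[str, float] = field(default_factory=dict)
    recombined: float | None = None
    nonrecombined: float | None = None

    def __post_init__(self) -> None:
        for label, v in {**self.amounts, **self.pdc1_amounts}.items():
            if v < 0:
                raise ValidationError(
                    f"{self.domain_name}: negative amount for {label!r}")
        if "CE" not in self.amounts or not any(
                k.startswith("E_") for k in self.amounts):
            raise ValidationError(
                f"{self.domain_name}: need CE and at least one elution "
                "fraction for recovery computation")


# ---------------------------------------------------------------------------
# readers

def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    return df


def read_quant_table(path: str | Path) -> QuantTable:
    """Read a peptide-level quant TSV; all non-key columns are channels."""
    df = _read_tsv(path, QuantTable.KEY_COLUMNS)
    channels = tuple(c for c in df.columns if c not in QuantTable.KEY_COLUMNS)
    logger.info("read_quant_table: %d rows, channels %s", len(df), channels)
    return QuantTable(df, channels)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    cols = [*QuantTable.KEY_COLUMNS, *table.channels]
    table.data.to_csv(path, sep="\t", index=False, columns=cols,
                      float_format="%.10g")


def read_annotation(path: str | Path) -> AnnotationTable:
    df = _read_tsv(path, ("protein_id", "functional_class"))
    classes: dict[str, str] = {}
    complexes: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        cls = row["functional_class"].strip()
        classes[pid] = cls
        raw = row.get("complexes", "") if "complexes" in df.columns else ""
        names = frozenset(x.strip() for x in raw.split(",") if x.strip())
        if names:
            complexes[pid] = names
    return AnnotationTable(classes, complexes)


def write_annotation(annot: AnnotationTable, path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "functional_class": cls,
         "complexes": ",".join(sorted(annot.complexes.get(pid, ())))}
        for pid, cls in sorted(annot.classes.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "functional_class", "complexes"]
                 ).to_csv(path, sep="\t", index=False)


def read_peaklists(path: str | Path,
                   acquisition_window: tuple[float, float] | None = None,
                   ) -> list[PeakList]:
    """Read a long-format peak TSV into one PeakList per spot."""
    df = _read_tsv(path, ("spot_id", "mz", "intensity"))
    if df.empty:
        logger.warning("read_peaklists: %s contains no peaks", path)
        return []
    out = []
    for spot, grp in df.groupby("spot_id", sort=False):
        out.append(PeakList(
            spot_id=str(spot),
            mz=grp["mz"].astype(float).to_numpy(),
            intensity=grp["intensity"].astype(float).to_numpy(),
            acquisition_window=acquisition_window,
        ))
    logger.info("read_peaklists: %d spots, %d peaks", len(out), len(df))
    return out


def write_peaklists(peaklists: list[PeakList], path: str | Path) -> None:
    rows = []
    for pl in peaklists:
        for mz, inten in zip(pl.mz, pl.intensity):
            rows.append({"spot_id": pl.spot_id, "mz": mz, "intensity": inten})
    pd.DataFrame(rows, columns=["spot_id", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def _parse_bubbles(text: str) -> list[tuple[float, float]]:
    if not text.strip():
        return []
    out = []
    for part in text.split(";"):
        try:
            s, e = part.split(":")
            out.append((float(s), float(e)))
        except ValueError as exc:
            raise FormatError(f"malformed bubble spec {part!r}") from exc
    return out


def read_molecules(path: str | Path) -> MoleculeTable:
    df = _read_tsv(path, ("molecule_id", "total_length", "unit", "topology",
                          "bubbles"))
    mols = [
        Molecule(
            molecule_id=row["molecule_id"],
            total_length=float(row["total_length"]),
            unit=row["unit"],
            topology=row["topology"],
            bubbles=_parse_bubbles(row["bubbles"]),
        )
        for _, row in df.iterrows()
    ]
    logger.info("read_molecules: %d molecules", len(mols))
    return MoleculeTable(mols)


def write_molecules(table: MoleculeTable, path: str | Path) -> None:
    rows = [
        {"molecule_id": m.molecule_id,
         "total_length": "%.10g" % m.total_length,
         "unit": m.unit, "topology": m.topology,
         "bubbles": ";".join("%.10g:%.10g" % b for b in m.bubbles)}
        for m in table
    ]
    pd.DataFrame(rows, columns=["molecule_id", "total_length", "unit",
                                "topology", "bubbles"]
                 ).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path, ring_length: int,
                  cut_site: int = 0) -> FeatureMap:
    """Read BED-like features (chrom, start, end, name); chrom is ignored."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    features: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path.name}:{i + 1}: expected >=3 columns")
            name = parts[3] if len(parts) > 3 else f"feature{i + 1}"
            features[name] = (int(parts[1]), int(parts[2]))
    return FeatureMap(ring_length=ring_length, features=features,
                      cut_site=cut_site)


def read_amounts(path: str | Path) -> list[FractionAmounts]:
    df = _read_tsv(path, ("domain", "measure", "fraction", "fmoles"))
    out = []
    for domain, grp in df.groupby("domain", sort=False):
        amounts: dict[str, float] = {}
        pdc1: dict[str, float] = {}
        rec = nonrec = None
        for _, row in grp.iterrows():
            v = float(row["fmoles"])
            measure = row["measure"] or "domain"
            if measure == "domain":
                amounts[row["fraction"]] = v
            elif measure == "pdc1":
                pdc1[row["fraction"]] = v
            elif measure == "recombined":
                rec = v
            elif measure == "nonrecombined":
                nonrec = v
            else:
                raise FormatError(f"unknown measure {measure!r}")
        out.append(FractionAmounts(domain, amounts, pdc1, rec, nonrec))
    return out


def write_amounts(amounts: list[FractionAmounts], path: str | Path) -> None:
    rows = []
    for fa in amounts:
        for frac, v in fa.amounts.items():
            rows.append({"domain": fa.domain_name, "measure": "domain",
                         "fraction": frac, "fmoles": v})
        for frac, v in fa.pdc1_amounts.items():
            rows.append({"domain": fa.domain_name, "measure": "pdc1",
                         "fraction": frac, "fmoles": v})
        if fa.recombined is not None:
            rows.append({"domain": fa.domain_name, "measure": "recombined",
                         "fraction": "", "fmoles": fa.recombined})
        if fa.nonrecombined is not None:
            rows.append({"domain": fa.domain_name, "measure": "nonrecombined",
                         "fraction": "", "fmoles": fa.nonrecombined})
    pd.DataFrame(rows, columns=["domain", "measure", "fraction", "fmoles"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results(results: pd.DataFrame, path: str | Path,
                  columns: list[str] | None = None) -> None:
    """Write a result table as TSV with deterministic column order."""
    if columns is None:
        columns = list(results.columns)
    results.to_csv(path, sep="\t", index=False, columns=columns,
                   float_format="%.10g")
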