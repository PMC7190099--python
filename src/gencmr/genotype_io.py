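"""Reading, writing and normalizing noninvasive genotype sample records.

The sample unit is one georeferenced dung sample carrying a diploid
microsatellite (STR) genotype, amplification statuses for three
sex-chromosome markers, and an mtDNA control-region haplotype label.
Coordinates are planar meters in a projected system; all distances in the
pipeline are Euclidean (study areas of a few tens of km make projection
distortion negligible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Allele value used for a missing allele in tabular formats (GenAlEx convention).
MISSING = 0

#: Marker names for molecular sexing: two Y-specific loci and one X-specific locus.
SEX_MARKERS = ("SRY", "AMELY", "PLP1")

Genotype = dict[str, tuple[int, int]]


def normalize_pair(a: int, b: int) -> tuple[int, int]:
    """Return an unordered allele pair in canonical (sorted) order.

    A pair with exactly one missing allele is coerced to fully missing:
    a half-called locus cannot be compared reliably, so the record keeps
    either both alleles or neither.
    """
    if a == MISSING or b == MISSING:
        if a != b:
            logger.warning("half-missing allele pair (%s, %s) set to missing", a, b)
        return (MISSING, MISSING)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SampleRecord:
    """One dung sample: identity, spatiotemporal context, and genotype data."""

    sample_id: str
    date: Date
    x: float
    y: float
    genotype: Mapping[str, tuple[int, int]]
    sex_markers: Mapping[str, str]  # "+", "-", or "?" per marker
    haplotype: str | None = None
    freshness_class: str = "fresh"

    def typed_loci(self) -> list[str]:
        return [l for l, g in self.genotype.items() if g != (MISSING, MISSING)]

    def n_typed(self) -> int:
        return len(self.typed_loci())


def assign_sex(record: SampleRecord) -> str:
    """Molecular sexing from Y-specific (SRY, AMELY) and X-specific (PLP1) markers.

    A dung extract is called male only when both Y markers and the X marker
    amplified, female only when the X marker amplified and both Y markers
    cleanly failed. Every other pattern — amplification failure of the X
    control, a single Y marker, or unknown statuses — is inconclusive and
    maps to ``"unknown"``: total DNA quality cannot be distinguished from a
    true marker absence.
    """
    sry = record.sex_markers.get("SRY", "?")
    amely = record.sex_markers.get("AMELY", "?")
    plp1 = record.sex_markers.get("PLP1", "?")
    if plp1 == "+" and sry == "+" and amely == "+":
        return "male"
    if plp1 == "+" and sry == "-" and amely == "-":
        return "female"
    return "unknown"


@dataclass
class HaplotypeSet:
    """Exact-identity equivalence classes of mtDNA control-region sequences."""

    sequence_to_id: dict[str, int] = field(default_factory=dict)
    sample_to_id: dict[str, int] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(set(self.sequence_to_id.values()))

    def label(self, hap_id: int) -> str:
        return f"H{hap_id}"


def _normalize_sequence(seq: str) -> str:
    return seq.upper().strip("-").replace(" ", "")


def collapse_haplotypes(fasta: str | Path) -> HaplotypeSet:
    """Collapse aligned-length sequences into haplotypes by exact identity.

    IDs are dense integers starting at 1, assigned in order of first
    appearance. Sequences containing ambiguity codes (``N``) are
    unassignable and are left out of the per-sample map rather than being
    fuzzily matched. Length differences after normalization are an error:
    this function never aligns.
    """
    hapset = HaplotypeSet()
    length: int | None = None
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seq = _normalize_sequence(str(rec.seq))
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"sequence {rec.id!r} has length {len(seq)}, expected {length}; "
                "input must be pre-aligned"
            )
        if "N" in seq:
            logger.warning("sequence %s contains ambiguity codes; unassigned", rec.id)
            continue
        if seq not in hapset.sequence_to_id:
            hapset.sequence_to_id[seq] = len(hapset.sequence_to_id) + 1
        hapset.sample_to_id[rec.id] = hapset.sequence_to_id[seq]
    return hapset


# ---------------------------------------------------------------------------
# Tabular sample I/O


def sample_columns(loci: Sequence[str]) -> list[str]:
    cols = ["sample_id", "date", "x", "y"]
    for locus in loci:
        cols += [f"{locus}_1", f"{locus}_2"]
    cols += list(SEX_MARKERS) + ["haplotype", "freshness"]
    return cols


def loci_from_header(columns: Iterable[str]) -> list[str]:
    """Recover locus names from paired ``<locus>_1`` / ``<locus>_2`` columns."""
    firsts = [c[:-2] for c in columns if c.endswith("_1")]
    return [l for l in firsts if f"{l}_2" in set(columns)]


def write_samples(records: Sequence[SampleRecord], path: str | Path, loci: Sequence[str] | None = None, sep: str = "\t") -> None:
    if loci is None:
        loci = list(records[0].genotype) if records else []
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "date": r.date.isoformat(),
            "x": r.x,
            "y": r.y,
        }
        for locus in loci:
            a, b = r.genotype.get(locus, (MISSING, MISSING))
            row[f"{locus}_1"], row[f"{locus}_2"] = a, b
        for m in SEX_MARKERS:
            row[m] = r.sex_markers.get(m, "?")
        row["haplotype"] = r.haplotype if r.haplotype is not None else ""
        row["freshness"] = r.freshness_class
        rows.append(row)
    pd.DataFrame(rows, columns=sample_columns(loci)).to_csv(path, sep=sep, index=False)


def read_samples(path: str | Path, sep: str = "\t") -> list[SampleRecord]:
    """Parse a delimited sample table into :class:`SampleRecord` objects.

    Malformed rows raise with the offending row named; duplicate sample IDs
    are an error; a locus with exactly one missing allele is downgraded to
    fully missing with a warning (see :func:`normalize_pair`).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    loci = loci_from_header(df.columns)
    if not loci:
        raise ValueError(f"{path}: header names no '<locus>_1/<locus>_2' column pairs")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based, after header
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}:{line}: duplicate sample_id {sid!r}")
        seen.add(sid)
        genotype: Genotype = {}
        for locus in loci:
            try:
                a = int(row[f"{locus}_1"])
                b = int(row[f"{locus}_2"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{line}: non-numeric allele at locus {locus} "
                    f"({row[f'{locus}_1']!r}, {row[f'{locus}_2']!r})"
                ) from exc
            genotype[locus] = normalize_pair(a, b)
        markers = {m: (row[m] if row[m] in "+-" else "?") for m in SEX_MARKERS}
        hap = row.get("haplotype", "")
        records.append(
            SampleRecord(
                sample_id=sid,
                date=Date.fromisoformat(row["date"]),
                x=float(row["x"]),
                y=float(row["y"]),
                genotype=genotype,
                sex_markers=markers,
                haplotype=hap if hap else None,
                freshness_class=row.get("freshness", "fresh") or "fresh",
            )
        )
    return records


def write_genalex(records: Sequence[SampleRecord], path: str | Path, loci: Sequence[str] | None = None, title: str = "gencmr export") -> None:
    """Codominant CSV export: two columns per locus, 0 = missing allele."""
    if loci is None:
        loci = list(records[0].genotype) if records else []
    n = len(records)
    header1 = [str(len(loci)), str(n), "1", str(n)] + [""] * (2 * len(loci) - 3)
    header2 = [title] + [""] * (4 + 2 * len(loci) - 5)
    header3 = ["Sample", "Pop"]
    for locus in loci:
        header3 += [locus, ""]
    lines = [",".join(header1), ",".join(header2), ",".join(header3)]
    for r in records:
        row = [r.sample_id, "1"]
        for locus in loci:
            a, b = r.genotype.get(locus, (MISSING, MISSING))
            row += [str(a), str(b)]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def with_assigned_sex(records: Sequence[SampleRecord]) -> list[tuple[SampleRecord, str]]:
    return [(r, assign_sex(r)) for r in records]


__all__ = [
    "MISSING",
    "SEX_MARKERS",
    "SampleRecord",
    "HaplotypeSet",
    "assign_sex",
    "collapse_haplotypes",
    "normalize_pair",
    "read_samples",
    "write_samples",
    "write_genalex",
    "loci_from_header",
    "sample_columns",
    "replace",
]
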