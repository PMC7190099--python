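"""Individual identification from replicated noninvasive genotypes.

Samples are collapsed to unique individuals by pairwise genotype matching
with an error allowance: two samples match when their genotypes differ at
no more than ``max_mismatch`` of the loci typed in both, their sexes are
compatible, and their mtDNA haplotypes are identical whenever both are
known. Matching is a pairwise rule, so clusters are the connected
components of the match graph (single linkage); a cluster containing a
pair that differs at two or more loci is flagged ambiguous rather than
split, because silently splitting would bias abundance upward.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .genotype_io import MISSING, SampleRecord, assign_sex

logger = logging.getLogger(__name__)


@dataclass
class Individual:
    individual_id: str
    consensus: dict[str, tuple[int, int]]
    sex: str  # "female" | "male" | "unknown"
    haplotype: str | None
    samples: list[SampleRecord]
    ambiguous: bool = False
    capture_events: list[tuple[Date, tuple[float, float]]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_events(self) -> int:
        return len(self.capture_events)


def genotype_mismatches(
    g1: dict[str, tuple[int, int]],
    g2: dict[str, tuple[int, int]],
    loci: Sequence[str],
) -> tuple[int, int]:
    """(number of differing loci, number of loci compared) over shared typed loci."""
    compared = mismatches = 0
    for locus in loci:
        a = g1.get(locus, (MISSING, MISSING))
        b = g2.get(locus, (MISSING, MISSING))
        if a[0] == MISSING or b[0] == MISSING:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    return mismatches, compared


def samples_match(
    s1: SampleRecord,
    s2: SampleRecord,
    loci: Sequence[str],
    max_mismatch: int = 1,
    min_compared: int = 6,
) -> bool:
    """Pairwise recapture rule.

    Genotypes may differ at up to ``max_mismatch`` compared loci (allowing
    one genotyping error), but only when at least ``min_compared`` loci
    could be compared — matches on tiny overlap are not trusted. Unknown
    sex or missing haplotype never vetoes; observed conflicts do.
    """
    mism, compared = genotype_mismatches(s1.genotype, s2.genotype, loci)
    if compared < min_compared or mism > max_mismatch:
        return False
    x1, x2 = assign_sex(s1), assign_sex(s2)
    if x1 != "unknown" and x2 != "unknown" and x1 != x2:
        return False
    if s1.haplotype is not None and s2.haplotype is not None and s1.haplotype != s2.haplotype:
        return False
    return True


def _consensus_genotype(
    members: Sequence[SampleRecord],
    loci: Sequence[str],
    pair_frequency: Counter,
) -> dict[str, tuple[int, int]]:
    consensus: dict[str, tuple[int, int]] = {}
    for locus in loci:
        observed = [
            s.genotype[locus]
            for s in members
            if s.genotype.get(locus, (MISSING, MISSING))[0] != MISSING
        ]
        if not observed:
            consensus[locus] = (MISSING, MISSING)
            continue
        tally = Counter(observed)
        top = max(tally.values())
        # majority vote; ties broken toward the pair more frequent dataset-wide
        tied = [pair for pair, c in tally.items() if c == top]
        consensus[locus] = max(tied, key=lambda pair: (pair_frequency[(locus, pair)], pair))
    return consensus


def _consensus_categorical(values: list[str], what: str, cluster_id: str) -> tuple[str | None, bool]:
    distinct = set(values)
    if not distinct:
        return None, False
    if len(distinct) > 1:
        logger.warning("cluster %s has conflicting %s values %s", cluster_id, what, sorted(distinct))
        return Counter(values).most_common(1)[0][0], True
    return values[0], False


def filter_and_match(
    samples: Sequence[SampleRecord],
    loci: Sequence[str],
    min_loci: int = 7,
    max_mismatch: int = 1,
) -> tuple[list[Individual], int]:
    """Collapse samples into individuals.

    Samples typed at fewer than ``min_loci`` loci are excluded first (the
    excluded count is returned). Matching pairs must additionally share at
    least ``min_loci - 1`` compared loci. Returns individuals sorted by
    first capture, plus the number of excluded samples.
    """
    usable = [s for s in samples if s.n_typed() >= min_loci]
    n_excluded = len(samples) - len(usable)
    if n_excluded:
        logger.info("excluded %d samples typed at < %d loci", n_excluded, min_loci)

    pair_frequency: Counter = Counter()
    for s in usable:
        for locus, pair in s.genotype.items():
            if pair[0] != MISSING:
                pair_frequency[(locus, pair)] += 1

    graph = nx.Graph()
    graph.add_nodes_from(range(len(usable)))
    min_compared = max(min_loci - 1, 1)
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            if samples_match(usable[i], usable[j], loci, max_mismatch, min_compared):
                graph.add_edge(i, j)

    individuals: list[Individual] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for n, comp in enumerate(components, start=1):
        members = sorted((usable[i] for i in comp), key=lambda s: (s.date, s.sample_id))
        iid = f"IND{n:04d}"
        consensus = _consensus_genotype(members, loci, pair_frequency)
        ambiguous = False
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                mism, _ = genotype_mismatches(members[a].genotype, members[b].genotype, loci)
                if mism > max_mismatch:
                    ambiguous = True
        if ambiguous:
            logger.warning("cluster %s contains pairs differing at > %d loci", iid, max_mismatch)
        sexes = [x for x in (assign_sex(s) for s in members) if x != "unknown"]
        sex, sex_conflict = _consensus_categorical(sexes, "sex", iid)
        haps = [s.haplotype for s in members if s.haplotype is not None]
        hap, hap_conflict = _consensus_categorical(haps, "haplotype", iid)
        individuals.append(
            Individual(
                individual_id=iid,
                consensus=consensus,
                sex=sex or "unknown",
                haplotype=hap,
                samples=members,
                ambiguous=ambiguous or sex_conflict or hap_conflict,
            )
        )
    return individuals, n_excluded


def deduplicate_events(
    individual: Individual,
    same_place_radius: float = 0.0,
) -> tuple[list[tuple[Date, tuple[float, float]]], int]:
    """Collapse same-day, same-place samples into single capture events.

    Within a day, samples within ``same_place_radius`` meters of an
    already-accepted event location join that event (radius 0 requires
    exact point identity). Returns the event list and the number of
    duplicates removed. The event list is also stored on the individual.
    """
    events: list[tuple[Date, tuple[float, float]]] = []
    removed = 0
    for s in sorted(individual.samples, key=lambda r: (r.date, r.sample_id)):
        duplicate = False
        for d, (ex, ey) in events:
            if d != s.date:
                continue
            if ((s.x - ex) ** 2 + (s.y - ey) ** 2) ** 0.5 <= same_place_radius:
                duplicate = True
                break
        if duplicate:
            removed += 1
        else:
            events.append((s.date, (s.x, s.y)))
    individual.capture_events = events
    return events, removed


@dataclass(frozen=True)
class CaptureSpectrum:
    """Histogram of individuals by number of capture events."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 or n <= 0 for n, c in self.counts.items()):
            raise ValueError("capture counts must be positive, frequencies nonnegative")

    @property
    def k(self) -> int:
        """Distinct individuals."""
        return sum(self.counts.values())

    @property
    def s(self) -> int:
        """Total capture events."""
        return sum(n * c for n, c in self.counts.items())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({str(n): c for n, c in sorted(self.counts.items())}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CaptureSpectrum":
        data = json.loads(Path(path).read_text())
        return cls({int(n): int(c) for n, c in data.items()})

    @classmethod
    def from_mapping(cls, mapping: dict[int, int]) -> "CaptureSpectrum":
        return cls({int(n): int(c) for n, c in mapping.items() if c > 0})


def capture_spectrum(individuals: Sequence[Individual]) -> CaptureSpectrum:
    """Capture-class spectrum from deduplicated events per individual."""
    counter: Counter = Counter()
    for ind in individuals:
        n = ind.n_events if ind.capture_events else ind.n_samples
        counter[n] += 1
    return CaptureSpectrum(dict(sorted(counter.items())))


def individuals_table(individuals: Sequence[Individual], loci: Sequence[str]) -> pd.DataFrame:
    rows = []
    for ind in individuals:
        row: dict[str, object] = {
            "individual_id": ind.individual_id,
            "sex": ind.sex,
            "haplotype": ind.haplotype or "",
            "n_samples": ind.n_samples,
            "n_events": ind.n_events,
            "ambiguous": ind.ambiguous,
        }
        for locus in loci:
            a, b = ind.consensus.get(locus, (MISSING, MISSING))
            row[f"{locus}_1"], row[f"{locus}_2"] = a, b
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "CaptureSpectrum",
    "Individual",
    "capture_spectrum",
    "deduplicate_events",
    "filter_and_match",
    "genotype_mismatches",
    "individuals_table",
    "samples_match",
]
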