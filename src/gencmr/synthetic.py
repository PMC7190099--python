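"""Synthetic populations, genotypes and dung surveys for pipeline testing.

The generator emulates the data-generating process the downstream analyses
assume: a closed, spatially distributed population of matrilineal groups,
Mendelian microsatellite inheritance from known allele frequencies,
distance-decayed detection of dung around fixed activity centers, and a
genotyping-error channel (allelic dropout, false alleles, whole-locus
missingness, sex-marker failure). Every stochastic stage consumes a named
substream derived from one global integer seed, so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, SampleRecord, normalize_pair

# fixed substream indices; changing these changes every simulation
_STREAMS = {
    "population": 1,
    "genotypes": 2,
    "survey": 3,
    "haplotype_seqs": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def default_allele_frequencies(
    n_alleles: Sequence[int] = (16, 13, 12, 6, 10, 12, 8, 10),
    decay: float = 0.85,
    base_size: int = 120,
) -> dict[str, dict[int, float]]:
    """Allele-frequency tables for eight dinucleotide loci.

    Frequencies decay geometrically over allele size classes, which yields
    expected heterozygosities around 0.75-0.9 for the richer loci — the
    regime where an 8-locus panel identifies individuals with cumulative
    sibling-identity probability well below 1e-2.
    """
    freqs: dict[str, dict[int, float]] = {}
    for i, na in enumerate(n_alleles):
        w = decay ** np.arange(na)
        w /= w.sum()
        sizes = base_size + 2 * np.arange(na)
        freqs[f"L{i + 1}"] = {int(s): float(p) for s, p in zip(sizes, w)}
    return freqs


def default_grid(n_side: int = 10, spacing: float = 3000.0, origin: tuple[float, float] = (0.0, 0.0)) -> list[tuple[float, float]]:
    """Square survey grid of ``n_side**2`` points at ``spacing`` meters."""
    x0, y0 = origin
    return [
        (x0 + i * spacing, y0 + j * spacing)
        for i in range(n_side)
        for j in range(n_side)
    ]


def default_visit_schedule(
    grid: Sequence[tuple[float, float]],
    n_visits: int = 2,
    start: Date = Date(2013, 6, 1),
    season_gap_days: int = 120,
) -> list[tuple[tuple[float, float], Date]]:
    """Visit every grid point ``n_visits`` times, one sweep per season."""
    schedule = []
    for v in range(n_visits):
        base = start + timedelta(days=v * season_gap_days)
        for i, pt in enumerate(grid):
            schedule.append((pt, base + timedelta(days=i % 30)))
    return schedule


@dataclass
class SimulationConfig:
    """Study-design and population parameters for the generator.

    Lengths are meters, densities individuals per km^2, rates are
    probabilities per the unit named in each field comment.
    """

    region: tuple[float, float, float, float] | None = None  # survey hull (x0, y0, x1, y1)
    true_density: float = 0.62  # individuals / km^2
    grid_spacing: float = 3000.0
    n_grid_points: int = 100
    visit_schedule: list[tuple[tuple[float, float], Date]] = field(default_factory=list)
    lambda0: float = 0.2  # expected detections per visit at distance 0
    sigma: float = 1500.0  # spatial scale of the exponential detection kernel
    buffer: float = 2000.0  # activity centers may lie this far outside the hull
    group_size_mean: float = 3.0
    group_scatter: float = 300.0  # sd of member activity centers around the group center
    group_spread: float = 50.0  # max pairwise spread of same-visit group depositions
    jitter_sd: float = 100.0  # sd of dung location around the visited point
    n_haplotypes: int = 6
    haplotype_freqs: Sequence[float] | None = None
    allele_freqs: Mapping[str, Mapping[int, float]] = field(default_factory=default_allele_frequencies)
    dropout_rate: float = 0.05  # per heterozygous-locus observation
    false_allele_rate: float = 0.01  # per locus observation
    missing_locus_rate: float = 0.02
    sex_marker_failure_rate: float = 0.02  # per marker per sample
    haplotype_missing_rate: float = 0.05
    sex_ratio_female: float = 0.55
    female_dispersal_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.visit_schedule:
            n_side = max(2, round(math.isqrt(self.n_grid_points)))
            self.visit_schedule = default_visit_schedule(
                default_grid(n_side, self.grid_spacing)
            )
        if self.region is None:
            xs = [p[0] for p, _ in self.visit_schedule]
            ys = [p[1] for p, _ in self.visit_schedule]
            self.region = (min(xs), min(ys), max(xs), max(ys))
        if self.haplotype_freqs is None:
            w = 0.7 ** np.arange(self.n_haplotypes)
            self.haplotype_freqs = tuple(float(v) for v in w / w.sum())
        x0, y0, x1, y1 = self.region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("region must have positive area")
        for name in ("dropout_rate", "false_allele_rate", "missing_locus_rate",
                     "sex_marker_failure_rate", "haplotype_missing_rate",
                     "sex_ratio_female", "female_dispersal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.true_density < 0:
            raise ValueError("true_density must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype_freqs must sum to 1")
        for locus, table in self.allele_freqs.items():
            if not table:
                raise ValueError(f"locus {locus} has an empty frequency table")
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies at {locus} must sum to 1")

    @property
    def loci(self) -> list[str]:
        return list(self.allele_freqs)

    @property
    def buffered_region(self) -> tuple[float, float, float, float]:
        x0, y0, x1, y1 = self.region
        b = self.buffer
        return (x0 - b, y0 - b, x1 + b, y1 + b)

    @property
    def buffered_area_km2(self) -> float:
        x0, y0, x1, y1 = self.buffered_region
        return (x1 - x0) * (y1 - y0) / 1e6


@dataclass(frozen=True)
class TrueIndividual:
    individual_id: str
    sex: str  # "female" | "male"
    center: tuple[float, float]
    haplotype_id: int
    mother_id: str | None
    group_id: int


@dataclass
class TruePopulation:
    """The simulated ground truth: who exists, where, and who begat whom."""

    individuals: list[TrueIndividual]
    config_seed: int

    def __len__(self) -> int:
        return len(self.individuals)

    def by_id(self) -> dict[str, TrueIndividual]:
        return {ind.individual_id: ind for ind in self.individuals}

    def groups(self) -> dict[int, list[TrueIndividual]]:
        out: dict[int, list[TrueIndividual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.group_id, []).append(ind)
        return out


def simulate_population(config: SimulationConfig) -> TruePopulation:
    """Draw a closed population of matrilineal groups.

    The total count is Poisson with mean density x buffered area. Groups
    are seeded by a female founder carrying a haplotype drawn from the
    configured haplotype frequencies; every later member is the offspring
    of a female already in the group and inherits her haplotype. Each
    non-founder female then disperses into a uniformly chosen other group
    with probability ``female_dispersal_prob``, retaining her natal
    haplotype — the process that erodes haplotype monomorphism within
    groups.
    """
    rng = _rng(config.seed, "population")
    n_total = int(rng.poisson(config.true_density * config.buffered_area_km2))
    individuals: list[dict] = []
    x0, y0, x1, y1 = config.buffered_region
    group_centers: list[tuple[float, float]] = []
    group_members: list[list[int]] = []  # indices into `individuals`
    remaining = n_total
    gid = 0
    while remaining > 0:
        size = min(remaining, 1 + int(rng.poisson(max(config.group_size_mean - 1.0, 0.0))))
        cx = float(rng.uniform(x0, x1))
        cy = float(rng.uniform(y0, y1))
        founder_hap = 1 + int(rng.choice(len(config.haplotype_freqs), p=np.asarray(config.haplotype_freqs)))
        members: list[int] = []
        for j in range(size):
            idx = len(individuals)
            if j == 0:
                sex, mother, hap = "female", None, founder_hap
            else:
                females = [m for m in members if individuals[m]["sex"] == "female"]
                mother = int(rng.choice(females)) if females else members[0]
                hap = individuals[mother]["hap"]
                sex = "female" if rng.random() < config.sex_ratio_female else "male"
            individuals.append({"sex": sex, "mother": mother, "hap": hap, "group": gid})
            members.append(idx)
        group_members.append(members)
        group_centers.append((cx, cy))
        remaining -= size
        gid += 1

    # female dispersal between established groups
    n_groups = len(group_centers)
    if n_groups > 1:
        for idx, ind in enumerate(individuals):
            if ind["sex"] == "female" and ind["mother"] is not None:
                if rng.random() < config.female_dispersal_prob:
                    other = int(rng.integers(n_groups - 1))
                    if other >= ind["group"]:
                        other += 1
                    ind["group"] = other

    out: list[TrueIndividual] = []
    for idx, ind in enumerate(individuals):
        cx, cy = group_centers[ind["group"]]
        ax = float(np.clip(cx + rng.normal(0, config.group_scatter), x0, x1))
        ay = float(np.clip(cy + rng.normal(0, config.group_scatter), y0, y1))
        out.append(
            TrueIndividual(
                individual_id=f"I{idx + 1:04d}",
                sex=ind["sex"],
                center=(ax, ay),
                haplotype_id=ind["hap"],
                mother_id=None if ind["mother"] is None else f"I{ind['mother'] + 1:04d}",
                group_id=ind["group"],
            )
        )
    return TruePopulation(individuals=out, config_seed=config.seed)


def simulate_genotypes(pop: TruePopulation, config: SimulationConfig) -> dict[str, dict[str, tuple[int, int]]]:
    """Mendelian genotypes over the population pedigree.

    Founders draw two independent alleles per locus from the configured
    frequencies. Each mother is paired with a single sire genotype drawn
    from the same frequencies (so her offspring are full siblings), and
    every offspring receives one uniformly chosen allele from each parent.
    """
    rng = _rng(config.seed, "genotypes")
    loci = config.loci
    tables = {
        locus: (np.array(list(t.keys())), np.array(list(t.values())))
        for locus, t in config.allele_freqs.items()
    }

    def draw(locus: str) -> int:
        alleles, p = tables[locus]
        return int(rng.choice(alleles, p=p))

    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    sires: dict[str, dict[str, tuple[int, int]]] = {}
    for ind in pop.individuals:  # creation order: mothers precede offspring
        g: dict[str, tuple[int, int]] = {}
        if ind.mother_id is None:
            for locus in loci:
                g[locus] = normalize_pair(draw(locus), draw(locus))
        else:
            if ind.mother_id not in sires:
                sires[ind.mother_id] = {
                    locus: (draw(locus), draw(locus)) for locus in loci
                }
            mg = genotypes[ind.mother_id]
            sg = sires[ind.mother_id]
            for locus in loci:
                g[locus] = normalize_pair(
                    mg[locus][int(rng.integers(2))], sg[locus][int(rng.integers(2))]
                )
        genotypes[ind.individual_id] = g
    return genotypes


def _corrupt_genotype(
    g: Mapping[str, tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    for locus, (a, b) in g.items():
        if rng.random() < config.missing_locus_rate:
            out[locus] = (MISSING, MISSING)
            continue
        if a != b and rng.random() < config.dropout_rate:
            keep = a if rng.random() < 0.5 else b
            a = b = keep
        if rng.random() < config.false_allele_rate:
            # dinucleotide stutter: shift one allele by +-2 repeat units
            shift = int(rng.choice([-2, 2]))
            if rng.random() < 0.5:
                a = a + shift
            else:
                b = b + shift
        out[locus] = normalize_pair(a, b)
    return out


def _true_marker_pattern(sex: str) -> dict[str, str]:
    if sex == "male":
        return {"SRY": "+", "AMELY": "+", "PLP1": "+"}
    return {"SRY": "-", "AMELY": "-", "PLP1": "+"}


def detection_probability(pop: TruePopulation, config: SimulationConfig) -> np.ndarray:
    """Analytic per-individual probability of at least one detection."""
    centers = np.array([ind.center for ind in pop.individuals], dtype=float)
    if len(centers) == 0:
        return np.zeros(0)
    points = np.array([p for p, _ in config.visit_schedule], dtype=float)
    d = np.hypot(
        centers[:, 0:1] - points[None, :, 0], centers[:, 1:2] - points[None, :, 1]
    )
    total_rate = config.lambda0 * np.exp(-d / config.sigma).sum(axis=1)
    return 1.0 - np.exp(-total_rate)


def expected_detected(pop: TruePopulation, config: SimulationConfig) -> float:
    """Expected number of distinct individuals detected at least once."""
    return float(detection_probability(pop, config).sum())


def simulate_survey(
    pop: TruePopulation,
    genotypes: Mapping[str, Mapping[str, tuple[int, int]]],
    config: SimulationConfig,
    return_truth: bool = False,
) -> list[SampleRecord] | tuple[list[SampleRecord], dict[str, str]]:
    """Run the dung survey over the visit schedule.

    Per visit and individual, the number of collected samples is Poisson
    with mean lambda0 * exp(-d / sigma), d the center-to-point distance.
    Same-visit samples from one social group share a jittered anchor and
    are placed within the group-spread radius of one another, giving the
    sociality stage its co-deposition signal. Each group's passage past a
    sampling point is a distinct deposition event, so its samples carry a
    cohort-specific freshness label: field crews judge deposition age, and
    two groups do not transit the same transect at the same moment. The
    association rule's same-age requirement therefore separates groups
    that happen to be collected at one point on one day. Observed
    genotypes pass through the error channel; sex markers and the
    haplotype label carry their own failure modes.

    With ``return_truth`` the sample-to-individual map is returned
    alongside the records, for recovery tests against the ground truth.
    """
    if not config.visit_schedule:
        raise ValueError("visit_schedule must be non-empty")
    rng = _rng(config.seed, "survey")
    centers = np.array([ind.center for ind in pop.individuals], dtype=float)
    records: list[SampleRecord] = []
    truth: dict[str, str] = {}
    counter = 0
    for visit_idx, ((px, py), visit_date) in enumerate(config.visit_schedule):
        if len(centers) == 0:
            continue
        d = np.hypot(centers[:, 0] - px, centers[:, 1] - py)
        lam = config.lambda0 * np.exp(-d / config.sigma)
        counts = rng.poisson(lam)
        hit = np.nonzero(counts)[0]
        if hit.size == 0:
            continue
        anchors: dict[int, tuple[float, float]] = {}
        for i in hit:
            ind = pop.individuals[int(i)]
            if ind.group_id not in anchors:
                anchors[ind.group_id] = (
                    px + float(rng.normal(0, config.jitter_sd)),
                    py + float(rng.normal(0, config.jitter_sd)),
                )
            ax, ay = anchors[ind.group_id]
            for _ in range(int(counts[i])):
                counter += 1
                theta = rng.uniform(0, 2 * np.pi)
                r = config.group_spread / 2.0 * np.sqrt(rng.uniform())
                sx, sy = ax + r * np.cos(theta), ay + r * np.sin(theta)
                markers = _true_marker_pattern(ind.sex)
                for m in markers:
                    if markers[m] == "+" and rng.random() < config.sex_marker_failure_rate:
                        markers[m] = "-"
                hap: str | None = f"H{ind.haplotype_id}"
                if rng.random() < config.haplotype_missing_rate:
                    hap = None
                truth[f"S{counter:05d}"] = ind.individual_id
                records.append(
                    SampleRecord(
                        sample_id=f"S{counter:05d}",
                        date=visit_date,
                        x=float(sx),
                        y=float(sy),
                        genotype=_corrupt_genotype(genotypes[ind.individual_id], config, rng),
                        sex_markers=markers,
                        haplotype=hap,
                        freshness_class=f"cohort-{visit_idx}-{ind.group_id}",
                    )
                )
    if return_truth:
        return records, truth
    return records


def sample_truth(
    pop: TruePopulation,
    genotypes: Mapping[str, Mapping[str, tuple[int, int]]],
    config: SimulationConfig,
    records: Sequence[SampleRecord],
) -> dict:
    """Ground-truth bundle (JSON-serializable) for recovery tests."""
    return {
        "seed": config.seed,
        "true_density": config.true_density,
        "buffered_area_km2": config.buffered_area_km2,
        "n_individuals": len(pop),
        "n_groups": len(pop.groups()),
        "n_samples": len(records),
        "lambda0": config.lambda0,
        "sigma": config.sigma,
        "individuals": [
            {
                "id": ind.individual_id,
                "sex": ind.sex,
                "x": ind.center[0],
                "y": ind.center[1],
                "haplotype": f"H{ind.haplotype_id}",
                "mother": ind.mother_id,
                "group": ind.group_id,
            }
            for ind in pop.individuals
        ],
    }


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def haplotype_sequences(config: SimulationConfig, length: int = 600) -> dict[str, str]:
    """Synthetic control-region haplotype sequences, one per haplotype ID.

    Haplotype k differs from the reference at 2k fixed positions, so all
    sequences are distinct and collapse to exactly ``n_haplotypes`` classes.
    """
    rng = _rng(config.seed, "haplotype_seqs")
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=length)
    seqs: dict[str, str] = {}
    for k in range(config.n_haplotypes):
        seq = ref.copy()
        pos = rng.choice(length, size=2 * k, replace=False) if k else np.array([], dtype=int)
        for p in pos:
            seq[p] = (seq[p] + 1 + rng.integers(3)) % 4
        seqs[f"H{k + 1}"] = "".join(bases[seq])
    return seqs


def write_haplotype_fasta(config: SimulationConfig, records: Sequence[SampleRecord], path: str | Path) -> None:
    """FASTA with one entry per sample that has a haplotype label."""
    seqs = haplotype_sequences(config)
    with open(path, "w") as fh:
        for r in records:
            if r.haplotype is not None and r.haplotype in seqs:
                fh.write(f">{r.sample_id}\n{seqs[r.haplotype]}\n")


__all__ = [
    "SimulationConfig",
    "TrueIndividual",
    "TruePopulation",
    "default_allele_frequencies",
    "default_grid",
    "default_visit_schedule",
    "detection_probability",
    "expected_detected",
    "haplotype_sequences",
    "sample_truth",
    "simulate_genotypes",
    "simulate_population",
    "simulate_survey",
    "write_haplotype_fasta",
    "write_truth",
]
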