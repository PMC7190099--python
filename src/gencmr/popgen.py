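"""Population-genetic statistics for microsatellite panels.

Implements the descriptive and inferential statistics used to qualify a
marker panel for individual identification and kinship work: per-locus
allele frequencies and diversity (Na, Ne, Ho, He, unbiased He, Fis),
probability-of-identity measures, a Monte-Carlo exact test of
Hardy-Weinberg equilibrium, genotyping-error rates from replicated
individuals, the Queller-Goodnight pairwise relatedness estimator, and
maximum-likelihood kinship classification.

All estimators operate on identified individuals rather than raw samples:
repeated captures of one animal would otherwise pseudoreplicate its
genotype and bias allele frequencies toward heavily resampled individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING

Genotype = Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class LocusFrequencies:
    locus: str
    freqs: dict[int, float]
    n: int  # diploid individuals typed at this locus

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus}: frequencies sum to {total}, not 1")
        if self.n < 1:
            raise ValueError(f"{self.locus}: n must be >= 1")


def allele_frequencies(genotypes: Sequence[Genotype], locus: str) -> LocusFrequencies:
    """Sample allele frequencies at one locus; missing loci excluded."""
    counts: dict[int, int] = {}
    n = 0
    for g in genotypes:
        a, b = g.get(locus, (MISSING, MISSING))
        if a == MISSING:
            continue
        n += 1
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    if n == 0:
        raise ValueError(f"no individuals typed at locus {locus}")
    total = 2 * n
    return LocusFrequencies(locus, {a: c / total for a, c in sorted(counts.items())}, n)


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    Na: int
    Ne: float
    Ho: float
    He: float
    UHe: float
    Fis: float | None  # None when the locus is monomorphic
    hwe_p: float | None = None


def locus_diversity(freqs: LocusFrequencies, genotypes: Sequence[Genotype]) -> LocusDiversity:
    """Standard per-locus diversity summary.

    Ne = 1 / sum(p^2); He = 1 - sum(p^2); UHe = 2n/(2n-1) * He;
    Ho = fraction of typed individuals that are heterozygous;
    Fis = (He - Ho) / He, undefined for a monomorphic locus.
    """
    p = np.array(list(freqs.freqs.values()))
    sum_p2 = float((p**2).sum())
    he = 1.0 - sum_p2
    n = freqs.n
    n_het = sum(
        1
        for g in genotypes
        if g.get(freqs.locus, (MISSING, MISSING))[0] != MISSING
        and g[freqs.locus][0] != g[freqs.locus][1]
    )
    ho = n_het / n
    return LocusDiversity(
        locus=freqs.locus,
        Na=len(p),
        Ne=1.0 / sum_p2,
        Ho=ho,
        He=he,
        UHe=(2 * n) / (2 * n - 1) * he if n > 0 else he,
        Fis=(he - ho) / he if he > 0 else None,
    )


def diversity_table(genotypes: Sequence[Genotype], loci: Sequence[str], hwe_seed: int | None = None) -> pd.DataFrame:
    """Per-locus diversity report (one row per locus plus mean/sd rows)."""
    rows = []
    for locus in loci:
        f = allele_frequencies(genotypes, locus)
        d = locus_diversity(f, genotypes)
        p_hwe = None
        if hwe_seed is not None and d.Na >= 2:
            p_hwe = hwe_exact(genotype_counts(genotypes, locus), seed=hwe_seed).p
        rows.append(
            {"locus": locus, "Na": d.Na, "Ne": d.Ne, "Ho": d.Ho, "He": d.He,
             "UHe": d.UHe, "Fis": d.Fis, "HWE_p": p_hwe}
        )
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Probability of identity


@dataclass(frozen=True)
class PidResult:
    loci: list[str]
    pid_locus: list[float]
    pidsib_locus: list[float]
    pid_cumulative: list[float]
    pidsib_cumulative: list[float]


def pid_sib(freqs: Sequence[LocusFrequencies]) -> PidResult:
    """Per-locus and cumulative P(ID) and sibling P(ID).

    Per locus, with allele frequencies p_i:
    P(ID)    = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2
    P(ID)sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4
    Cumulative values are running products in the order given, so callers
    control the locus ordering (most informative first, typically).
    """
    if not freqs:
        raise ValueError("at least one locus required")
    loci, pid_l, sib_l = [], [], []
    for f in freqs:
        p = np.array(list(f.freqs.values()))
        s2 = float((p**2).sum())
        s4 = float((p**4).sum())
        pid = s4 + 2 * (s2**2 - s4)  # sum_{i<j} (2 p_i p_j)^2 = 2 (s2^2 - s4)
        sib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        loci.append(f.locus)
        pid_l.append(pid)
        sib_l.append(sib)
    return PidResult(
        loci=loci,
        pid_locus=pid_l,
        pidsib_locus=sib_l,
        pid_cumulative=list(np.cumprod(pid_l)),
        pidsib_cumulative=list(np.cumprod(sib_l)),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)


def genotype_counts(genotypes: Sequence[Genotype], locus: str) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for g in genotypes:
        a, b = g.get(locus, (MISSING, MISSING))
        if a == MISSING:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def _table_logprob_variable(pairs: np.ndarray) -> float:
    """Variable part of log P(genotype table | allele counts) under HWE.

    Guo & Thompson conditional probability: P = n! 2^H prod_a(m_a!) /
    ((2n)! prod_{i<=j} n_ij!). Given fixed allele counts only
    H log 2 - sum log n_ij! varies across tables.
    """
    a = np.minimum(pairs[:, 0], pairs[:, 1])
    b = np.maximum(pairs[:, 0], pairs[:, 1])
    h = int((a != b).sum())
    key = a.astype(np.int64) * 1_000_003 + b.astype(np.int64)
    _, counts = np.unique(key, return_counts=True)
    return h * math.log(2.0) - float(gammaln(counts + 1).sum())


@dataclass(frozen=True)
class HweResult:
    p: float
    se: float
    batches: int
    iterations: int


def hwe_exact(
    counts: Mapping[tuple[int, int], int],
    batches: int = 100,
    iterations: int = 1000,
    seed: int = 0,
) -> HweResult:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    Genotype tables are sampled conditional on the observed allele counts
    by randomly re-pairing the allele vector; the p-value is the fraction
    of sampled tables whose conditional probability does not exceed the
    observed table's. The batch structure yields a Monte-Carlo standard
    error on p. A monomorphic locus returns p = 1 by convention.
    """
    alleles: list[int] = []
    for (a, b), c in counts.items():
        alleles += [a, b] * c
    pool = np.array(alleles)
    if len(np.unique(pool)) < 2:
        return HweResult(p=1.0, se=0.0, batches=batches, iterations=iterations)
    obs = np.array([[a, b] for (a, b), c in counts.items() for _ in range(c)])
    obs_lp = _table_logprob_variable(obs)
    rng = np.random.default_rng(seed)
    tol = 1e-9
    batch_props = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iterations):
            perm = rng.permutation(pool)
            lp = _table_logprob_variable(perm.reshape(-1, 2))
            if lp <= obs_lp + tol:
                hits += 1
        batch_props[b] = hits / iterations
    p = float(batch_props.mean())
    se = float(batch_props.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return HweResult(p=p, se=se, batches=batches, iterations=iterations)


def hwe_enumerate(counts: Mapping[tuple[int, int], int]) -> float:
    """Exhaustive exact HWE p-value for small two-allele tables.

    Enumerates every heterozygote count compatible with the allele counts;
    the independent oracle for the Monte-Carlo test.
    """
    pool: dict[int, int] = {}
    n = 0
    n_het_obs = 0
    for (a, b), c in counts.items():
        pool[a] = pool.get(a, 0) + c
        pool[b] = pool.get(b, 0) + c
        n += c
        if a != b:
            n_het_obs += c
    if len(pool) != 2:
        raise ValueError("enumeration oracle supports exactly 2 alleles")
    m1 = min(pool.values())
    # heterozygote count shares parity with m1 and cannot exceed min allele count
    probs = {}
    for h in range(m1 % 2, m1 + 1, 2):
        n11 = (m1 - h) // 2
        n22 = n - n11 - h
        if n22 < 0:
            continue
        lp = h * math.log(2.0) - (gammaln(n11 + 1) + gammaln(h + 1) + gammaln(n22 + 1))
        probs[h] = lp
    lps = np.array(list(probs.values()))
    ws = np.exp(lps - lps.max())
    ws /= ws.sum()
    obs_lp = probs[n_het_obs]
    return float(ws[lps <= obs_lp + 1e-9].sum())


def bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Flag p_i as significant iff p_i <= alpha / m."""
    if len(pvalues) == 0:
        raise ValueError("at least one p-value required")
    threshold = alpha / len(pvalues)
    return [p <= threshold for p in pvalues]


# ---------------------------------------------------------------------------
# Genotyping-error rates from replicated individuals


@dataclass(frozen=True)
class ErrorRates:
    dropout: float | None  # None when no heterozygous observations exist
    false_allele: float | None
    n_het_obs: int
    n_obs: int


def error_rates(
    groups: Sequence[tuple[Genotype, Sequence[Genotype]]],
    loci: Sequence[str],
) -> dict[str, ErrorRates]:
    """Per-locus allelic-dropout and false-allele rates.

    ``groups`` pairs each consensus genotype with its replicate sample
    genotypes. Dropout rate: observations of a consensus-heterozygous
    locus recorded homozygous for one consensus allele, over all
    observations of consensus-heterozygous loci. False-allele rate:
    observations containing an allele absent from the consensus, over all
    locus observations. With no replicated individuals the rates are
    undefined (``None``), not zero.
    """
    replicated = [(c, s) for c, s in groups if len(s) >= 2]
    out: dict[str, ErrorRates] = {}
    for locus in loci:
        het_obs = dropouts = false = total = 0
        for consensus, samples in replicated:
            ca, cb = consensus.get(locus, (MISSING, MISSING))
            if ca == MISSING:
                continue
            for s in samples:
                a, b = s.get(locus, (MISSING, MISSING))
                if a == MISSING:
                    continue
                total += 1
                if ca != cb:
                    het_obs += 1
                    if a == b and a in (ca, cb):
                        dropouts += 1
                if a not in (ca, cb) or b not in (ca, cb):
                    false += 1
        out[locus] = ErrorRates(
            dropout=dropouts / het_obs if het_obs else None,
            false_allele=false / total if total else None,
            n_het_obs=het_obs,
            n_obs=total,
        )
    return out


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness


def _qg_terms(gx: tuple[int, int], gy: tuple[int, int], freqs: Mapping[int, float]) -> tuple[float, float]:
    """Numerator and denominator with x as the reference individual."""
    a, b = gx
    c, d = gy
    pa = freqs.get(a, 0.0)
    pb = freqs.get(b, 0.0)
    shared = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = shared - pa - pb
    den = 1.0 + (a == b) - pa - pb
    return num, den


def qg_relatedness(
    g1: Genotype,
    g2: Genotype,
    freqs: Mapping[str, LocusFrequencies],
) -> float | None:
    """Symmetrized Queller-Goodnight relatedness over shared typed loci.

    Numerators and denominators are summed across loci (and across the two
    choices of reference individual) before the final division; a pair
    with no shared typed loci is undefined and returns ``None``.
    """
    num = den = 0.0
    shared = 0
    for locus, f in freqs.items():
        ga = g1.get(locus, (MISSING, MISSING))
        gb = g2.get(locus, (MISSING, MISSING))
        if ga[0] == MISSING or gb[0] == MISSING:
            continue
        shared += 1
        n1, d1 = _qg_terms(ga, gb, f.freqs)
        n2, d2 = _qg_terms(gb, ga, f.freqs)
        num += n1 + n2
        den += d1 + d2
    if shared == 0 or den == 0.0:
        return None
    return num / den


def qg_matrix(
    genotypes: Sequence[Genotype],
    freqs: Mapping[str, LocusFrequencies],
) -> np.ndarray:
    """Symmetric pairwise relatedness matrix; diagonal NaN; undefined pairs NaN."""
    n = len(genotypes)
    r = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            v = qg_relatedness(genotypes[i], genotypes[j], freqs)
            if v is not None:
                r[i, j] = r[j, i] = v
    return r


# ---------------------------------------------------------------------------
# Maximum-likelihood kinship classification

#: IBD-coefficient triples (k0, k1, k2) per relationship category.
KINSHIP_CLASSES: dict[str, tuple[float, float, float]] = {
    "unrelated": (1.0, 0.0, 0.0),
    "half-sib": (0.5, 0.5, 0.0),
    "full-sib": (0.25, 0.5, 0.25),
    "parent-offspring": (0.0, 1.0, 0.0),
}

#: Kinship order classes used for social-network edge weighting.
FIRST_ORDER = frozenset({"parent-offspring", "full-sib"})
SECOND_ORDER = frozenset({"half-sib"})


def _hwe_prob(g: tuple[int, int], p: Mapping[int, float]) -> float:
    a, b = g
    pa, pb = p.get(a, 0.0), p.get(b, 0.0)
    return pa * pa if a == b else 2 * pa * pb


def _one_ibd_transition(g1: tuple[int, int], g2: tuple[int, int], p: Mapping[int, float]) -> float:
    """P(G2 | G1, exactly one allele shared identical by descent)."""
    a, b = g1
    c, d = g2
    pc, pd = p.get(c, 0.0), p.get(d, 0.0)
    if a == b:  # G1 homozygous aa
        if c == d:
            return pc if c == a else 0.0
        if c == a:
            return pd
        if d == a:
            return pc
        return 0.0
    # G1 heterozygous ab: the transmitted allele is a or b with prob 1/2
    if c == d:
        if c == a or c == b:
            return 0.5 * pc
        return 0.0
    t = 0.0
    if c == a or c == b:
        t += 0.5 * pd
    if d == a or d == b:
        t += 0.5 * pc
    return t


@dataclass(frozen=True)
class KinshipResult:
    category: str
    order: str  # "first" | "second" | "none"
    loglik: dict[str, float]
    n_loci: int


def ml_kinship(
    g1: Genotype,
    g2: Genotype,
    freqs: Mapping[str, LocusFrequencies],
) -> KinshipResult | None:
    """Classify a dyad into unrelated / half-sib / full-sib / parent-offspring.

    Per shared typed locus the genotype-pair likelihood under IBD
    coefficients (k0, k1, k2) is
    k0 P(G1) P(G2) + k1 P(G1) T(G1 -> G2) + k2 P(G1) [G1 == G2],
    with T the one-allele-IBD transition probability. Log-likelihoods sum
    over loci; the category with the maximum total wins (ties broken
    toward the less related category, listed order). Pairs sharing no
    typed locus are undefined.
    """
    logliks = {name: 0.0 for name in KINSHIP_CLASSES}
    shared = 0
    for locus, f in freqs.items():
        ga = g1.get(locus, (MISSING, MISSING))
        gb = g2.get(locus, (MISSING, MISSING))
        if ga[0] == MISSING or gb[0] == MISSING:
            continue
        shared += 1
        p = f.freqs
        p1 = _hwe_prob(ga, p)
        p0 = p1 * _hwe_prob(gb, p)
        pt = p1 * _one_ibd_transition(ga, gb, p)
        p2 = p1 if ga == gb else 0.0
        for name, (k0, k1, k2) in KINSHIP_CLASSES.items():
            lik = k0 * p0 + k1 * pt + k2 * p2
            logliks[name] += math.log(lik) if lik > 0 else -math.inf
    if shared == 0:
        return None
    best = max(logliks, key=lambda k: (logliks[k], -list(KINSHIP_CLASSES).index(k)))
    order = "first" if best in FIRST_ORDER else "second" if best in SECOND_ORDER else "none"
    return KinshipResult(category=best, order=order, loglik=logliks, n_loci=shared)


__all__ = [
    "ErrorRates",
    "FIRST_ORDER",
    "HweResult",
    "KINSHIP_CLASSES",
    "KinshipResult",
    "LocusDiversity",
    "LocusFrequencies",
    "PidResult",
    "SECOND_ORDER",
    "allele_frequencies",
    "bonferroni",
    "diversity_table",
    "error_rates",
    "genotype_counts",
    "hwe_enumerate",
    "hwe_exact",
    "locus_diversity",
    "ml_kinship",
    "pid_sib",
    "qg_matrix",
    "qg_relatedness",
]
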