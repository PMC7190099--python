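"""Capture-class abundance models for genetic capture-recapture.

Population size is estimated from the capture-class spectrum (how many
individuals were captured once, twice, ...) under multinomial-allocation
models in which s capture events fall independently on N individuals:

* ECM  — equal capture: every individual has the same capture weight.
  logL(N) = log C(N, k) - s log N, maximized over integer N.
* TIRM — two innate rates: individuals captured once form a low-rate
  class A, individuals captured more than once a high-rate class B whose
  capture weight is alpha >= 1 times class A's; all unobserved
  individuals belong to class A. alpha is estimated by a two-stage
  moment/refit scheme (below), because the joint profile likelihood in
  (N, alpha) is unbounded along alpha with N: rate heterogeneity and
  population size are not jointly identifiable from a single spectrum.
* TIRMpart — partitioned TIRM: an extreme high-capture class is split
  off by a three-class version of the same likelihood, removed from the
  data, TIRM is refitted to the remainder, and the removed individuals
  are added back to the point estimate.

The two-stage alpha estimate: start from the observed rate ratio
alpha0 = (s_B/k_B)/(s_A/k_A), maximize over N; then correct class A's
mean rate for the individuals that were never captured,
alpha1 = (s_B/k_B)/(s_A/(N1-k_B)), and maximize over N once more.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy.special import gammaln

from .identify import CaptureSpectrum


@dataclass(frozen=True)
class AbundanceFit:
    model: str  # "ECM" | "TIRM" | "TIRMpart"
    n_hat: int
    alpha: float | None
    loglik: float
    k: int
    s: int
    maxpop: int
    class_a: tuple[int, int] = (0, 0)  # (individuals, events) in the low class
    class_b: tuple[int, int] = (0, 0)
    excluded: tuple[int, int] = (0, 0)  # removed third class (TIRMpart)
    boundary: bool = False
    ci: tuple[int, int] | None = None
    ci_unreliable: bool = False

    def __post_init__(self) -> None:
        if not self.k <= self.n_hat <= self.maxpop:
            raise ValueError("n_hat outside [k, maxpop]")


def _counts(spectrum: CaptureSpectrum) -> np.ndarray:
    return np.concatenate(
        [np.full(m, c, dtype=int) for c, m in sorted(spectrum.counts.items())]
    ) if spectrum.counts else np.zeros(0, dtype=int)


def _check(spectrum: CaptureSpectrum) -> tuple[int, int]:
    k, s = spectrum.k, spectrum.s
    if k < 1:
        raise ValueError("empty spectrum")
    if s < k:
        raise ValueError(f"impossible spectrum: s={s} < k={k}")
    return k, s


def two_class_loglik(
    n: np.ndarray | int,
    alpha: float,
    ka: int,
    sa: int,
    kb: int,
    sb: int,
) -> np.ndarray | float:
    """log-likelihood of a two-weight allocation at population size ``n``.

    Class B (weight alpha) is fully observed; class A holds the remaining
    ka observed plus all n - ka - kb unobserved individuals.
    """
    n = np.asarray(n, dtype=float)
    s = sa + sb
    na = n - kb
    ll = (
        gammaln(na + 1) - gammaln(na - ka + 1) - gammaln(ka + 1)
        + (sb * np.log(alpha) if kb else 0.0)
        - s * np.log(na + alpha * kb)
    )
    return ll


def _argmax_n(alpha: float, ka: int, sa: int, kb: int, sb: int, maxpop: int) -> tuple[int, float]:
    k = ka + kb
    ns = np.arange(k, maxpop + 1)
    ll = two_class_loglik(ns, alpha, ka, sa, kb, sb)
    j = int(np.argmax(ll))  # ties break toward the smaller N
    return int(ns[j]), float(ll[j])


def fit_ecm(spectrum: CaptureSpectrum, maxpop: int = 10000) -> AbundanceFit:
    """Equal-capture-model MLE by exhaustive integer search over [k, maxpop]."""
    k, s = _check(spectrum)
    n_hat, ll = _argmax_n(1.0, k, s, 0, 0, maxpop)
    return AbundanceFit(
        model="ECM", n_hat=n_hat, alpha=None, loglik=ll, k=k, s=s,
        maxpop=maxpop, class_a=(k, s), boundary=n_hat == maxpop,
    )


def _split_once_repeat(counts: np.ndarray) -> tuple[int, int, int, int]:
    a = counts[counts == 1]
    b = counts[counts > 1]
    return len(a), int(a.sum()), len(b), int(b.sum())


def fit_tirm(spectrum: CaptureSpectrum, maxpop: int = 10000) -> AbundanceFit:
    """Two-innate-rates MLE with the two-stage alpha estimate.

    With no repeated captures (or no singletons) the model degenerates to
    ECM: alpha = 1 and the log-likelihood equals the ECM value.
    """
    k, s = _check(spectrum)
    counts = _counts(spectrum)
    ka, sa, kb, sb = _split_once_repeat(counts)
    if kb == 0 or ka == 0:
        ecm = fit_ecm(spectrum, maxpop)
        return replace(ecm, model="TIRM", alpha=1.0, class_a=(ka, sa), class_b=(kb, sb))
    alpha0 = (sb / kb) / (sa / ka)
    n1, _ = _argmax_n(alpha0, ka, sa, kb, sb, maxpop)
    alpha1 = max(1.0, (sb / kb) / (sa / (n1 - kb)))
    n2, ll = _argmax_n(alpha1, ka, sa, kb, sb, maxpop)
    return AbundanceFit(
        model="TIRM", n_hat=n2, alpha=alpha1, loglik=ll, k=k, s=s,
        maxpop=maxpop, class_a=(ka, sa), class_b=(kb, sb), boundary=n2 == maxpop,
    )


def three_class_partitions(values: list[int]) -> Iterator[tuple[list[int], list[int], list[int]]]:
    """All contiguous splits of sorted count values into three nonempty classes."""
    values = sorted(values)
    for a in range(len(values) - 2):
        for b in range(a + 1, len(values) - 1):
            yield values[: a + 1], values[a + 1 : b + 1], values[b + 1 :]


def _three_class_fit(
    counts: np.ndarray,
    low: list[int],
    mid: list[int],
    high: list[int],
    maxpop: int,
) -> tuple[int, float, tuple[float, float]]:
    """Two-stage fit of the three-weight allocation for one partition."""
    s = int(counts.sum())
    g1 = counts[np.isin(counts, low)]
    g2 = counts[np.isin(counts, mid)]
    g3 = counts[np.isin(counts, high)]
    k1, s1 = len(g1), int(g1.sum())
    k2, s2 = len(g2), int(g2.sum())
    k3, s3 = len(g3), int(g3.sum())
    k = k1 + k2 + k3
    ns = np.arange(k, maxpop + 1)

    def ll_over_n(a2: float, a3: float) -> np.ndarray:
        na = ns - k2 - k3
        return (
            gammaln(na + 1) - gammaln(na - k1 + 1) - gammaln(k1 + 1)
            + s2 * np.log(a2) + s3 * np.log(a3)
            - s * np.log(na + a2 * k2 + a3 * k3)
        )

    r1 = s1 / k1
    a2, a3 = (s2 / k2) / r1, (s3 / k3) / r1
    n1 = int(ns[np.argmax(ll_over_n(a2, a3))])
    r1 = s1 / (n1 - k2 - k3)
    a2, a3 = max(1.0, (s2 / k2) / r1), max(1.0, (s3 / k3) / r1)
    ll = ll_over_n(a2, a3)
    j = int(np.argmax(ll))
    return int(ns[j]), float(ll[j]), (a2, a3)


def best_three_class_partition(
    spectrum: CaptureSpectrum, maxpop: int = 10000
) -> tuple[list[int], list[int], list[int], float] | None:
    """Highest-likelihood contiguous three-class partition, or None if < 3 classes."""
    values = sorted(spectrum.counts)
    if len(values) < 3:
        return None
    counts = _counts(spectrum)
    best = None
    for low, mid, high in three_class_partitions(values):
        _, ll, _ = _three_class_fit(counts, low, mid, high, maxpop)
        if best is None or ll > best[3]:
            best = (low, mid, high, ll)
    return best


def fit_tirmpart(spectrum: CaptureSpectrum, maxpop: int = 10000) -> AbundanceFit:
    """Partitioned TIRM.

    The best contiguous three-class partition of the spectrum identifies
    an extreme high-capture class; its individuals are removed, TIRM is
    refitted to the remaining spectrum, and the removed count is added
    back to the point estimate. With fewer than three distinct capture
    counts (nothing to split) the result is plain TIRM. The reported
    log-likelihood is the refitted TIRM's, i.e. it refers to the reduced
    data and is not comparable with fits to the full spectrum.
    """
    _check(spectrum)
    part = best_three_class_partition(spectrum, maxpop)
    if part is None:
        fit = fit_tirm(spectrum, maxpop)
        return replace(fit, model="TIRMpart")
    low, mid, high, _ = part
    removed_k = sum(spectrum.counts[v] for v in high)
    removed_s = sum(v * spectrum.counts[v] for v in high)
    reduced = CaptureSpectrum({v: c for v, c in spectrum.counts.items() if v not in high})
    fit = fit_tirm(reduced, maxpop)
    n_hat = fit.n_hat + removed_k
    return AbundanceFit(
        model="TIRMpart", n_hat=n_hat, alpha=fit.alpha, loglik=fit.loglik,
        k=spectrum.k, s=spectrum.s, maxpop=max(maxpop, n_hat),
        class_a=fit.class_a, class_b=fit.class_b,
        excluded=(removed_k, removed_s), boundary=fit.boundary,
    )


FITTERS = {"ECM": fit_ecm, "TIRM": fit_tirm, "TIRMpart": fit_tirmpart}


# ---------------------------------------------------------------------------
# Parametric bootstrap


def simulate_spectrum(
    n: int,
    s: int,
    rng: np.random.Generator,
    alpha: float = 1.0,
    n_high: int = 0,
) -> CaptureSpectrum:
    """Simulate a capture-class spectrum: s events multinomially allocated
    over n individuals, n_high of which carry weight alpha; unobserved
    individuals drop out of the spectrum."""
    w = np.ones(n)
    if n_high:
        w[:n_high] = alpha
    counts = rng.multinomial(s, w / w.sum())
    observed = counts[counts > 0]
    vals, freqs = np.unique(observed, return_counts=True)
    return CaptureSpectrum({int(v): int(c) for v, c in zip(vals, freqs)})


def _simulate_from_fit(fit: AbundanceFit, s: int, rng: np.random.Generator) -> CaptureSpectrum:
    if fit.model == "ECM":
        return simulate_spectrum(fit.n_hat, s, rng)
    return simulate_spectrum(fit.n_hat, s, rng, alpha=fit.alpha or 1.0, n_high=fit.class_b[0])


def bootstrap_ci(
    fit: AbundanceFit,
    spectrum: CaptureSpectrum,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> AbundanceFit:
    """Percentile parametric-bootstrap CI for the point estimate.

    Spectra are simulated from the fitted model holding the observed
    number of events s fixed (sampling effort is conditioned on), refitted
    with the same model, and the (1 +- level)/2 percentiles of the
    refitted estimates form the interval. A fit at the maxpop boundary
    yields a CI flagged unreliable.
    """
    rng = np.random.default_rng(seed)
    fitter = FITTERS[fit.model]
    estimates = np.empty(n_boot)
    for i in range(n_boot):
        sim = _simulate_from_fit(fit, spectrum.s, rng)
        estimates[i] = fitter(sim, fit.maxpop).n_hat
    lo, hi = np.percentile(estimates, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    unreliable = fit.boundary or bool((estimates >= fit.maxpop).mean() > 0.5)
    return replace(fit, ci=(int(lo), int(hi)), ci_unreliable=unreliable)


def lrt_models(
    fit0: AbundanceFit,
    fit1: AbundanceFit,
    spectrum: CaptureSpectrum,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap likelihood-ratio comparison of a nested model pair.

    LR is reported as logL(fit1) - logL(fit0) (the difference of maximized
    log-likelihoods). The null distribution comes from spectra simulated
    under fit0, each refitted with both models; p carries the +1/(n+1)
    finite-sample correction.
    """
    order = ["ECM", "TIRM", "TIRMpart"]
    if order.index(fit0.model) >= order.index(fit1.model):
        raise ValueError(f"{fit0.model} is not nested in {fit1.model}")
    lr_obs = fit1.loglik - fit0.loglik
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = _simulate_from_fit(fit0, spectrum.s, rng)
        l0 = FITTERS[fit0.model](sim, fit0.maxpop).loglik
        l1 = FITTERS[fit1.model](sim, fit1.maxpop).loglik
        if l1 - l0 >= lr_obs:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return lr_obs, p


def extrapolate_abundance(
    value: float,
    area_sampled_km2: float = 891.0,
    area_target_km2: float = 3585.0,
) -> int:
    """Scale an abundance linearly by area, truncating toward zero."""
    if area_sampled_km2 <= 0 or area_target_km2 <= 0:
        raise ValueError("areas must be positive")
    return int(value * area_target_km2 / area_sampled_km2)


def ecm_occupancy_estimate(k: int, s: int, maxpop: int = 10000) -> int:
    """Moment-style estimate: N minimizing |N(1 - (1 - 1/N)^s) - k|.

    The expected number of distinct individuals among s uniform draws from
    N is N(1 - (1 - 1/N)^s); this inverts that relation on the integers
    and serves as an independent check on the ECM MLE.
    """
    ns = np.arange(max(k, 1), maxpop + 1, dtype=float)
    expected = ns * (1.0 - (1.0 - 1.0 / ns) ** s)
    return int(ns[np.argmin(np.abs(expected - k))])


__all__ = [
    "AbundanceFit",
    "FITTERS",
    "best_three_class_partition",
    "bootstrap_ci",
    "ecm_occupancy_estimate",
    "extrapolate_abundance",
    "fit_ecm",
    "fit_tirm",
    "fit_tirmpart",
    "lrt_models",
    "simulate_spectrum",
    "three_class_partitions",
    "two_class_loglik",
]
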