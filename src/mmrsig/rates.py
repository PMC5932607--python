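"""Mutation-rate estimation for self-fertilizing mutation-accumulation lines.

A mutation arising in germ-cell generation g of a line propagated for G
generations passes through k = G - g rounds of selfing, in each of which a
heterozygous mutation is lost with probability 1/4, stays heterozygous with
probability 1/2, or fixes homozygous with probability 1/4.  Whole-genome
sequencing of the final animal detects both heterozygous and fixed
mutations, so the per-mutation detection probability is
2^-k + (1 - 2^-k)/2 = 1/2 + 2^-(k+1), and summing over the generation of
origin gives the detection factor

    f(G) = sum_{g=1..G} (1/2 + 2^-(G-g+1)) = G/2 + 1 - 2^-G.

With d germ-cell divisions per generation (15 for the C. elegans life
cycle) and genome length L, detected counts are Poisson with mean
mu * d * L * f(G), giving the closed-form maximum-likelihood estimate
mu_hat = sum(m_i) / (d * L * sum(f(G_i))) and an exact (Garwood) Poisson
confidence interval on the summed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: WBcel235 C. elegans genome length (bp).
WBCEL235_GENOME_LENGTH = 100_286_401

#: Germ-cell divisions per generation in the C. elegans life cycle.
DIVISIONS_PER_GENERATION = 15


@dataclass
class LineObservation:
    sample_id: str
    genotype: str
    generations: int  # G
    mutations: int  # m: substitutions + indels after duplicate filtering

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mutations < 0:
            raise ValueError("mutations must be >= 0")


@dataclass
class RateEstimate:
    mu_hat: float  # per bp per germ-cell division
    ci_low: float
    ci_high: float
    total_m: int
    denominator: float  # detection-weighted bp * divisions


def detection_factor(G: int) -> float:
    """Expected detected-mutation weight per unit rate over G generations,
    f(G) = G/2 + 1 - 2^-G; f(1) = 1 and f is strictly increasing."""
    if G < 1:
        raise ValueError("G must be >= 1")
    return G / 2.0 + 1.0 - 2.0 ** (-G)


def garwood_interval(m: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean given count m."""
    alpha = 1.0 - confidence
    low = 0.0 if m == 0 else stats.chi2.ppf(alpha / 2.0, 2 * m) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * m + 2) / 2.0
    return low, high


class SelfingRateEstimator:
    """Maximum-likelihood per-base-pair per-division mutation rate from
    mutation-accumulation line counts under selfing transmission.

    Parameters
    ----------
    genome_length : callable genome size L in bp (default WBcel235 total)
    divisions_per_generation : germ-cell divisions per generation d
    ci_method : "garwood" (exact Poisson, default) or "normal"
    confidence : CI level

    Attributes (after fit)
    ----------------------
    mu_hat_, ci_low_, ci_high_, total_m_, denominator_
    """

    def __init__(
        self,
        genome_length: float = WBCEL235_GENOME_LENGTH,
        divisions_per_generation: int = DIVISIONS_PER_GENERATION,
        ci_method: str = "garwood",
        confidence: float = 0.95,
    ):
        self.genome_length = genome_length
        self.divisions_per_generation = divisions_per_generation
        self.ci_method = ci_method
        self.confidence = confidence

    def get_params(self, deep: bool = True) -> dict:
        return {
            "genome_length": self.genome_length,
            "divisions_per_generation": self.divisions_per_generation,
            "ci_method": self.ci_method,
            "confidence": self.confidence,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, mutations: Sequence[int], generations: Sequence[int]):
        m = np.asarray(mutations, dtype=float)
        G = np.asarray(generations, dtype=int)
        if m.shape != G.shape or m.size == 0:
            raise ValueError("need one mutation count per line")
        if np.any(G < 1):
            raise ValueError("generations must be >= 1")
        f = np.array([detection_factor(int(g)) for g in G])
        denom = self.divisions_per_generation * self.genome_length * f.sum()
        total = float(m.sum())
        self.total_m_ = int(round(total))
        self.denominator_ = denom
        self.mu_hat_ = total / denom
        if self.ci_method == "garwood":
            lo, hi = garwood_interval(self.total_m_, self.confidence)
        elif self.ci_method == "normal":
            z = stats.norm.ppf(0.5 + self.confidence / 2.0)
            half = z * np.sqrt(total)
            lo, hi = max(total - half, 0.0), total + half
        else:
            raise ValueError(f"unknown ci_method: {self.ci_method}")
        self.ci_low_ = lo / denom
        self.ci_high_ = hi / denom
        return self

    def estimate_(self) -> RateEstimate:
        return RateEstimate(
            self.mu_hat_, self.ci_low_, self.ci_high_, self.total_m_, self.denominator_
        )


def estimate_rate(
    lines: Sequence[LineObservation],
    genome_length: float = WBCEL235_GENOME_LENGTH,
    divisions_per_generation: int = DIVISIONS_PER_GENERATION,
    ci_method: str = "garwood",
) -> RateEstimate:
    """Pooled rate estimate over a set of line observations.

    Lines of different generation numbers pool naturally: total counts over
    the summed detection-weighted denominator.
    """
    est = SelfingRateEstimator(genome_length, divisions_per_generation, ci_method)
    est.fit([l.mutations for l in lines], [l.generations for l in lines])
    return est.estimate_()


def expected_count(
    mu: float,
    G: int,
    genome_length: float = WBCEL235_GENOME_LENGTH,
    divisions_per_generation: int = DIVISIONS_PER_GENERATION,
) -> float:
    """Expected detected mutations in one line: mu * d * L * f(G)."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return mu * divisions_per_generation * genome_length * detection_factor(G)
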