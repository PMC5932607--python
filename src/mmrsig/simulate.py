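"""Synthetic data with known ground truth for every pipeline input.

Three generators:

* :func:`simulate_genome` — an i.i.d. background genome with controllable
  GC content and optionally boosted homopolymer census, plus the realized
  tract census as truth.
* :func:`simulate_ma_lines` — selfing mutation-accumulation lines: per
  generation, new mutations arise as Poisson(mu * d * L) events, and each
  passes through the remaining rounds of self-fertilization in which a
  heterozygous mutation is lost / stays heterozygous / fixes with
  probability 1/4 / 1/2 / 1/4.  Surviving (detected) mutations are placed
  on the genome respecting their channel's local context — substitutions at
  positions with the right trinucleotide, 1-bp indels inside homopolymer
  tracts with probability proportional to a length-bias curve — and emitted
  as VCF together with the true per-channel counts.
* :func:`simulate_cohort` — tumor catalogs as non-negative mixtures of
  known signatures: per-sample exposures are log-normal, a designated
  MMR-like signature is inflated in MSI-labelled samples, and channel
  counts are Poisson around the mixture.

Mutations are simulated at the generation level (one composite draw per
generation) rather than per individual germ-cell division; the detection
mathematics is identical.  Site collisions within a line are resolved by
rejection.  All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import channels as ch
from .io import VariantRecord
from .rates import DIVISIONS_PER_GENERATION
from .repeats import RepeatTract, find_repeats

# ---------------------------------------------------------------------------
# genome


def expected_iid_run_census(
    length: int, base_probs: Mapping[str, float], run_len: int
) -> float:
    """Expected number of maximal homopolymer runs of exactly ``run_len``
    bases in an i.i.d. sequence: ~ L * sum_b p_b^l (1 - p_b)^2."""
    return float(
        sum(length * p**run_len * (1.0 - p) ** 2 for p in base_probs.values())
    )


def simulate_genome(
    length: int,
    gc: float = 0.36,
    homopolymer_boost: Mapping[int, float] | None = None,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[dict[str, str], pd.Series]:
    """I.i.d. genome with optional homopolymer-census boosting.

    ``homopolymer_boost`` maps run length to a multiplier on the i.i.d.
    expected census; extra tracts are injected at random non-overlapping
    positions with non-matching flanks.  Returns the genome and the
    realized homopolymer census (truth).
    """
    if length < 10_000:
        raise ValueError("need length >= 10 kb for meaningful tract censuses")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    bases = np.array(list("ATCG"))
    p = np.array([probs[b] for b in "ATCG"])
    seq = rng.choice(bases, size=length, p=p)
    if homopolymer_boost:
        inject = []
        for run_len, boost in homopolymer_boost.items():
            n_extra = int(round((boost - 1.0) * expected_iid_run_census(length, probs, run_len)))
            inject.extend([run_len] * max(n_extra, 0))
        total_bp = sum(l + 2 for l in inject)
        if total_bp > length // 2:
            raise ValueError("infeasible boost: injected tracts exceed half the genome")
        used = np.zeros(length, dtype=bool)
        for run_len in inject:
            for _ in range(200):  # rejection sampling of a free slot
                start = int(rng.integers(1, length - run_len - 1))
                if not used[start - 1 : start + run_len + 1].any():
                    break
            else:
                continue
            base = bases[rng.choice(4, p=p)]
            seq[start : start + run_len] = base
            others = [b for b in "ACGT" if b != base]
            seq[start - 1] = rng.choice(others)
            seq[start + run_len] = rng.choice(others)
            used[start - 1 : start + run_len + 1] = True
    genome = {chrom: "".join(seq)}
    census = find_repeats(genome, 1).census()
    return genome, census


# ---------------------------------------------------------------------------
# defaults (synthetic stand-ins; shapes are loosely worm-like but arbitrary)


def default_worm_channel_probs() -> np.ndarray:
    """Synthetic 104-channel probability vector for MMR-deficient worm-like
    lines: ~75% indels (mostly 1-bp, A/T heavy), substitutions dominated by
    T>C and C>T with elevated A[T>A]T and G[C>T]N.  These are constructed
    constants, not measured data."""
    p = np.zeros(ch.N_CHANNELS)
    class_weight = {"C>A": 0.5, "C>G": 0.3, "C>T": 1.5, "T>A": 0.6, "T>C": 1.6, "T>G": 0.4}
    for i, label in enumerate(ch.SUBSTITUTION_CHANNELS):
        five, sub, three = label[0], label[2:5], label[6]
        w = class_weight[sub]
        if label == "A[T>A]T":
            w += 6.0
        if sub == "C>T" and five == "G":
            w *= 2.0
        p[i] = w
    p[: ch.N_SUBSTITUTION] *= 0.25 / p[: ch.N_SUBSTITUTION].sum()
    indel = {
        "del1_AT": 0.33,
        "ins1_AT": 0.29,
        "del1_CG": 0.025,
        "ins1_CG": 0.025,
        "del_2to5": 0.045,
        "ins_2to5": 0.020,
        "del_gt5": 0.010,
        "ins_gt5": 0.005,
    }
    for name, w in indel.items():
        p[ch.CHANNEL_INDEX[name]] = w
    return p / p.sum()


def default_length_bias(max_len: int = 20) -> dict[int, float]:
    """Per-tract 1-bp indel propensity by homopolymer length: rises steeply
    to length 10, then declines — a slippage-like shape."""
    bias = {}
    for l in range(4, max_len + 1):
        if l <= 10:
            bias[l] = float(np.exp(0.7 * (l - 4)))
        else:
            bias[l] = float(np.exp(0.7 * 6) * 0.8 ** (l - 10))
    return bias


# ---------------------------------------------------------------------------
# mutation-accumulation lines


@dataclass
class SimulatedLine:
    sample_id: str
    records: list[VariantRecord]
    true_counts: np.ndarray  # 104, detected mutations per channel
    n_arising: int
    n_detected: int


@dataclass
class SyntheticTruth:
    """Ground-truth parameters emitted alongside simulated data."""

    seed: int
    mu: float | None = None
    generations: int | None = None
    divisions: int = DIVISIONS_PER_GENERATION
    channel_probs: np.ndarray | None = None
    length_bias: dict[int, float] | None = None
    signatures: pd.DataFrame | None = None
    exposures: pd.DataFrame | None = None
    msi_labels: pd.Series | None = None
    extra: dict = field(default_factory=dict)


def detection_probability(k: int) -> float:
    """P(detected) after k rounds of selfing transmission: 1/2 + 2^-(k+1)."""
    return 0.5 + 2.0 ** (-(k + 1))


class _GenomePlacer:
    """Indexes a genome for context-respecting mutation placement."""

    def __init__(self, genome: Mapping[str, str], length_bias: Mapping[int, float]):
        self.genome = genome
        self.context_positions: dict[str, list[tuple[str, int]]] = {
            c: [] for c in ch.PYRIMIDINE_CONTEXTS
        }
        for chrom, seq in genome.items():
            for i in range(1, len(seq) - 1):
                tri = seq[i - 1 : i + 2]
                if any(b not in "ACGT" for b in tri):
                    continue
                self.context_positions[ch.collapse_trinucleotide(tri)].append((chrom, i))
        track = find_repeats(genome, 1)
        max_bias = max(length_bias)
        self.tracts: dict[str, list[RepeatTract]] = {"AT": [], "CG": []}
        self.tract_weights: dict[str, np.ndarray] = {}
        for t in track:
            cls = "AT" if t.unit in "AT" else "CG"
            self.tracts[cls].append(t)
        for cls, ts in self.tracts.items():
            self.tract_weights[cls] = np.array(
                [length_bias.get(min(t.tract_len, max_bias), 0.0) for t in ts]
            )

    def pick_substitution(self, channel: int, rng) -> tuple[str, int, str, str] | None:
        """Place a substitution channel; returns (chrom, pos0, ref, alt)."""
        label = ch.SUBSTITUTION_CHANNELS[channel]
        context = ch.context_of_channel(channel)
        alt = label[4]
        positions = self.context_positions[context]
        if not positions:
            return None
        chrom, i = positions[rng.integers(len(positions))]
        ref = self.genome[chrom][i]
        if ref != context[1]:  # purine strand: emit the reverse-complement event
            ref, alt = ch.reverse_complement(context[1]), ch.reverse_complement(alt)
        return chrom, i, ref, alt

    def pick_tract_position(self, base_class: str, kind: str, rng):
        """Pick a 1-bp indel site inside a homopolymer tract, weighted by
        the length-bias curve; falls back to any base of the class."""
        ts = self.tracts[base_class]
        w = self.tract_weights[base_class]
        if ts and w.sum() > 0:
            t = ts[rng.choice(len(ts), p=w / w.sum())]
            if kind == "del":
                pos0 = int(rng.integers(t.start, t.end))
            else:
                pos0 = t.start  # left-aligned insertion point
            return t.chrom, pos0, t.unit
        chrom = list(self.genome)[0]
        seq = self.genome[chrom]
        for _ in range(1000):
            pos0 = int(rng.integers(1, len(seq) - 1))
            if seq[pos0] in base_class:
                return chrom, pos0, seq[pos0]
        raise RuntimeError(f"no {base_class} base found in genome")


def _realize_mutation(
    channel: int,
    placer: _GenomePlacer,
    used: dict[str, set[int]],
    rng,
    sample_id: str,
) -> VariantRecord | None:
    genome = placer.genome
    label = ch.CHANNELS_104[channel]
    for _ in range(50):  # rejection on collisions
        if channel < ch.N_SUBSTITUTION:
            placed = placer.pick_substitution(channel, rng)
            if placed is None:
                return None
            chrom, i, ref, alt = placed
            span = range(i, i + 1)
            if any(p in used[chrom] for p in span):
                continue
            used[chrom].update(span)
            return VariantRecord(sample_id, chrom, i + 1, ref, alt)
        seq_len = {"1": 1, "2to5": int(rng.integers(2, 6)), "gt5": int(rng.integers(6, 21))}
        if label.startswith(("del1", "ins1")):
            kind = label[:3]
            base_class = label.split("_")[1]
            chrom, pos0, base = placer.pick_tract_position(base_class, kind, rng)
            if pos0 < 1:
                continue
            seq = genome[chrom]
            if kind == "del":
                span = range(pos0 - 1, pos0 + 2)
                if any(p in used[chrom] for p in span):
                    continue
                used[chrom].update(span)
                return VariantRecord(
                    sample_id, chrom, pos0, seq[pos0 - 1] + seq[pos0], seq[pos0 - 1]
                )
            span = range(pos0 - 1, pos0 + 1)
            if any(p in used[chrom] for p in span):
                continue
            used[chrom].update(span)
            return VariantRecord(sample_id, chrom, pos0, seq[pos0 - 1], seq[pos0 - 1] + base)
        kind, bin_label = label.split("_")
        n = seq_len[bin_label]
        chrom = list(genome)[rng.integers(len(genome))]
        seq = genome[chrom]
        pos0 = int(rng.integers(1, len(seq) - n - 1))
        span = range(pos0 - 1, pos0 + n + 1)
        if any(p in used[chrom] for p in span):
            continue
        used[chrom].update(span)
        anchor = seq[pos0 - 1]
        if kind == "del":
            return VariantRecord(sample_id, chrom, pos0, anchor + seq[pos0 : pos0 + n], anchor)
        ins = "".join(rng.choice(list("ACGT"), size=n))
        return VariantRecord(sample_id, chrom, pos0, anchor, anchor + ins)
    return None


def simulate_ma_lines(
    genome: Mapping[str, str],
    mu: float,
    G: int,
    n_lines: int,
    d: int = DIVISIONS_PER_GENERATION,
    channel_probs: np.ndarray | None = None,
    length_bias: Mapping[int, float] | None = None,
    seed: int = 0,
    sample_prefix: str = "line",
) -> tuple[list[SimulatedLine], SyntheticTruth]:
    """Simulate selfing mutation-accumulation lines on a genome.

    Per generation g of each line, Poisson(mu * d * L) mutations arise;
    each survives the remaining G - g selfing transmissions (detected as
    heterozygous or fixed) with probability 1/2 + 2^-(G-g+1).  Detected
    mutations are realized on the genome per their drawn channel and
    returned as VCF-convention records plus true per-channel counts.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    probs = default_worm_channel_probs() if channel_probs is None else np.asarray(channel_probs, float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("channel_probs must be a probability vector")
    bias = dict(length_bias) if length_bias is not None else default_length_bias()
    rng = np.random.default_rng(seed)
    L = sum(len(s) for s in genome.values())
    placer = _GenomePlacer(genome, bias)
    lines: list[SimulatedLine] = []
    for li in range(n_lines):
        sample_id = f"{sample_prefix}{li + 1}"
        used: dict[str, set[int]] = {c: set() for c in genome}
        records: list[VariantRecord] = []
        counts = np.zeros(ch.N_CHANNELS, dtype=int)
        n_arising = 0
        n_detected = 0
        for g in range(1, G + 1):
            n_new = rng.poisson(mu * d * L)
            n_arising += n_new
            p_det = detection_probability(G - g)
            for _ in range(n_new):
                if rng.random() >= p_det:
                    continue
                channel = int(rng.choice(ch.N_CHANNELS, p=probs))
                rec = _realize_mutation(channel, placer, used, rng, sample_id)
                if rec is None:
                    continue
                records.append(rec)
                counts[channel] += 1
                n_detected += 1
        lines.append(SimulatedLine(sample_id, records, counts, n_arising, n_detected))
    truth = SyntheticTruth(
        seed=seed, mu=mu, generations=G, divisions=d, channel_probs=probs, length_bias=bias
    )
    return lines, truth


def simulate_line_counts(
    mu: float,
    G: int,
    n_lines: int,
    genome_length: float,
    d: int = DIVISIONS_PER_GENERATION,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Detected mutation counts only (no placement), for rate-estimator
    calibration studies: per generation Poisson arising counts thinned by
    the selfing detection probability."""
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.zeros(n_lines, dtype=int)
    lam = mu * d * genome_length
    for g in range(1, G + 1):
        arising = rng.poisson(lam, size=n_lines)
        p_det = detection_probability(G - g)
        counts += rng.binomial(arising, p_det)
    return counts


def write_vcf(records: Sequence[VariantRecord], path: str | Path, genome: Mapping[str, str]) -> None:
    """Write sites-only VCF v4.2 (CHROM/POS/REF/ALT), sorted by position."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# tumor cohorts


def default_synthetic_signatures() -> pd.DataFrame:
    """Three constructed, well-separated 104-channel signatures:

    * ``MMR-like`` — dominated by 1-bp indels with G[C>T]N and A[T>A]T
      substitutions (slippage-plus-mismatch shape);
    * ``Clock-like`` — C>T at NCG contexts (CpG-deamination shape);
    * ``Background`` — a fixed context-structured (spiky) profile across
      all channels, mimicking the strong context preferences real
      background processes show.  A perfectly flat profile would sit inside
      the cone spanned by the other signatures and be unidentifiable, which
      real signatures are not.

    Synthetic constants for simulation truth, not measured signatures.
    """
    sigs = pd.DataFrame(
        0.0, index=["MMR-like", "Clock-like", "Background"], columns=list(ch.CHANNELS_104)
    )
    mmr = default_worm_channel_probs()
    sigs.loc["MMR-like"] = mmr
    for i, label in enumerate(ch.SUBSTITUTION_CHANNELS):
        sub, three = label[2:5], label[6]
        if sub == "C>T" and three == "G":
            sigs.iloc[1, i] = 5.0
        elif sub == "C>T":
            sigs.iloc[1, i] = 0.3
        else:
            sigs.iloc[1, i] = 0.05
    sigs.iloc[2] = np.random.default_rng(12345).dirichlet(np.full(ch.N_CHANNELS, 0.3))
    return sigs.div(sigs.sum(axis=1), axis=0)


def simulate_cohort(
    n_samples: int = 120,
    signatures: pd.DataFrame | None = None,
    mmr_signature: str = "MMR-like",
    msi_fraction: float = 0.2,
    coupling: float = 20.0,
    log_mean: float = float(np.log(150.0)),
    log_sigma: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tumor-like cohort: counts = Poisson(E @ S) with log-normal exposures.

    Roughly ``msi_fraction`` of samples are labelled MSI (as in colorectal /
    gastric cohorts, where about a fifth of samples are MSI-H) and have
    their MMR-like exposure multiplied by ``coupling``.  Returns the
    samples x 104 count matrix and the truth (signatures, exposures,
    labels).
    """
    sigs = default_synthetic_signatures() if signatures is None else signatures
    if not np.allclose(sigs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("signature rows must sum to 1")
    if coupling != 1.0 and mmr_signature not in sigs.index:
        raise ValueError("no MMR-like signature designated for MSI coupling")
    rng = np.random.default_rng(seed)
    r = sigs.shape[0]
    exposures = rng.lognormal(log_mean, log_sigma, size=(n_samples, r))
    labels = np.where(rng.random(n_samples) < msi_fraction, "MSI", "MSS")
    if mmr_signature in sigs.index:
        j = list(sigs.index).index(mmr_signature)
        exposures[labels == "MSI", j] *= coupling
    lam = exposures @ sigs.values
    counts = rng.poisson(lam)
    samples = [f"tumor{i + 1}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=samples, columns=sigs.columns)
    truth = SyntheticTruth(
        seed=seed,
        signatures=sigs,
        exposures=pd.DataFrame(exposures, index=samples, columns=sigs.index),
        msi_labels=pd.Series(labels, index=samples),
    )
    return counts_df, truth
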