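"""Variant classification into the 104-channel scheme and spectrum building.

Substitutions are classified by their pyrimidine-collapsed trinucleotide
context; indels by inserted/deleted base class (1 bp) or length bin.  A
cross-sample duplicate filter removes calls shared between samples, which in
mutation-accumulation data are almost always inherited or artifactual rather
than independent de novo events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import channels as ch
from .io import VariantRecord, spectra_frame, to_zero_based


@dataclass
class MutationSpectrum:
    sample_id: str
    counts: np.ndarray  # length 104
    scheme_version: str = ch.SCHEME_VERSION
    n_skipped: int = 0

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.counts / total


@dataclass(frozen=True)
class NormalizedIndel:
    """Left-aligned minimal indel: `seq` inserted before / deleted at `start0`."""

    chrom: str
    start0: int  # 0-based
    kind: str  # "ins" | "del"
    seq: str


def _trim_shared(ref: str, alt: str, pos0: int) -> tuple[int, str, str]:
    """Strip shared prefix/suffix from an allele pair; returns minimal form."""
    # suffix first so the anchored prefix convention survives
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def normalize_indel(record: VariantRecord, genome: Mapping[str, str]) -> NormalizedIndel:
    """Left-align an anchored indel record against the genome.

    Left-alignment shifts the event to the 5'-most equivalent placement,
    which makes repeat-tract assignment and the positional duplicate filter
    deterministic.
    """
    if record.var_class == "SNV":
        raise ValueError("not an indel")
    seq = genome[record.chrom]
    pos0, ref, alt = _trim_shared(record.ref, record.alt, to_zero_based(record.pos))
    if len(ref) > 1 and len(alt) == 1:  # deletion of ref[1:] after anchor
        kind, allele, start0 = "del", ref[1:], pos0 + 1
    elif len(alt) > 1 and len(ref) == 1:  # insertion of alt[1:] after anchor
        kind, allele, start0 = "ins", alt[1:], pos0 + 1
    else:
        raise ValueError(f"cannot normalize alleles {record.ref}>{record.alt}")
    while start0 > 0 and seq[start0 - 1] == allele[-1]:
        allele = seq[start0 - 1] + allele[:-1]
        start0 -= 1
    return NormalizedIndel(record.chrom, start0, kind, allele)


def classify_substitution(
    record: VariantRecord, genome: Mapping[str, str]
) -> int | None:
    """Channel index in [0, 96) for an SNV, or None if unclassifiable.

    A variant whose ±1 bp context overlaps a chromosome end, contains an
    ambiguous base, or whose stated reference base disagrees with the genome
    is skipped (the caller counts skips).
    """
    if record.var_class != "SNV":
        raise ValueError("not an SNV")
    seq = genome[record.chrom]
    i = to_zero_based(record.pos)
    if i < 1 or i >= len(seq) - 1:
        return None
    five, ref_base, three = seq[i - 1], seq[i], seq[i + 1]
    if ref_base != record.ref:
        return None
    if any(b not in "ACGT" for b in (five, ref_base, three)):
        return None
    return ch.substitution_channel(five, record.ref, record.alt, three)


def classify_indel(record: VariantRecord, genome: Mapping[str, str]) -> int | None:
    """Channel index in [96, 104) for an indel, or None for SV-sized events."""
    if record.var_class == "SNV":
        raise ValueError("not an indel")
    if record.length == 0:
        raise ValueError("indel of length 0")
    if record.length > ch.MAX_INDEL_BP:
        return None
    norm = normalize_indel(record, genome)
    return ch.indel_channel(norm.kind, norm.seq)


def dedupe_shared_sites(
    records: Sequence[VariantRecord], genome: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Drop variants observed at the same site in two or more samples.

    Substitutions are keyed by the full allele identity (chrom, pos, ref,
    alt); indels by their left-aligned position alone — two different
    deletions starting at one position are both removed, but two different
    substitutions at one position are both kept.  Relative order is
    preserved and the filter is idempotent.
    """

    def key(r: VariantRecord):
        if r.var_class == "SNV":
            return ("snv", r.chrom, r.pos, r.ref, r.alt)
        if genome is not None:
            norm = normalize_indel(r, genome)
            return ("indel", norm.chrom, norm.start0)
        return ("indel", r.chrom, r.pos)

    seen_samples: dict[tuple, set[str]] = {}
    keys = [key(r) for r in records]
    for r, k in zip(records, keys):
        seen_samples.setdefault(k, set()).add(r.sample_id)
    return [r for r, k in zip(records, keys) if len(seen_samples[k]) < 2]


def build_spectrum(
    records: Iterable[VariantRecord],
    genome: Mapping[str, str],
    sample_id: str | None = None,
) -> MutationSpectrum:
    """Count one sample's classifiable variants into a 104-channel spectrum."""
    counts = np.zeros(ch.N_CHANNELS, dtype=int)
    n_skipped = 0
    sid = sample_id
    for r in records:
        if sid is None:
            sid = r.sample_id
        elif sample_id is None and r.sample_id != sid:
            raise ValueError("records from multiple samples; pass sample_id")
        idx = (
            classify_substitution(r, genome)
            if r.var_class == "SNV"
            else classify_indel(r, genome)
        )
        if idx is None:
            n_skipped += 1
        else:
            counts[idx] += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} unclassifiable record(s) skipped")
    return MutationSpectrum(sid or "", counts, n_skipped=n_skipped)


def build_cohort_matrix(
    records: Sequence[VariantRecord],
    genome: Mapping[str, str],
    dedupe: bool = True,
) -> pd.DataFrame:
    """Spectra for every sample in a record list, as a samples × 104 frame."""
    if dedupe:
        records = dedupe_shared_sites(records, genome)
    by_sample: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    spectra = [
        build_spectrum(recs, genome, sample_id=sid) for sid, recs in by_sample.items()
    ]
    return spectra_frame(spectra)
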