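"""Readers and writers for variant calls, reference genomes and result tables.

Coordinates are 1-based inclusive at the I/O boundary (VCF convention) and
0-based half-open internally; :func:`to_zero_based` is the single conversion
point.  Indels are represented anchored at the I/O boundary (ref "CA",
alt "C") and left-aligned against the genome before any downstream use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

_ACGT = frozenset("ACGT")

#: Minimal columns of the ICGC simple-somatic-mutation dialect.
ICGC_COLUMNS = (
    "icgc_sample_id",
    "chromosome",
    "chromosome_start",
    "reference_genome_allele",
    "mutated_to_allele",
)


def to_zero_based(pos: int) -> int:
    """Convert a 1-based inclusive coordinate to 0-based half-open start."""
    return pos - 1


@dataclass
class VariantRecord:
    """One variant call for one sample, VCF-style anchored alleles.

    ``pos`` is 1-based.  For indels, ``ref`` and ``alt`` share a leading
    anchor base; ``length`` is the number of inserted/deleted bases.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str = field(init=False)
    length: int = field(init=False)

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        if not ref or not alt or not (_ACGT >= set(ref)) or not (_ACGT >= set(alt)):
            raise ValueError(f"non-ACGT alleles: {self.ref!r}>{self.alt!r}")
        self.ref, self.alt = ref, alt
        if len(ref) == len(alt):
            if len(ref) != 1:
                raise ValueError(f"MNV not supported: {ref}>{alt}")
            self.var_class, self.length = "SNV", 0
        elif len(alt) > len(ref):
            self.var_class, self.length = "INS", len(alt) - len(ref)
        else:
            self.var_class, self.length = "DEL", len(ref) - len(alt)


@dataclass
class SampleMeta:
    """Per-sample metadata: worm MA line or tumor sample."""

    sample_id: str
    origin: str  # "worm_line" | "tumor"
    genotype: str = ""
    generation: int | None = None
    cancer_type: str | None = None
    msi_status: str = "unknown"  # "MSI" | "MSS" | "unknown"

    def __post_init__(self) -> None:
        if self.origin == "worm_line":
            if not self.genotype or self.generation is None:
                raise ValueError("worm_line requires genotype and generation")
        elif self.origin == "tumor":
            if self.msi_status not in ("MSI", "MSS", "unknown"):
                raise ValueError(f"bad msi_status: {self.msi_status}")
        else:
            raise ValueError(f"bad origin: {self.origin}")


def normalize_msi_status(label: str) -> str:
    """Map clinical MSI labels onto the binary MSI / MSS convention.

    MSI-H is MMR-deficient (MSI); MSI-L and MSS are MMR-proficient (MSS).
    """
    label = label.strip().upper().replace("_", "-")
    if label in ("MSI-H", "MSI"):
        return "MSI"
    if label in ("MSI-L", "MSS"):
        return "MSS"
    return "unknown"


# ---------------------------------------------------------------------------
# variant reading


def _anchor_icgc(
    chrom: str, start: int, ref: str, alt: str, genome: Mapping[str, str] | None
):
    """Convert an ICGC-style row ('-' alleles for pure ins/del) to anchored."""
    if ref != "-" and alt != "-":
        return start, ref, alt
    if genome is None:
        raise ValueError(
            "ICGC ins/del rows use '-' alleles and need a genome to anchor"
        )
    seq = genome[chrom]
    if alt == "-":  # deletion of `ref` starting at `start` (1-based)
        anchor = seq[start - 2]
        return start - 1, anchor + ref, anchor
    # insertion: ICGC places start at the base after which bases are inserted
    anchor = seq[start - 1]
    return start, anchor, anchor + alt


def read_variants(
    path: str | Path,
    dialect: str = "vcf",
    sample_id: str | None = None,
    genome: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read variant calls from a VCF or an ICGC-style simple-somatic TSV.

    Multi-allelic VCF rows are split into one record per alternate allele.
    Rows with non-ACGT alleles are rejected; a single warning reports how
    many were dropped.  Input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    n_rejected = 0
    if dialect == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        if sample_id is None:
            sample_id = vcf.samples[0] if len(vcf.samples) == 1 else path.stem
        for v in vcf:
            for alt in v.ALT:
                try:
                    records.append(
                        VariantRecord(sample_id, v.CHROM, v.POS, v.REF, alt)
                    )
                except ValueError:
                    n_rejected += 1
        vcf.close()
    elif dialect == "icgc_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ICGC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ICGC TSV missing columns: {missing}")
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                start = int(getattr(row, "chromosome_start"))
                pos, ref, alt = _anchor_icgc(
                    getattr(row, "chromosome"),
                    start,
                    getattr(row, "reference_genome_allele").upper(),
                    getattr(row, "mutated_to_allele").upper(),
                    genome,
                )
                records.append(
                    VariantRecord(
                        getattr(row, "icgc_sample_id"),
                        getattr(row, "chromosome"),
                        pos,
                        ref,
                        alt,
                    )
                )
            except (ValueError, TypeError) as exc:
                if "anchor" in str(exc):
                    raise
                n_rejected += 1
            except Exception as exc:  # malformed row: name the line
                raise ValueError(f"malformed row at line {i + 2}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    if n_rejected:
        warnings.warn(f"{n_rejected} record(s) rejected (non-ACGT alleles)")
    return records


# ---------------------------------------------------------------------------
# genome reading


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a chrom → uppercase-sequence mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def genome_length(genome: Mapping[str, str]) -> int:
    return sum(len(s) for s in genome.values())


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular interchange (TSV, fixed channel order, 12 significant digits)

_FLOAT_FMT = "%.12g"


def write_table(frame: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write spectra / signatures / estimates as a TSV.

    Rows are objects (samples, signatures, genotypes); columns are the fixed,
    documented channel order or estimate fields.  Integers round-trip
    bit-exactly; reals to 12 significant digits.
    """
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=frame.index.name or "id")
    _ = kind


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def spectra_frame(spectra: Iterable) -> pd.DataFrame:
    """Stack MutationSpectrum objects into a samples × 104 DataFrame."""
    from .channels import CHANNELS_104, SCHEME_VERSION

    spectra = list(spectra)
    for s in spectra:
        if s.scheme_version != SCHEME_VERSION:
            raise ValueError(
                f"channel-scheme mismatch: {s.scheme_version} != {SCHEME_VERSION}"
            )
    if spectra:
        data = np.array([s.counts for s in spectra]).reshape(len(spectra), -1)
    else:
        data = np.empty((0, len(CHANNELS_104)))
    frame = pd.DataFrame(
        data, index=[s.sample_id for s in spectra], columns=list(CHANNELS_104)
    )
    frame.index.name = "sample_id"
    return frame


def read_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample metadata TSV (sample_id, origin, genotype, generation,
    cancer_type, msi_status; missing fields empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = []
    for row in df.itertuples(index=False):
        gen = getattr(row, "generation", "")
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                origin=row.origin,
                genotype=getattr(row, "genotype", ""),
                generation=int(gen) if gen != "" else None,
                cancer_type=getattr(row, "cancer_type", "") or None,
                msi_status=normalize_msi_status(getattr(row, "msi_status", ""))
                if getattr(row, "msi_status", "")
                else "unknown",
            )
        )
    return metas
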