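"""Signature comparison: cosine similarity, catalog matching, and
cross-species trinucleotide-frequency adjustment ("humanization").

Spectra measured in different sequence spaces (the C. elegans genome versus
the human exome) are not directly comparable because the opportunity for
each trinucleotide-context mutation differs.  Humanization rescales the 96
substitution channels by the ratio of target to source trinucleotide
frequencies and renormalizes.  Indel channels are excluded from all
cross-species and catalog comparisons, since indel opportunity depends on
both base and homopolymer content.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import channels as ch

#: cosine similarity at or above this is called "high"
HIGH_SIMILARITY = 0.80


def cosine_similarity(s1, s2) -> float:
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector")
    return float(a @ b / (na * nb))


def compute_trinuc_frequencies(
    genome: Mapping[str, str],
    regions: Sequence[tuple[str, int, int]] | None = None,
    normalize: bool = False,
) -> pd.Series:
    """Counts (or frequencies) of the 32 pyrimidine-centered trinucleotides.

    Every overlapping 3-mer is counted once; purine-centered 3-mers are
    added to their reverse complement's bin.  3-mers containing N are
    skipped and excluded from totals.  ``regions`` are 0-based half-open
    (chrom, start, end) intervals restricting the sequence space (e.g. an
    exome); without them the whole genome is used.
    """
    counts = {c: 0 for c in ch.PYRIMIDINE_CONTEXTS}
    if regions is None:
        seqs = list(genome.values())
    else:
        seqs = []
        for chrom, start, end in regions:
            seq = genome[chrom]
            if start < 0 or end > len(seq) or start >= end:
                raise ValueError(f"region {chrom}:{start}-{end} out of bounds")
            seqs.append(seq[start:end])
    for seq in seqs:
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if any(b not in "ACGT" for b in tri):
                continue
            counts[ch.collapse_trinucleotide(tri)] += 1
    s = pd.Series(counts, dtype=float)
    s.index.name = "context"
    if normalize:
        s = s / s.sum()
    return s


def _substitution_part(pattern) -> np.ndarray:
    p = np.asarray(pattern, dtype=float)
    if p.shape[-1] == ch.N_CHANNELS:
        p = p[..., : ch.N_SUBSTITUTION]
    elif p.shape[-1] != ch.N_SUBSTITUTION:
        raise ValueError(f"expected 96 or 104 channels, got {p.shape[-1]}")
    return p


def humanize(pattern96, f_source: pd.Series, f_target: pd.Series) -> np.ndarray:
    """Adjust a 96-channel substitution pattern from one sequence space to
    another: each channel is multiplied by the ratio of target to source
    frequency of its trinucleotide context, then the vector is renormalized
    to sum to 1."""
    p = _substitution_part(pattern96)
    contexts = [ch.context_of_channel(i) for i in range(ch.N_SUBSTITUTION)]
    src = np.array([float(f_source[c]) for c in contexts])
    tgt = np.array([float(f_target[c]) for c in contexts])
    if np.any(src <= 0):
        raise ValueError("zero source frequency")
    w = p * tgt / src
    total = w.sum()
    if total == 0:
        raise ValueError("pattern vanished under adjustment")
    return w / total


#: the 4 C>T channels in an NCG context (CpG sites); elevated in methylated
#: genomes through 5meC deamination, absent in C. elegans
CPG_CT_CHANNELS: tuple[int, ...] = tuple(
    i
    for i, label in enumerate(ch.SUBSTITUTION_CHANNELS)
    if label[2:5] == "C>T" and label[6] == "G"
)


def match_to_catalog(
    signatures: pd.DataFrame,
    catalog: pd.DataFrame,
    threshold: float = HIGH_SIMILARITY,
    exclude_cpg_ct: bool = False,
) -> pd.DataFrame:
    """Best catalog match per query signature by cosine similarity.

    Queries may be 104-channel (the indel block is dropped and the
    substitution part renormalized) or 96-channel; the catalog must be
    96-channel.  With ``exclude_cpg_ct`` the 4 N[C>T]G channels are removed
    from both sides and both renormalized before comparison, discounting
    the CpG-deamination component that has no counterpart in unmethylated
    genomes.
    """
    if catalog.shape[1] != ch.N_SUBSTITUTION:
        raise ValueError("catalog must have 96 substitution channels")
    keep = np.ones(ch.N_SUBSTITUTION, dtype=bool)
    if exclude_cpg_ct:
        keep[list(CPG_CT_CHANNELS)] = False

    def prep(v) -> np.ndarray:
        p = _substitution_part(v)[keep]
        total = p.sum()
        if total == 0:
            raise ValueError("signature has no mass on compared channels")
        return p / total

    cat = {name: prep(row.values) for name, row in catalog.iterrows()}
    rows = []
    for name, row in signatures.iterrows():
        q = prep(row.values)
        sims = {cname: cosine_similarity(q, cvec) for cname, cvec in cat.items()}
        best = max(sims, key=sims.get)
        rows.append(
            {
                "signature": name,
                "best_match": best,
                "similarity": sims[best],
                "high": sims[best] >= threshold,
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def cosine_distance_matrix(spectra) -> pd.DataFrame:
    """S x S matrix of d_ij = 1 - cos(s_i, s_j), for embedding routines.

    ``spectra`` is a samples x channels frame/array; all-zero rows are an
    error.
    """
    if isinstance(spectra, pd.DataFrame):
        index, X = spectra.index, spectra.values.astype(float)
    else:
        X = np.asarray(spectra, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if X.shape[0] < 2:
        raise ValueError("need >= 2 spectra")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("all-zero spectrum")
    C = (X / norms[:, None]) @ (X / norms[:, None]).T
    D = 1.0 - np.clip(C, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=index, columns=index)
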