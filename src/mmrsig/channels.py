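"""The 104-channel mutation classification scheme.

Spectra combine 96 trinucleotide-context base-substitution channels with 8
small-indel channels.  Substitution channels are pyrimidine-centered
("strand-collapsed"): a mutated purine is reported as the reverse complement
event on the opposite strand.  Channel order is substitution class major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, both alphabetical
— the conventional 96-channel layout — followed by the 8 indel channels.
"""

from __future__ import annotations

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 8 indel channels: 1-bp events split by base class of the inserted/deleted
#: base, longer events binned by length (2-5 bp, >5 bp).
INDEL_CHANNELS = (
    "del1_AT",
    "del1_CG",
    "ins1_AT",
    "ins1_CG",
    "del_2to5",
    "ins_2to5",
    "del_gt5",
    "ins_gt5",
)

SCHEME_VERSION = "mmrsig-104-v1"

#: Largest indel length (bp) still treated as an indel; anything longer is a
#: structural variant and excluded from spectra.
MAX_INDEL_BP = 399


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_substitution_channels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
                _ = ref
    return tuple(labels)


SUBSTITUTION_CHANNELS: tuple[str, ...] = _build_substitution_channels()
CHANNELS_104: tuple[str, ...] = SUBSTITUTION_CHANNELS + INDEL_CHANNELS

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_104)}

N_SUBSTITUTION = len(SUBSTITUTION_CHANNELS)  # 96
N_CHANNELS = len(CHANNELS_104)  # 104

#: The 32 pyrimidine-centered trinucleotide contexts, in channel order of the
#: first substitution class (each context carries 3 substitution channels).
PYRIMIDINE_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}{center}{three}"
    for center in "CT"
    for five in BASES
    for three in BASES
)


def substitution_channel(five: str, ref: str, alt: str, three: str) -> int:
    """Channel index in [0, 96) for a substitution with its flanking bases.

    Purine reference bases are collapsed onto the pyrimidine strand by
    reverse-complementing the whole description.
    """
    if ref in "AG":
        five, ref, alt, three = (
            reverse_complement(three),
            reverse_complement(ref),
            reverse_complement(alt),
            reverse_complement(five),
        )
    label = f"{five}[{ref}>{alt}]{three}"
    try:
        return CHANNEL_INDEX[label]
    except KeyError:  # pragma: no cover - guarded by callers
        raise ValueError(f"not a valid substitution channel: {label}") from None


def indel_channel(kind: str, seq: str) -> int:
    """Channel index in [96, 104) for an insertion/deletion.

    Parameters
    ----------
    kind : "ins" or "del"
    seq : inserted or deleted bases (without any anchor base)
    """
    n = len(seq)
    if n == 0:
        raise ValueError("indel of length 0")
    if n > MAX_INDEL_BP:
        raise ValueError(f"indel of {n} bp exceeds {MAX_INDEL_BP} bp (SV)")
    if n == 1:
        base_class = "AT" if seq in "AT" else "CG"
        label = f"{kind}1_{base_class}"
    elif n <= 5:
        label = f"{kind}_2to5"
    else:
        label = f"{kind}_gt5"
    return CHANNEL_INDEX[label]


def context_of_channel(index: int) -> str:
    """Trinucleotide context (5' + ref + 3') of a substitution channel."""
    label = SUBSTITUTION_CHANNELS[index]
    return label[0] + label[2] + label[6]


def collapse_trinucleotide(trinuc: str) -> str:
    """Map a trinucleotide onto its pyrimidine-centered representative."""
    if trinuc[1] in "AG":
        return reverse_complement(trinuc)
    return trinuc
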