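"""Repeat-tract enumeration and homopolymer-aware indel analysis.

Mismatch-repair deficiency produces 1-bp indels predominantly by replication
slippage in homopolymer runs, at a rate that rises steeply with run length.
This module enumerates maximal homopolymer / di- / trinucleotide tracts of a
genome, assigns left-aligned 1-bp indels to tracts, tabulates indel counts
against the genomic tract census by length, and fits the per-tract indel
rate as a smooth function of homopolymer length with a penalized-spline
Poisson GAM.
"""

from __future__ import annotations

import hashlib
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import NormalizedIndel, normalize_indel
from .io import VariantRecord

MIN_UNITS = 4  # tracts need >= 4 unit copies


@dataclass(frozen=True)
class RepeatTract:
    chrom: str
    start: int  # 0-based half-open
    end: int
    unit: str
    n_units: int

    @property
    def tract_len(self) -> int:
        return self.end - self.start


@dataclass
class RepeatTrack:
    """All maximal tracts of one unit length for one genome."""

    tracts: list[RepeatTract]
    unit_len: int
    genome_md5: str

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def census(self) -> pd.Series:
        """Number of tracts per tract length (bp)."""
        lengths = pd.Series([t.tract_len for t in self.tracts], dtype=int)
        return lengths.value_counts().sort_index()


def genome_md5(genome: Mapping[str, str]) -> str:
    h = hashlib.md5()
    for chrom in sorted(genome):
        h.update(chrom.encode())
        h.update(genome[chrom].encode())
    return h.hexdigest()


def _is_minimal_unit(unit: str) -> bool:
    """A unit must not itself be a repeat of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _scan_chrom(chrom: str, seq: str, unit_len: int) -> list[RepeatTract]:
    n = len(seq)
    if n < unit_len * MIN_UNITS:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    match = arr[:-unit_len] == arr[unit_len:]
    # maximal runs of consecutive matches
    padded = np.concatenate(([False], match, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]  # match-index runs [a, b)
    out: list[RepeatTract] = []
    for a, b in zip(starts.tolist(), ends.tolist()):
        total = (b - a) + unit_len  # periodic interval length
        n_units = total // unit_len
        if n_units < MIN_UNITS:
            continue
        unit = seq[a : a + unit_len]
        if any(base not in "ACGT" for base in unit):
            continue
        if not _is_minimal_unit(unit):
            continue
        out.append(RepeatTract(chrom, a, a + n_units * unit_len, unit, n_units))
    return out


def find_repeats(genome: Mapping[str, str], unit_len: int) -> RepeatTrack:
    """Enumerate maximal repeat tracts with >= 4 unit copies.

    A tract is maximal when it cannot be extended on either side with
    another full unit.  Units that are themselves repeats of a shorter unit
    (e.g. "AA", "AAA") are excluded, so an A-run is reported only as a
    homopolymer and never doubles as a dinucleotide tract.  Trailing partial
    units do not extend a tract.
    """
    if unit_len not in (1, 2, 3):
        raise ValueError("unit_len must be 1, 2 or 3")
    tracts: list[RepeatTract] = []
    for chrom, seq in genome.items():
        tracts.extend(_scan_chrom(chrom, seq, unit_len))
    return RepeatTrack(tracts, unit_len, genome_md5(genome))


# ---------------------------------------------------------------------------
# indel -> tract assignment


@dataclass
class IndelAssignment:
    record: VariantRecord
    normalized: NormalizedIndel
    in_homopolymer: bool
    tract_unit: str | None = None
    tract_len: int | None = None


class _TractIndex:
    """Per (chrom, unit) sorted tract lookup."""

    def __init__(self, track: RepeatTrack):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[RepeatTract]]] = {}
        for t in sorted(track.tracts, key=lambda t: (t.chrom, t.start)):
            starts, tracts = self._by_key.setdefault((t.chrom, t.unit), ([], []))
            starts.append(t.start)
            tracts.append(t)

    def lookup(self, chrom: str, unit: str, pos: int, inclusive_end: bool) -> RepeatTract | None:
        entry = self._by_key.get((chrom, unit))
        if entry is None:
            return None
        starts, tracts = entry
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        t = tracts[i]
        end = t.end if not inclusive_end else t.end + 1
        return t if t.start <= pos < end else None


def assign_indels(
    indels: Sequence[VariantRecord],
    track: RepeatTrack,
    genome: Mapping[str, str],
) -> list[IndelAssignment]:
    """Annotate 1-bp indels with homopolymer-tract membership and length.

    An insertion of base B immediately abutting a B-tract counts as
    in-tract: the slippage event lengthens the run, and left-alignment
    places it at the tract start.  Indels longer than 1 bp are ignored.
    """
    if track.unit_len != 1:
        raise ValueError("assign_indels needs the homopolymer (unit_len=1) track")
    if track.genome_md5 != genome_md5(genome):
        raise ValueError("repeat track was built from a different genome")
    index = _TractIndex(track)
    out: list[IndelAssignment] = []
    for rec in indels:
        if rec.var_class == "SNV" or rec.length != 1:
            continue
        norm = normalize_indel(rec, genome)
        base = norm.seq
        # deletions must hit a tract position; insertions may abut the end
        tract = index.lookup(
            norm.chrom, base, norm.start0, inclusive_end=(norm.kind == "ins")
        )
        if tract is None:
            out.append(IndelAssignment(rec, norm, False))
        else:
            out.append(IndelAssignment(rec, norm, True, tract.unit, tract.tract_len))
    return out


def length_profile(
    assignments: Sequence[IndelAssignment], track: RepeatTrack
) -> pd.DataFrame:
    """Tabulate the genomic tract census N and in-tract 1-bp indel count k
    per homopolymer length."""
    census = track.census()
    k = pd.Series(0, index=census.index, dtype=int)
    for a in assignments:
        if a.in_homopolymer:
            k[a.tract_len] = k.get(a.tract_len, 0) + 1
    profile = pd.DataFrame({"n_tracts": census, "n_indels": k}).fillna(0).astype(int)
    profile.index.name = "length"
    return profile


# ---------------------------------------------------------------------------
# spline rate model


@dataclass
class SplineRateFit:
    lengths: np.ndarray
    rate: np.ndarray  # fitted indels per tract, by length
    ci_low: np.ndarray
    ci_high: np.ndarray
    basis: str
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))


class HomopolymerIndelSpline:
    """Poisson GAM for the per-tract 1-bp indel rate as a function of
    homopolymer length.

    Models k_l ~ Poisson(N_l * r(l)) with log r(l) a penalized cubic
    B-spline in l, fitted with statsmodels' GLMGam and the tract census as
    exposure offset.  Pointwise 95% confidence intervals come from the
    delta method on the linear predictor and widen where N_l or k_l is
    small.

    Parameters
    ----------
    df : spline basis dimension (default: adapts to the number of observed
        lengths, at most 8)
    degree : spline degree (cubic by default)
    alpha : smoothing penalty weight; a float, or "gcv" to select it by
        generalized cross-validation.  The default is a mild fixed penalty:
        with the short length ranges typical of homopolymer profiles
        (roughly 4-35 bp) GCV is noisy, and the fixed value leaves the
        linear trend unpenalized while damping spurious wiggle.
    """

    def __init__(self, df: int | None = None, degree: int = 3, alpha: float | str = 1.0):
        self.df = df
        self.degree = degree
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"df": self.df, "degree": self.degree, "alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, profile: pd.DataFrame):
        """Fit from a length profile (index: length; columns n_tracts, n_indels)."""
        from statsmodels.gam.api import BSplines, GLMGam
        import statsmodels.api as sm

        prof = profile[profile["n_tracts"] > 0]
        lengths = prof.index.to_numpy(dtype=float)
        if len(lengths) < 2:
            raise ValueError("degenerate profile: need >= 2 distinct lengths")
        if len(lengths) < 5:
            raise ValueError("need >= 5 distinct lengths with tracts")
        k = prof["n_indels"].to_numpy(dtype=float)
        n = prof["n_tracts"].to_numpy(dtype=float)
        self.lengths_ = lengths.astype(int)

        if k.sum() == 0:
            # all-zero counts: rate 0, exact-Poisson upper bound per length
            upper = stats.chi2.ppf(0.975, 2) / 2.0
            self.rate_ = np.zeros_like(n)
            self.ci_low_ = np.zeros_like(n)
            self.ci_high_ = upper / n
            self.result_ = None
            self._smoother = None
            return self

        df = self.df or int(np.clip(len(lengths) - 1, 4, 8))
        smoother = BSplines(
            lengths[:, None], df=[df], degree=[min(self.degree, df - 1)]
        )
        exog = np.ones((len(lengths), 1))
        model = GLMGam(
            k,
            exog=exog,
            smoother=smoother,
            alpha=1.0 if self.alpha == "gcv" else float(self.alpha),
            family=sm.families.Poisson(),
            exposure=n,
        )
        if self.alpha == "gcv":
            alpha_opt = model.select_penweight()[0]
            model = GLMGam(
                k,
                exog=exog,
                smoother=smoother,
                alpha=alpha_opt,
                family=sm.families.Poisson(),
                exposure=n,
            )
        self.result_ = model.fit()
        self._smoother = smoother
        eta, lo, hi = self._linpred(lengths)
        self.rate_, self.ci_low_, self.ci_high_ = np.exp(eta), np.exp(lo), np.exp(hi)
        return self

    def _linpred(self, lengths: np.ndarray):
        basis = self._smoother.transform(np.asarray(lengths, dtype=float)[:, None])
        X = np.column_stack([np.ones(len(lengths)), basis])
        params = self.result_.params
        eta = X @ params
        cov = np.asarray(self.result_.cov_params())
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, cov, X), 0, None))
        z = stats.norm.ppf(0.975)
        return eta, eta - z * se, eta + z * se

    def predict(self, lengths) -> np.ndarray:
        """Fitted per-tract rate r(l) at the given lengths."""
        if self.result_ is None:
            return np.zeros(len(lengths))
        eta, _, _ = self._linpred(np.asarray(lengths))
        return np.exp(eta)

    def to_fit(self) -> SplineRateFit:
        return SplineRateFit(
            lengths=self.lengths_,
            rate=self.rate_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            basis=f"cubic B-spline, alpha={self.alpha}",
            coefficients=np.asarray(self.result_.params) if self.result_ is not None else np.array([]),
        )


def fit_indel_rate_spline(profile: pd.DataFrame, **params) -> SplineRateFit:
    """Convenience wrapper: fit the homopolymer indel-rate spline."""
    return HomopolymerIndelSpline(**params).fit(profile).to_fit()
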