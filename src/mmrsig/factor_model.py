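"""Additive Poisson factor model for genotype-resolved mutational patterns.

Worm mutation-accumulation samples mix a background process with the
process unlocked by each mutated gene.  With a design matrix X whose entry
(s, f) is the exposure of sample s to factor f (generations propagated
under that genetic factor), channel counts are modelled additively:

    y_sc ~ Poisson( (X beta)_sc ),   beta >= 0,

an identity-link non-negative Poisson regression solved per channel.  The
problem is convex per channel; multiplicative updates (KL-NMF with the
"W" factor fixed at X) converge monotonically to the MLE, so the fit is
deterministic given the data.  Factor rows of beta are per-generation
channel rates; normalized rows are the factor's mutational pattern.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS_104
from .io import SampleMeta
from .nmf import generalized_kl

_EPS = 1e-12


def build_design(
    meta: Sequence[SampleMeta],
    factor_map: Mapping[str, Sequence[str]],
    interactions: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Samples x factors design with entry (s, f) = G_s if factor f is
    active in sample s, else 0.

    ``factor_map`` maps genotype to its active factors (e.g. every genotype
    carries "background" plus its own gene factors).  ``interactions``
    optionally maps a genotype to extra interaction columns for double
    mutants.
    """
    observed = {m.genotype for m in meta}
    factors: list[str] = []
    for genotype, fs in factor_map.items():
        if genotype not in observed:
            continue
        for f in fs:
            if f not in factors:
                factors.append(f)
    if interactions:
        for genotype, fs in interactions.items():
            if genotype not in observed:
                continue
            for f in fs:
                if f not in factors:
                    factors.append(f)
    rows = []
    index = []
    for m in meta:
        if m.genotype not in factor_map:
            raise ValueError(f"unmapped genotype: {m.genotype!r}")
        active = set(factor_map[m.genotype])
        if interactions and m.genotype in interactions:
            active |= set(interactions[m.genotype])
        rows.append([float(m.generation) if f in active else 0.0 for f in factors])
        index.append(m.sample_id)
    X = pd.DataFrame(rows, index=index, columns=factors)
    if (X.sum(axis=0) == 0).any():
        dead = list(X.columns[X.sum(axis=0) == 0])
        raise ValueError(f"all-zero design columns: {dead}")
    return X


class AdditivePoissonPatterns:
    """Identity-link non-negative Poisson regression of channel counts on a
    factor design, fitted by multiplicative updates.

    Attributes (after fit)
    ----------------------
    patterns_ : (F, C) per-factor per-channel rates (per unit exposure)
    normalized_ : patterns with each factor row scaled to sum to 1 (NaN rows
        for factors with no mutations)
    loglik_path_ : KL objective across iterations (non-increasing)
    """

    def __init__(self, max_iter: int = 5000, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, Y):
        Xm = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
        Ym = np.asarray(Y.values if isinstance(Y, pd.DataFrame) else Y, dtype=float)
        if Xm.ndim != 2 or Ym.ndim != 2 or Xm.shape[0] != Ym.shape[0]:
            raise ValueError("X (S x F) and Y (S x C) must align on samples")
        if np.any(Xm < 0) or np.any(Ym < 0):
            raise ValueError("X and Y must be non-negative")
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            # name the offending columns for the caller
            names = (
                list(X.columns) if isinstance(X, pd.DataFrame) else list(range(Xm.shape[1]))
            )
            raise ValueError(f"design not identifiable (collinear columns among {names})")
        F = Xm.shape[1]
        C = Ym.shape[1]
        col_sums = Xm.sum(axis=0)  # >0 by the rank check
        B = np.full((F, C), Ym.mean() / max(Xm.mean() * F, _EPS))
        path = []
        for it in range(self.max_iter):
            W = Xm @ B + _EPS
            B_new = B * (Xm.T @ (Ym / W)) / col_sums[:, None]
            if it % 20 == 0:
                path.append(generalized_kl(Ym, Xm @ B_new))
            delta = np.max(np.abs(B_new - B)) / (np.max(B) + _EPS)
            B = B_new
            if delta < self.tol:
                break
        # channels with zero counts have exact MLE 0
        B[:, Ym.sum(axis=0) == 0] = 0.0
        self.patterns_ = B
        row_tot = B.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.normalized_ = np.where(row_tot[:, None] > 0, B / row_tot[:, None], np.nan)
        self.loglik_path_ = np.asarray(path)
        self.factors_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        self.channels_ = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
        return self

    def patterns_frame(self) -> pd.DataFrame:
        cols = self.channels_ or list(CHANNELS_104[: self.patterns_.shape[1]])
        idx = self.factors_ or list(range(self.patterns_.shape[0]))
        return pd.DataFrame(self.patterns_, index=idx, columns=cols)


def fit_additive_poisson(Y, X, **params) -> pd.DataFrame:
    """Functional wrapper: factor patterns (rates) as a DataFrame."""
    return AdditivePoissonPatterns(**params).fit(X, Y).patterns_frame()
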