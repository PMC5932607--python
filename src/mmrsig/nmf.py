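"""De novo mutational-signature extraction by KL-divergence NMF.

Factorizes a samples x 104-channel count matrix V into non-negative
exposures E (samples x r) and signatures P (r x 104, rows on the simplex)
by minimizing the generalized Kullback-Leibler divergence

    D(V || EP) = sum_ij V_ij log(V_ij / (EP)_ij) - V_ij + (EP)_ij

with the classic multiplicative updates; this is equivalent to
maximum-likelihood fitting of a Poisson model V_ij ~ Pois((EP)_ij).  Random
restarts guard against local minima; the best-divergence fit is kept.  The
factorization rank (number of signatures) is chosen where the Akaike
Information Criterion and residual sum of squares saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .channels import CHANNELS_104

_EPS = 1e-12


def generalized_kl(V: np.ndarray, W: np.ndarray) -> float:
    """D(V || W) = sum V log(V/W) - V + W with 0 log 0 = 0."""
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    mask = V > 0
    div = float(np.sum(W) - np.sum(V))
    div += float(np.sum(V[mask] * np.log(V[mask] / (W[mask] + _EPS))))
    return div


def poisson_loglik(V: np.ndarray, Lam: np.ndarray) -> float:
    """Poisson log-likelihood of counts V under means Lam."""
    V = np.asarray(V, dtype=float)
    Lam = np.asarray(Lam, dtype=float) + _EPS
    return float(np.sum(V * np.log(Lam) - Lam - gammaln(V + 1.0)))


def _mu_updates(V, E, P, max_iter, tol):
    """Multiplicative updates for V ~ E @ P under generalized KL."""
    prev = np.inf
    n_iter = max_iter
    ones_s = np.ones(V.shape[0])
    ones_c = np.ones(V.shape[1])
    for it in range(1, max_iter + 1):
        W = E @ P + _EPS
        E *= (V / W) @ P.T / np.maximum(np.outer(ones_s, P.sum(axis=1)), _EPS)
        W = E @ P + _EPS
        P *= E.T @ (V / W) / np.maximum(np.outer(E.sum(axis=0), ones_c), _EPS)
        if it % 10 == 0 or it == max_iter:
            d = generalized_kl(V, E @ P)
            if prev - d < tol * max(abs(prev), 1.0):
                n_iter = it
                break
            prev = d
    return E, P, generalized_kl(V, E @ P), n_iter


class KLSignatureNMF:
    """KL-divergence (Poisson) NMF signature extractor, sklearn-style.

    Parameters
    ----------
    n_signatures : factorization rank r
    n_restarts : random restarts; the best-divergence fit is kept
    max_iter, tol : multiplicative-update stopping rule (relative change in
        divergence)
    random_state : seed; identical seeds give identical output

    Attributes (after fit)
    ----------------------
    signatures_ : (r, n_channels) rows summing to 1
    exposures_ : (n_samples, r) expected mutation counts per signature
    divergence_ : best generalized KL divergence reached
    n_iter_ : iterations of the winning restart
    """

    def __init__(
        self,
        n_signatures: int = 2,
        n_restarts: int = 50,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_signatures = n_signatures
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_signatures": self.n_signatures,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _validate(V) -> np.ndarray:
        V = np.asarray(
            V.values if isinstance(V, pd.DataFrame) else V, dtype=float
        )
        if V.ndim != 2:
            raise ValueError("V must be 2-D (samples x channels)")
        if np.any(V < 0):
            raise ValueError("V must be non-negative")
        if not np.any(V):
            raise ValueError("V is all zero")
        if np.any(V.sum(axis=1) == 0):
            raise ValueError("V contains all-zero sample rows")
        return V

    def fit(self, V, y=None):
        Vm = self._validate(V)
        r = self.n_signatures
        if not 1 <= r <= min(Vm.shape):
            raise ValueError(f"rank {r} out of range for shape {Vm.shape}")
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(Vm.mean() / r)
        best = None
        for _ in range(self.n_restarts):
            E0 = rng.uniform(0.5, 1.5, size=(Vm.shape[0], r)) * scale
            P0 = rng.uniform(0.5, 1.5, size=(r, Vm.shape[1])) * scale
            E, P, d, n_iter = _mu_updates(Vm, E0, P0, self.max_iter, self.tol)
            if best is None or d < best[2]:
                best = (E, P, d, n_iter)
        E, P, d, n_iter = best
        # absorb signature scale into exposures so signature rows sum to 1
        row_sums = P.sum(axis=1)
        P = P / row_sums[:, None]
        E = E * row_sums[None, :]
        self.signatures_ = P
        self.exposures_ = E
        self.divergence_ = d
        self.n_iter_ = n_iter
        self.channels_ = (
            list(V.columns) if isinstance(V, pd.DataFrame) else list(CHANNELS_104[: Vm.shape[1]])
        )
        return self

    def fit_transform(self, V, y=None) -> np.ndarray:
        return self.fit(V).exposures_

    def transform(self, V) -> np.ndarray:
        """Exposures for new samples under the fitted (fixed) signatures."""
        Vm = self._validate(V)
        P = self.signatures_
        rng = np.random.default_rng(self.random_state)
        E = rng.uniform(0.5, 1.5, size=(Vm.shape[0], P.shape[0])) * np.sqrt(
            Vm.mean() / P.shape[0]
        )
        for _ in range(self.max_iter):
            W = E @ P + _EPS
            E_new = E * ((Vm / W) @ P.T) / np.maximum(P.sum(axis=1)[None, :], _EPS)
            if np.max(np.abs(E_new - E)) < self.tol * (1.0 + np.max(E)):
                E = E_new
                break
            E = E_new
        return E

    def loglik(self, V) -> float:
        Vm = self._validate(V)
        return poisson_loglik(Vm, self.exposures_ @ self.signatures_)


def nmf_kl(V, r: int, n_restarts: int = 50, seed: int | None = None):
    """Functional wrapper: returns (signatures, exposures, divergence)."""
    model = KLSignatureNMF(r, n_restarts=n_restarts, random_state=seed).fit(V)
    return model.signatures_, model.exposures_, model.divergence_


@dataclass
class ModelSelectionResult:
    table: pd.DataFrame  # index rank; columns divergence, rss, aic, loglik
    chosen_rank: int


def select_rank(
    V,
    ranks,
    n_restarts: int = 50,
    seed: int | None = None,
    rel_tol: float = 0.01,
) -> ModelSelectionResult:
    """Fit every candidate rank and choose where the AIC saturates.

    AIC_r = 2 k_r - 2 logL_r with the Poisson log-likelihood of the raw
    counts at the fitted factorization and k_r = r * (n_channels + S - 1)
    free parameters (signatures constrained to the simplex).  The chosen
    rank is the smallest at which the AIC improvement over the previous
    rank falls below ``rel_tol`` of the AIC magnitude ("saturation"); the
    RSS is reported alongside as the saturation cross-check.
    """
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks:
        raise ValueError("ranks is empty")
    Vm = KLSignatureNMF._validate(V)
    S, C = Vm.shape
    rows = []
    for r in ranks:
        model = KLSignatureNMF(r, n_restarts=n_restarts, random_state=seed).fit(Vm)
        fit = model.exposures_ @ model.signatures_
        ll = poisson_loglik(Vm, fit)
        k = r * (C + S - 1)
        rows.append(
            {
                "rank": r,
                "divergence": model.divergence_,
                "rss": float(np.sum((Vm - fit) ** 2)),
                "loglik": ll,
                "aic": 2.0 * k - 2.0 * ll,
            }
        )
    table = pd.DataFrame(rows).set_index("rank")
    chosen = ranks[-1]
    for prev, cur in zip(ranks, ranks[1:]):
        improvement = table.loc[prev, "aic"] - table.loc[cur, "aic"]
        if improvement < rel_tol * abs(table.loc[prev, "aic"]):
            chosen = prev
            break
    return ModelSelectionResult(table, chosen)


def attribute_mutations(exposures) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample attributed mutation counts and relative contributions.

    Returns (counts, relative); samples with zero total exposure get NaN
    relative contributions.
    """
    counts = (
        exposures.copy()
        if isinstance(exposures, pd.DataFrame)
        else pd.DataFrame(np.asarray(exposures, dtype=float))
    )
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = counts.div(totals.where(totals > 0), axis=0)
    return counts, relative
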