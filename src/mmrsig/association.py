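"""Statistics linking signature exposures to microsatellite-instability status.

Relative signature contributions are compared between MSI (MMR-deficient)
and MSS (MMR-proficient) samples with a one-tailed Wilcoxon rank-sum test
(alternative: greater in MSI), Bonferroni-corrected over the signatures
tested.  A designated signature's contribution is additionally summarized
as an AUC — the probability that a random MSI sample has a higher
contribution than a random MSS sample — with a DeLong confidence interval,
and attributed mutation counts are correlated with per-sample 1-bp indel
load.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: exact rank-sum enumeration up to this combined group size
EXACT_MAX_N = 12


def _rank_sum_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank sum of x within the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(x)].sum())


def wilcoxon_one_tailed(x, y) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum test, alternative "x greater".

    Uses exact enumeration of group assignments (with midranks) when the
    combined sample size is at most 12, and the normal approximation with
    tie correction otherwise.  Returns (W, p) with W the rank sum of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    W = _rank_sum_stat(x, y)
    n, m = len(x), len(y)
    if n + m <= EXACT_MAX_N:
        ranks = stats.rankdata(np.concatenate([x, y]))
        total = 0
        at_least = 0
        for subset in combinations(range(n + m), n):
            total += 1
            if ranks[list(subset)].sum() >= W - 1e-12:
                at_least += 1
        return W, at_least / total
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return W, float(res.pvalue)


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m * p)."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


def auc(scores, labels, ci_method: str = "delong", n_boot: int = 2000, seed: int = 0):
    """AUC of a score for separating MSI from MSS, with 95% CI.

    AUC = (concordant + 0.5 * ties) / (n_MSI * n_MSS), identical to the
    Wilcoxon U statistic divided by the product of group sizes.  The CI is
    DeLong's asymptotic interval by default, with a seeded stratified
    bootstrap fallback for tiny or degenerate groups.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    x = scores[labels == "MSI"]
    y = scores[labels == "MSS"]
    if x.size == 0 or y.size == 0:
        raise ValueError("both MSI and MSS samples are required")
    diff = x[:, None] - y[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    point = float(psi.mean())
    use_boot = ci_method == "bootstrap" or min(x.size, y.size) < 3
    if not use_boot:
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        var = 0.0
        if x.size > 1:
            var += np.var(v10, ddof=1) / x.size
        if y.size > 1:
            var += np.var(v01, ddof=1) / y.size
        if var == 0:
            use_boot = point not in (0.0, 1.0)
            if not use_boot:
                return point, (point, point)
        else:
            z = stats.norm.ppf(0.975)
            half = z * np.sqrt(var)
            return point, (max(0.0, point - half), min(1.0, point + half))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        d = xb[:, None] - yb[None, :]
        reps[b] = np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0)).mean()
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


def indel_correlation(attributed, indel1bp) -> float:
    """Pearson correlation between attributed mutation counts for one
    signature and per-sample 1-bp indel counts."""
    a = np.asarray(attributed, dtype=float)
    b = np.asarray(indel1bp, dtype=float)
    if a.size < 3:
        raise ValueError("need >= 3 samples")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class AssociationResult:
    table: pd.DataFrame  # per signature: W, p, p_bonferroni
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    signature_of_interest: str | None = None
    pearson_r: float | None = None


def associate(
    exposures: pd.DataFrame,
    msi_labels: pd.Series,
    signature_of_interest: str | None = None,
    indel1bp: pd.Series | None = None,
    auc_seed: int = 0,
) -> AssociationResult:
    """Test every signature's relative contribution for MSI association.

    ``exposures`` is samples x signatures (attributed counts); relative
    contributions are computed per sample.  ``msi_labels`` maps sample to
    "MSI"/"MSS".  The Bonferroni factor is the number of signatures tested.
    """
    labels = msi_labels.reindex(exposures.index)
    if labels.isna().any():
        raise ValueError("missing MSI labels for some samples")
    totals = exposures.sum(axis=1)
    rel = exposures.div(totals.where(totals > 0), axis=0)
    m = exposures.shape[1]
    rows = []
    for sig in exposures.columns:
        vals = rel[sig].dropna()
        lab = labels.loc[vals.index]
        W, p = wilcoxon_one_tailed(vals[lab == "MSI"], vals[lab == "MSS"])
        rows.append({"signature": sig, "W": W, "p": p, "p_bonferroni": float(bonferroni(p, m))})
    table = pd.DataFrame(rows).set_index("signature")
    result = AssociationResult(table)
    if signature_of_interest is not None:
        vals = rel[signature_of_interest].fillna(0.0)
        result.signature_of_interest = signature_of_interest
        result.auc, result.auc_ci = auc(vals.values, labels.values, seed=auc_seed)
        if indel1bp is not None:
            result.pearson_r = indel_correlation(
                exposures[signature_of_interest].values,
                indel1bp.reindex(exposures.index).values,
            )
    return result
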