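"""Niche-conservatism precondition test.

The assembly framework is only interpretable when closely related taxa
share habitat preferences.  This module estimates each taxon's
environmental niche optimum as the abundance-weighted mean of the
(standardised) environmental variables over the samples where it occurs,
builds the Euclidean matrix of niche differences, and relates it to
patristic phylogenetic distance with a Mantel correlogram: per distance
class d, the niche-distance matrix is correlated with the binary model
matrix of class membership under row/column permutations, with progressive
Holm correction over the tested classes.

Sign convention: positive Mantel r at a class means taxa within that
phylogenetic distance class have *more similar* niches than expected
(clustering); the raw Pearson correlation with the 0/1 model matrix is
sign-flipped so that short-distance clustering reads as positive, and the
default one-tailed test is in that direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CommunityTable, ValidationError
from .metrics import _rng

logger = logging.getLogger("phyloturn")

__all__ = [
    "niche_optima",
    "niche_distance",
    "mantel_correlogram",
    "CorrelogramResult",
    "plot_correlogram",
]


def niche_optima(
    table: CommunityTable,
    env: pd.DataFrame,
    meta: pd.DataFrame,
    standardize: bool = True,
    site_key: str = "site",
) -> pd.DataFrame:
    """Abundance-weighted environmental optimum of each ASV.

    ``optimum(i, k) = sum_j n_ij e_jk / sum_j n_ij`` over samples j, where
    ``e_jk`` is variable k at sample j's site.  Variables are standardised
    to zero mean / unit variance across sites first (default), so the
    subsequent Euclidean distances are not dominated by units.  ASVs
    absent from every sample are dropped with a warning.  Each optimum
    lies within the range of the variable over occupied sites.
    """
    env = env.astype(float)
    if standardize:
        sd = env.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValidationError(
                f"constant environmental variable {env.columns[(sd == 0).argmax()]!r}"
            )
        env = (env - env.mean(axis=0)) / sd
    sites = meta.loc[table.sample_ids, site_key].astype(str)
    missing = set(sites) - set(env.index.astype(str))
    if missing:
        raise ValidationError(f"sites without environmental values: {sorted(missing)}")
    E = env.loc[sites].to_numpy()  # samples x variables
    N = table.counts.astype(float)  # samples x ASVs
    totals = N.sum(axis=0)
    present = totals > 0
    if not present.all():
        logger.warning(
            "niche_optima: dropped %d ASVs absent from every sample",
            int((~present).sum()),
        )
    optima = (N[:, present].T @ E) / totals[present, None]
    asv_ids = [a for a, p in zip(table.asv_ids, present) if p]
    return pd.DataFrame(optima, index=asv_ids, columns=env.columns)


def niche_distance(optima: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between ASV niche-optimum rows."""
    if optima.isna().any().any():
        raise ValidationError("missing niche optima")
    d = squareform(pdist(optima.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=list(optima.index.astype(str)))


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics.

    ``classes`` has columns ``class_index``, ``lower``, ``upper``,
    ``center``, ``n_pairs``, ``r``, ``p``, ``p_corrected``, ``tested``.
    Untested classes (beyond the validity cutoff, or empty) carry raw
    statistics where computable but are excluded from the Holm step-down.
    """

    classes: pd.DataFrame
    cutoff: float
    permutations: int

    def shortest_tested(self) -> pd.Series:
        tested = self.classes[self.classes["tested"]]
        if tested.empty:
            raise ValidationError("no tested distance class")
        return tested.iloc[0]


def _progressive_holm(pvals: np.ndarray) -> np.ndarray:
    """Progressive Holm: class k is corrected within the first k tests.

    ``corrected[k]`` is the k-th element of the Holm step-down adjustment
    applied to ``pvals[:k+1]``, the convention of distance-class
    correlograms where classes are examined in order of increasing
    distance.
    """
    out = np.empty(len(pvals))
    for k in range(len(pvals)):
        prefix = pvals[: k + 1]
        order = np.argsort(prefix, kind="stable")
        adj = np.empty(k + 1)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k + 1 - rank) * prefix[idx])
            adj[idx] = min(1.0, running)
        out[k] = adj[k]
    return out


def mantel_correlogram(
    niche_d: DistanceMatrix,
    phylo_d: DistanceMatrix,
    n_classes: int | str = "auto",
    permutations: int = 999,
    seed=0,
    alternative: str = "greater",
    cutoff: float | None = None,
) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` equal-width
    classes over [0, max] (``"auto"``: Sturges' rule on the number of
    pairs).  For each class the sign-flipped Pearson correlation between
    the niche-distance vector and the class's 0/1 model matrix is the
    class r; significance comes from ``permutations`` simultaneous
    row/column permutations of the niche matrix, shared across classes,
    with the add-one convention.  Classes whose lower bound exceeds the
    cutoff (default: half the maximum phylogenetic distance, the standard
    correlogram validity domain) are computed but flagged untested;
    progressive Holm correction runs over the tested classes in order of
    increasing distance.
    """
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if set(niche_d.ids) != set(phylo_d.ids):
        raise ValidationError("niche and phylogenetic matrices have different ids")
    phylo_d = phylo_d.filter(niche_d.ids)
    n = len(niche_d.ids)
    tril = np.tril_indices(n, k=-1)
    x = phylo_d.data[tril]
    y_full = niche_d.data
    y = y_full[tril]
    n_pairs_total = x.size
    if n_classes == "auto":
        k = int(math.ceil(1 + math.log2(n_pairs_total)))  # Sturges
    else:
        k = int(n_classes)
        if k < 1:
            raise ValueError("n_classes must be >= 1")
    xmax = float(x.max())
    if xmax <= 0:
        raise ValidationError("all phylogenetic distances are zero")
    breaks = np.linspace(0.0, xmax, k + 1)
    # right-closed bins; distance 0 goes to the first class
    membership = np.clip(np.digitize(x, breaks[1:], right=True), 0, k - 1)
    if cutoff is None:
        cutoff = xmax / 2.0

    models = np.zeros((k, n_pairs_total))
    for c in range(k):
        models[c, membership == c] = 1.0
    n_pairs = models.sum(axis=1).astype(int)
    nonempty = n_pairs > 0
    # centred model rows for fast correlation against permuted niche vectors
    m_centered = models - models.mean(axis=1, keepdims=True)
    m_norm = np.linalg.norm(m_centered, axis=1)
    valid = nonempty & (m_norm > 0)

    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValidationError("niche distances have zero variance")

    def class_r(yvec_centered: np.ndarray, norm: float) -> np.ndarray:
        r = np.full(k, np.nan)
        r[valid] = -(m_centered[valid] @ yvec_centered) / (m_norm[valid] * norm)
        return r

    r_obs = class_r(yc, ynorm)

    rng = _rng(seed)
    exceed = np.zeros(k)
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = y_full[np.ix_(perm, perm)][tril]
        ypc = yp - yp.mean()
        r_perm = class_r(ypc, np.linalg.norm(ypc))
        if alternative == "greater":
            exceed += r_perm >= r_obs - 1e-12
        elif alternative == "less":
            exceed += r_perm <= r_obs + 1e-12
        else:
            exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
    p_raw = np.where(valid, (exceed + 1) / (permutations + 1), np.nan)

    tested = valid & (breaks[:-1] <= cutoff)
    if (~nonempty).any():
        logger.warning(
            "mantel_correlogram: %d empty distance classes skipped", int((~nonempty).sum())
        )
    p_corr = np.full(k, np.nan)
    tested_idx = np.flatnonzero(tested)
    if tested_idx.size:
        p_corr[tested_idx] = _progressive_holm(p_raw[tested_idx])

    classes = pd.DataFrame(
        {
            "class_index": np.arange(k),
            "lower": breaks[:-1],
            "upper": breaks[1:],
            "center": 0.5 * (breaks[:-1] + breaks[1:]),
            "n_pairs": n_pairs,
            "r": r_obs,
            "p": p_raw,
            "p_corrected": p_corr,
            "tested": tested,
        }
    )
    return CorrelogramResult(classes=classes, cutoff=cutoff, permutations=permutations)


def plot_correlogram(result: CorrelogramResult, ax=None, alpha: float = 0.05):
    """Correlogram plot: r against class center, significant classes filled."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cls = result.classes[result.classes["n_pairs"] > 0]
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(cls["center"], cls["r"], "-", color="black", lw=1)
    sig = cls["tested"] & (cls["p_corrected"] < alpha)
    ax.plot(cls.loc[~sig, "center"], cls.loc[~sig, "r"], "o", mfc="white", mec="black")
    ax.plot(cls.loc[sig, "center"], cls.loc[sig, "r"], "o", color="black")
    ax.set_xlabel("phylogenetic distance class")
    ax.set_ylabel("Mantel r")
    return ax
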