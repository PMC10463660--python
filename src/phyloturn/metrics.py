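"""Supporting community metrics: rarefaction, CSS normalisation, Shannon
diversity, Bray-Curtis dissimilarity, shared/unique ASV fractions and the
simple Mantel test.

These are the descriptive statistics reported alongside the assembly
framework; each is deterministic given its seed and validated against
closed forms or brute-force oracles in the test suite.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CommunityTable, ValidationError

logger = logging.getLogger("phyloturn")

__all__ = [
    "rarefy",
    "css_normalize",
    "shannon",
    "bray_curtis",
    "shared_unique_fractions",
    "mantel",
]


def _rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: CommunityTable, depth: int, seed) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Sampling is multivariate hypergeometric (reads drawn without
    replacement from the observed pool), so an ASV can never gain support
    it did not have.  Samples whose total is below ``depth`` are dropped
    and logged; if none remain an error is raised.  Samples whose total is
    exactly ``depth`` are returned unchanged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValidationError(f"all samples have fewer than {depth} reads")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rarefy: dropped %d samples with < %d reads", n_dropped, depth)
    out_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((len(out_ids), table.n_asvs), dtype=np.int64)
    row = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        counts = table.counts[i]
        if totals[i] == depth:
            out[row] = counts
        else:
            out[row] = rng.multivariate_hypergeometric(counts, depth)
        row += 1
    return CommunityTable(out_ids, list(table.asv_ids), out)


# ---------------------------------------------------------------------------
# CSS normalisation
# ---------------------------------------------------------------------------


def css_normalize(
    table: CommunityTable, quantile: float = 0.5, scale: float | None = None
) -> pd.DataFrame:
    """Cumulative-sum scaling of counts.

    For each sample the counts are divided by :math:`s_j`, the sum of that
    sample's counts that are at or below its own ``quantile``-th quantile
    of *nonzero* counts, then multiplied by a global scale constant
    (default: the median of the :math:`s_j`, keeping values on a count-like
    scale).  ``quantile=1.0`` reduces to total-sum scaling.  Returns a
    samples x ASVs float DataFrame.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    s = np.empty(table.n_samples)
    for i in range(table.n_samples):
        counts = table.counts[i]
        nz = counts[counts > 0]
        q = np.quantile(nz, quantile)
        s[i] = counts[counts <= q].sum()
    if scale is None:
        scale = float(np.median(s))
    norm = table.counts / s[:, None] * scale
    return pd.DataFrame(norm, index=table.sample_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# alpha / beta diversity
# ---------------------------------------------------------------------------


def shannon(table: CommunityTable) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (natural log)."""
    p = table.relative_abundances()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


def bray_curtis(data, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, BC(x, y) = sum|x-y| / sum(x+y).

    ``data`` may be a :class:`CommunityTable` (computed on counts), a
    DataFrame (rows = samples) or a plain array with ``ids``.  Pairs where
    both samples are all-zero are undefined and raise.
    """
    if isinstance(data, CommunityTable):
        values, ids = data.counts.astype(float), data.sample_ids
    elif isinstance(data, pd.DataFrame):
        values, ids = data.to_numpy(dtype=float), list(data.index.astype(str))
    else:
        values = np.asarray(data, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if (values.sum(axis=1) == 0).any():
        raise ValidationError("all-zero sample: Bray-Curtis undefined")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(map(str, ids)))


# ---------------------------------------------------------------------------
# shared / unique ASV fractions
# ---------------------------------------------------------------------------


def shared_unique_fractions(
    tables: dict[str, CommunityTable] | dict[tuple, CommunityTable],
) -> pd.DataFrame:
    """Partition each substrate's presence set into unique/shared fractions.

    ``tables`` maps a substrate label (or a ``(substrate, time)`` tuple) to
    the community table of that group; keys sharing a time are compared
    with each other.  For each focal group the set of ASVs present
    (count > 0 in any sample) is partitioned into: unique to the focal
    substrate, shared with exactly one other substrate (one category per
    other substrate), and shared with all substrates.  Fractions are of the
    focal presence set and sum to 1.  Supports 2 or 3 substrates per time.
    """
    # normalise keys to (substrate, time)
    keyed: dict[tuple[str, str], CommunityTable] = {}
    for k, t in tables.items():
        if isinstance(k, tuple):
            sub, tm = str(k[0]), str(k[1])
        else:
            sub, tm = str(k), "all"
        keyed[(sub, tm)] = t
    records = []
    times = sorted({tm for _, tm in keyed})
    for tm in times:
        groups = {sub: t for (sub, tm2), t in keyed.items() if tm2 == tm}
        if not 2 <= len(groups) <= 3:
            raise ValueError("shared_unique_fractions supports 2 or 3 substrates per time")
        presence = {}
        for sub, t in groups.items():
            present = {a for a, c in zip(t.asv_ids, t.counts.sum(axis=0)) if c > 0}
            if not present:
                raise ValidationError(f"substrate {sub!r} at time {tm!r}: empty presence set")
            presence[sub] = present
        for focal in groups:
            others = [s for s in groups if s != focal]
            focal_set = presence[focal]
            n = len(focal_set)
            in_all = focal_set.intersection(*(presence[o] for o in others))
            rec = {"substrate": focal, "time": tm, "n_asvs": n}
            rec["unique"] = sum(
                1 for a in focal_set if all(a not in presence[o] for o in others)
            ) / n
            for o in others:
                rec[f"shared_with_{o}"] = sum(
                    1
                    for a in focal_set
                    if a in presence[o]
                    and all(a not in presence[o2] for o2 in others if o2 != o)
                ) / n
            rec["shared_with_all"] = len(in_all) / n if len(others) > 1 else np.nan
            records.append(rec)
    df = pd.DataFrame(records)
    frac_cols = [c for c in df.columns if c not in ("substrate", "time", "n_asvs")]
    sums = df[frac_cols].sum(axis=1, skipna=True)
    assert np.allclose(sums, 1.0, atol=1e-9)
    return df


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _lower_triangle(dm: DistanceMatrix) -> np.ndarray:
    data = dm.data
    i, j = np.tril_indices(data.shape[0], k=-1)
    return data[i, j]


def _align_second(d1: DistanceMatrix, d2: DistanceMatrix) -> DistanceMatrix:
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices have different id sets")
    if tuple(d1.ids) != tuple(d2.ids):
        d2 = d2.filter(d1.ids)
    return d2


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed=0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the lower-triangle entries; the
    p-value permutes rows and columns of ``d2`` simultaneously.  Random
    permutation p-values use the add-one convention
    ``(count + 1) / (permutations + 1)`` so p is never 0.  With
    ``exhaustive=True`` (n <= 8 ids) all n! relabelings are enumerated and
    the p-value is the exact tail fraction (the identity permutation is in
    the reference set, so no smoothing is applied).

    ``alternative``: ``"greater"`` (default, the distance-decay direction),
    ``"less"`` or ``"two-sided"``.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d2 = _align_second(d1, d2)
    n = len(d1.ids)
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 ids")
    x = _lower_triangle(d1)
    y2 = d2.data
    y = y2[np.tril_indices(n, k=-1)]
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    xc = x - x.mean()
    xnorm = np.linalg.norm(xc)
    tril = np.tril_indices(n, k=-1)

    def perm_r(perm: np.ndarray) -> float:
        yp = y2[np.ix_(perm, perm)][tril]
        yc = yp - yp.mean()
        return float(xc @ yc / (xnorm * np.linalg.norm(yc)))

    eps = 1e-12
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        rs = np.array([perm_r(np.array(p)) for p in itertools.permutations(range(n))])
        total = math.factorial(n)
        if alternative == "greater":
            p = (rs >= r_obs - eps).sum() / total
        elif alternative == "less":
            p = (rs <= r_obs + eps).sum() / total
        else:
            p = (np.abs(rs) >= abs(r_obs) - eps).sum() / total
        return r_obs, float(p)

    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    rng = _rng(seed)
    rs = np.array([perm_r(rng.permutation(n)) for _ in range(permutations)])
    if alternative == "greater":
        count = (rs >= r_obs - eps).sum()
    elif alternative == "less":
        count = (rs <= r_obs + eps).sum()
    else:
        count = (np.abs(rs) >= abs(r_obs) - eps).sum()
    return r_obs, float((count + 1) / (permutations + 1))
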