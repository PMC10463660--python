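"""The two-step null-model framework for partitioning community assembly.

Step 1 (phylogenetic turnover): for every pair of local communities the
abundance-weighted beta mean nearest taxon distance (betaMNTD) is compared
with a null distribution obtained by shuffling taxa across the tips of the
phylogeny.  The standardised deviate is the beta nearest taxon index,

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null),

with sd using the reps-1 denominator.  |betaNTI| > 2 flags turnover
significantly shaped by selection: betaNTI < -2 homogeneous selection
(less turnover than expected), betaNTI > +2 heterogeneous selection.

Step 2 (taxonomic turnover): pairs not resolved by step 1 are classified
with the abundance-based Raup-Crick metric on Bray-Curtis (RCbray).  Null
communities are assembled from the group's metacommunity -- taxa recruited
without replacement with probability proportional to occupancy until the
observed richness is reached (one read each), remaining reads drawn with
probability proportional to metacommunity relative abundance until the
observed depth is reached -- and

    RCbray = 2 * [(#{BC_null < BC_obs} + 0.5 * #{BC_null = BC_obs}) / reps] - 1,

bounded in [-1, 1].  RCbray < -0.95 indicates homogenising dispersal,
RCbray > +0.95 dispersal limitation, and |RCbray| <= 0.95 drift.

Threshold comparisons are strict; exact boundary values fall through to
the next step.  Pairs whose null sd is below 1e-12 (e.g. star phylogenies)
are flagged undefined and excluded from classification denominators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .io import CommunityTable, ValidationError
from .metrics import _rng

logger = logging.getLogger("phyloturn")

__all__ = [
    "PROCESSES",
    "cophenetic",
    "bmntd",
    "bmntd_all_pairs",
    "bnti_all_pairs",
    "rcbray_pair",
    "rcbray_all_pairs",
    "classify",
    "summarize",
    "median_bnti",
    "env_correlation",
    "partition_assembly",
]

PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenising_dispersal",
    "dispersal_limitation",
    "drift",
)

_SD_FLOOR = 1e-12  # null sd below this => betaNTI undefined


# ---------------------------------------------------------------------------
# phylogenetic distances
# ---------------------------------------------------------------------------


def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Patristic distance matrix: branch-length path sums between tips."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValidationError("tree has fewer than 2 tips")
    return tree.tip_tip_distances()


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundances or uniform presence."""
    counts = np.asarray(counts, dtype=float)
    present = counts > 0
    if weighted:
        w = np.where(present, counts, 0.0)
    else:
        w = present.astype(float)
    totals = w.sum(axis=-1, keepdims=True)
    return np.divide(w, totals, out=np.zeros_like(w), where=totals > 0)


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------


def bmntd(
    abund_a: np.ndarray,
    abund_b: np.ndarray,
    dist: np.ndarray,
    weighted: bool = True,
) -> float:
    """betaMNTD between two communities over a shared taxon ordering.

    ``abund_a`` / ``abund_b`` are abundance vectors (any positive scale)
    aligned to ``dist``, the taxon patristic distance matrix.  Each taxon
    present in one community contributes its (relative-abundance) weight
    times the distance to its nearest taxon present in the other; a taxon
    shared by both communities contributes 0.  The two directed sums are
    averaged.
    """
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    ia, ib = a > 0, b > 0
    if not ia.any() or not ib.any():
        raise ValidationError("empty community in betaMNTD")
    sub = dist[np.ix_(ia, ib)]
    min_a = sub.min(axis=1)  # nearest taxon in b, for each taxon in a
    min_b = sub.min(axis=0)
    if weighted:
        wa = a[ia] / a[ia].sum()
        wb = b[ib] / b[ib].sum()
    else:
        wa = np.full(ia.sum(), 1.0 / ia.sum())
        wb = np.full(ib.sum(), 1.0 / ib.sum())
    return 0.5 * (float(wa @ min_a) + float(wb @ min_b))


def _nearest_taxon_matrix(dist: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[s, i] = distance from taxon i to its nearest taxon present in sample s."""
    n_samples = presence.shape[0]
    M = np.empty((n_samples, dist.shape[0]))
    for s in range(n_samples):
        M[s] = dist[:, presence[s]].min(axis=1)
    return M


def bmntd_all_pairs(
    counts: np.ndarray, dist: np.ndarray, weighted: bool = True
) -> np.ndarray:
    """All-pairs betaMNTD matrix (samples x samples) for a count matrix."""
    counts = np.asarray(counts, dtype=float)
    presence = counts > 0
    if (~presence.any(axis=1)).any():
        raise ValidationError("empty sample in betaMNTD")
    W = _weights(counts, weighted)
    M = _nearest_taxon_matrix(dist, presence)
    directed = W @ M.T  # directed[a, b] = sum_i w_ia * min_{j in b} D(i, j)
    out = 0.5 * (directed + directed.T)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------


def bnti_all_pairs(
    table: CommunityTable,
    tree: TreeNode | None = None,
    dist: DistanceMatrix | None = None,
    reps: int = 999,
    seed=0,
    weighted: bool = True,
    null_scheme: str = "shared",
) -> pd.DataFrame:
    """betaNTI for every unordered sample pair of ``table``.

    The null shuffles the taxon <-> tip assignment.  Under
    ``null_scheme="shared"`` (default, the framework convention) one
    permutation per randomisation is applied to the whole table, so all
    pairs share the same null draw within a rep; taxa shared by a pair
    keep contributing 0 under any shared relabeling, so a pair with
    exactly identical membership has a degenerate (all-zero) null and is
    flagged undefined.  ``null_scheme="independent"`` relabels the two
    communities of each pair independently per rep, which breaks
    self-matching and yields a dispersed null even for identical pairs.

    Returns a long-format DataFrame with columns ``sample_a``,
    ``sample_b``, ``bmntd_obs``, ``null_mean``, ``null_sd``, ``bnti``,
    ``undefined``.
    """
    if reps < 99:
        raise ValueError("need at least 99 randomisations")
    if null_scheme not in ("shared", "independent"):
        raise ValueError(f"unknown null_scheme {null_scheme!r}")
    if dist is None:
        if tree is None:
            raise ValueError("provide a tree or a distance matrix")
        dist = cophenetic(tree)
    if set(dist.ids) != set(table.asv_ids):
        raise ValidationError("table ASVs and distance-matrix ids differ; align first")
    D = dist.filter(table.asv_ids).data
    n_taxa = table.n_asvs
    counts = table.counts.astype(float)
    obs = bmntd_all_pairs(counts, D, weighted=weighted)

    rng = _rng(seed)
    S = table.n_samples
    sums = np.zeros((S, S))
    sumsq = np.zeros((S, S))
    if null_scheme == "shared":
        for _ in range(reps):
            p = rng.permutation(n_taxa)
            null = bmntd_all_pairs(counts, D[np.ix_(p, p)], weighted=weighted)
            sums += null
            sumsq += null * null
    else:
        # each sample's taxa are relabelled by its own permutation per rep;
        # M[s, tip] = distance from any tip to sample s's nearest relabelled
        # taxon, and W scattered onto relabelled positions gives all pairs
        # by one matrix product, as in the observed computation
        presence = counts > 0
        W = _weights(counts, weighted)
        idx = [np.flatnonzero(presence[s]) for s in range(S)]
        for _ in range(reps):
            perms = [rng.permutation(n_taxa) for _ in range(S)]
            M = np.empty((S, n_taxa))
            Wp = np.zeros((S, n_taxa))
            for s in range(S):
                M[s] = D[:, perms[s][idx[s]]].min(axis=1)
                Wp[s, perms[s][idx[s]]] = W[s, idx[s]]
            directed = Wp @ M.T
            null = 0.5 * (directed + directed.T)
            np.fill_diagonal(null, 0.0)
            sums += null
            sumsq += null * null

    mean = sums / reps
    var = (sumsq - reps * mean**2) / (reps - 1)
    sd = np.sqrt(np.maximum(var, 0.0))

    records = []
    n_undefined = 0
    for a in range(S):
        for b in range(a + 1, S):
            undefined = sd[a, b] < _SD_FLOOR
            if undefined:
                n_undefined += 1
                bnti = np.nan
            else:
                bnti = (obs[a, b] - mean[a, b]) / sd[a, b]
            records.append(
                {
                    "sample_a": table.sample_ids[a],
                    "sample_b": table.sample_ids[b],
                    "bmntd_obs": obs[a, b],
                    "null_mean": mean[a, b],
                    "null_sd": sd[a, b],
                    "bnti": bnti,
                    "undefined": undefined,
                }
            )
    if n_undefined:
        logger.warning(
            "bnti_all_pairs: %d pairs have a degenerate null (sd < %g); "
            "betaNTI undefined and excluded from classification",
            n_undefined,
            _SD_FLOOR,
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# RCbray
# ---------------------------------------------------------------------------


def _metacommunity_stats(meta_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy (number of samples occupied) and pooled relative abundance."""
    occupancy = (meta_counts > 0).sum(axis=0).astype(float)
    totals = meta_counts.sum(axis=0).astype(float)
    rel = totals / totals.sum()
    return occupancy, rel


def _null_community(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    rel_abund: np.ndarray,
    richness: int,
    depth: int,
) -> np.ndarray:
    """One null community: occupancy-weighted membership, abundance-weighted reads.

    Taxa are recruited without replacement with probability proportional
    to occupancy until ``richness`` is reached (Efraimidis-Spirakis via
    Gumbel keys), each seeded with one read; the remaining
    ``depth - richness`` reads are multinomial with probability
    proportional to pooled relative abundance restricted to the recruits.
    """
    candidates = np.flatnonzero(occupancy > 0)
    if richness > candidates.size:
        raise ValidationError(
            f"sample richness {richness} exceeds metacommunity richness {candidates.size}"
        )
    keys = np.log(occupancy[candidates]) + rng.gumbel(size=candidates.size)
    chosen = candidates[np.argpartition(-keys, richness - 1)[:richness]]
    counts = np.zeros(occupancy.size, dtype=np.int64)
    counts[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        p = rel_abund[chosen]
        psum = p.sum()
        if psum <= 0:
            p = np.full(richness, 1.0 / richness)
        else:
            p = p / psum
        counts[chosen] += rng.multinomial(remaining, p)
    return counts


def _rc_from_null(bc_obs: float, bc_null: np.ndarray) -> float:
    reps = bc_null.size
    less = (bc_null < bc_obs - 1e-12).sum()
    equal = (np.abs(bc_null - bc_obs) <= 1e-12).sum()
    return 2.0 * ((less + 0.5 * equal) / reps) - 1.0


def _bc_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis between two relative-abundance vectors."""
    return float(np.abs(x - y).sum() / (x + y).sum())


def rcbray_pair(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    metacommunity: CommunityTable,
    reps: int = 999,
    seed=0,
) -> float:
    """RCbray for one pair of samples against a metacommunity.

    The observed Bray-Curtis is computed on the pair's relative abundances
    (so observed and null are comparable when depths differ); each
    randomisation assembles a fresh null community per sample at the
    sample's observed richness and read depth.
    """
    if reps < 99:
        raise ValueError("need at least 99 randomisations")
    rng = _rng(seed)
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("empty sample in RCbray")
    occupancy, rel = _metacommunity_stats(metacommunity.counts)
    rich_a, depth_a = int((a > 0).sum()), int(a.sum())
    rich_b, depth_b = int((b > 0).sum()), int(b.sum())
    bc_obs = _bc_pair(a / depth_a, b / depth_b)
    bc_null = np.empty(reps)
    for r in range(reps):
        na = _null_community(rng, occupancy, rel, rich_a, depth_a)
        nb = _null_community(rng, occupancy, rel, rich_b, depth_b)
        bc_null[r] = _bc_pair(na / depth_a, nb / depth_b)
    return _rc_from_null(bc_obs, bc_null)


def rcbray_all_pairs(
    table: CommunityTable,
    reps: int = 999,
    seed=0,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """RCbray for sample pairs of ``table``, the table itself being the
    metacommunity (the within-group convention: occupancy and pooled
    abundances come from the same substrate-by-time group).

    Within each randomisation one null community is assembled per sample
    and shared across all pairs (mirroring the shared tip shuffle of the
    betaNTI null); per-pair marginal null distributions are identical to
    :func:`rcbray_pair`.  ``pairs`` restricts output to the listed pairs.

    Returns columns ``sample_a``, ``sample_b``, ``bc_obs``, ``rcbray``.
    """
    if reps < 99:
        raise ValueError("need at least 99 randomisations")
    rng = _rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("empty sample in RCbray")
    occupancy, rel = _metacommunity_stats(counts)
    richness = (counts > 0).sum(axis=1)
    S = table.n_samples
    relab = counts / totals[:, None]
    bc_obs = squareform(pdist(relab, metric="braycurtis"))

    less = np.zeros((S, S))
    equal = np.zeros((S, S))
    null_rel = np.empty((S, counts.shape[1]))
    for _ in range(reps):
        for s in range(S):
            null_rel[s] = _null_community(
                rng, occupancy, rel, int(richness[s]), int(totals[s])
            ) / totals[s]
        bc_null = squareform(pdist(null_rel, metric="braycurtis"))
        less += bc_null < bc_obs - 1e-12
        equal += np.abs(bc_null - bc_obs) <= 1e-12
    rc = 2.0 * ((less + 0.5 * equal) / reps) - 1.0

    if pairs is None:
        pairs = [
            (table.sample_ids[a], table.sample_ids[b])
            for a in range(S)
            for b in range(a + 1, S)
        ]
    index = {s: i for i, s in enumerate(table.sample_ids)}
    records = [
        {
            "sample_a": sa,
            "sample_b": sb,
            "bc_obs": bc_obs[index[sa], index[sb]],
            "rcbray": rc[index[sa], index[sb]],
        }
        for sa, sb in pairs
    ]
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------


def classify(
    pairs: pd.DataFrame,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Assign each pair its dominant assembly process.

    betaNTI < -t -> homogeneous selection; betaNTI > +t -> heterogeneous
    selection; otherwise RCbray < -u -> homogenising dispersal,
    RCbray > +u -> dispersal limitation, else drift.  Comparisons are
    strict, so exact boundary values fall through.  Pairs flagged
    ``undefined`` receive no process.  Pairs that need RCbray but lack it
    raise.
    """
    df = pairs.copy()
    undefined = df["undefined"].to_numpy() if "undefined" in df else np.zeros(len(df), bool)
    bnti = df["bnti"].to_numpy(dtype=float)
    needs_rc = ~undefined & (np.abs(bnti) <= bnti_threshold)
    if needs_rc.any():
        if "rcbray" not in df:
            raise ValidationError("RCbray required for pairs with |betaNTI| <= threshold")
        rc = df["rcbray"].to_numpy(dtype=float)
        if np.isnan(rc[needs_rc]).any():
            bad = df.loc[needs_rc & df["rcbray"].isna(), ["sample_a", "sample_b"]].iloc[0]
            raise ValidationError(
                f"missing RCbray for pair ({bad.sample_a}, {bad.sample_b}) "
                "with |betaNTI| <= threshold"
            )
    else:
        rc = df["rcbray"].to_numpy(dtype=float) if "rcbray" in df else np.full(len(df), np.nan)

    process = np.full(len(df), None, dtype=object)
    process[~undefined & (bnti < -bnti_threshold)] = "homogeneous_selection"
    process[~undefined & (bnti > bnti_threshold)] = "heterogeneous_selection"
    process[needs_rc & (rc < -rc_threshold)] = "homogenising_dispersal"
    process[needs_rc & (rc > rc_threshold)] = "dispersal_limitation"
    process[needs_rc & (np.abs(rc) <= rc_threshold)] = "drift"
    df["process"] = process
    return df


def summarize(
    pairs: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    group_keys: tuple[str, ...] = ("substrate", "time"),
) -> pd.DataFrame:
    """Per-group percentage of pairwise comparisons assigned each process.

    Pairs must have been formed within groups: both samples of every pair
    must share the grouping values.  Undefined pairs are reported in a
    separate ``n_undefined`` column and excluded from the percentage
    denominator.  Percentages sum to 100 within each group.
    """
    df = pairs.copy()
    if meta is not None:
        for key in group_keys:
            va = meta.loc[df["sample_a"], key].to_numpy()
            vb = meta.loc[df["sample_b"], key].to_numpy()
            if (va != vb).any():
                raise ValidationError(
                    f"pair crosses {key!r} groups; pairs must be formed within groups"
                )
            df[key] = va
        group_cols = list(group_keys)
    else:
        df["_group"] = "all"
        group_cols = ["_group"]

    records = []
    for group, sub in df.groupby(group_cols, sort=True):
        if not isinstance(group, tuple):
            group = (group,)
        undefined = sub["undefined"] if "undefined" in sub else pd.Series(False, index=sub.index)
        classified = sub[~undefined.astype(bool)]
        n = len(classified)
        if n == 0:
            raise ValidationError(f"group {group}: no classified pairs")
        if classified["process"].isna().any():
            raise ValidationError(f"group {group}: unclassified pairs present")
        rec = dict(zip(group_cols, group))
        counts = classified["process"].value_counts()
        for proc in PROCESSES:
            rec[proc] = 100.0 * counts.get(proc, 0) / n
        rec["n_pairs"] = n
        rec["n_undefined"] = int(undefined.sum())
        records.append(rec)
    out = pd.DataFrame(records)
    assert np.allclose(out[list(PROCESSES)].sum(axis=1), 100.0, atol=1e-9)
    return out


def median_bnti(
    pairs: pd.DataFrame,
    meta: pd.DataFrame,
    site_key: str = "site",
    substrate_key: str = "substrate",
) -> pd.DataFrame:
    """Median betaNTI per (site, substrate).

    For each sample, the betaNTI values of all its pairwise comparisons
    (within its substrate-by-time group) are collected; values are pooled
    over the site's samples and over all sampling times, and the median of
    the pool is reported.  Sites with no defined betaNTI are omitted with
    a warning.
    """
    pools: dict[tuple[str, str], list[float]] = {}
    for _, row in pairs.iterrows():
        if not np.isfinite(row["bnti"]):
            continue
        for sample in (row["sample_a"], row["sample_b"]):
            key = (str(meta.loc[sample, site_key]), str(meta.loc[sample, substrate_key]))
            pools.setdefault(key, []).append(float(row["bnti"]))
    all_keys = {
        (str(r[site_key]), str(r[substrate_key])) for _, r in meta.iterrows()
    }
    omitted = all_keys - set(pools)
    if omitted:
        logger.warning("median_bnti: no defined betaNTI for %s; omitted", sorted(omitted))
    records = [
        {site_key: site, substrate_key: substrate, "median_bnti": float(np.median(v)), "n": len(v)}
        for (site, substrate), v in sorted(pools.items())
    ]
    return pd.DataFrame(records)


def env_correlation(
    median_df: pd.DataFrame,
    env: pd.DataFrame,
    variable: str,
    site_key: str = "site",
) -> tuple[float, float, float]:
    """OLS of per-site median betaNTI on one environmental variable.

    Returns (slope, Pearson r, two-tailed p).  Requires at least 3 sites
    present in both inputs and nonzero variance on both sides.
    """
    merged = median_df.set_index(site_key).join(env[[variable]], how="inner")
    merged = merged.dropna(subset=["median_bnti", variable])
    if len(merged) < 3:
        raise ValidationError("need at least 3 sites with both values")
    x = merged[variable].to_numpy(dtype=float)
    y = merged["median_bnti"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in betaNTI or environmental variable")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


# ---------------------------------------------------------------------------
# grouped pipeline
# ---------------------------------------------------------------------------


def partition_assembly(
    table: CommunityTable,
    tree: TreeNode,
    meta: pd.DataFrame,
    group_keys: tuple[str, ...] = ("substrate", "time"),
    reps_bnti: int = 999,
    reps_rc: int = 999,
    seed=0,
    weighted: bool = True,
    min_reads: int = 1000,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
    null_scheme: str = "shared",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full two-step framework separately within each group.

    Samples with fewer than ``min_reads`` reads are dropped first (low
    library sizes obscure biological patterns); betaNTI and RCbray run on
    the remaining raw counts.  RCbray uses the group's samples as the
    metacommunity.  Returns (classified pairs, per-group profiles).
    """
    keep = table.sample_totals() >= min_reads
    if not keep.all():
        logger.info(
            "partition_assembly: dropped %d samples with < %d reads",
            int((~keep).sum()),
            min_reads,
        )
        table = table.select_samples(
            [s for s, k in zip(table.sample_ids, keep) if k]
        )
    dist = cophenetic(tree).filter(table.asv_ids)
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    groups = meta.loc[table.sample_ids].groupby(list(group_keys), sort=True)
    all_pairs = []
    for g_idx, (group, gmeta) in enumerate(groups):
        samples = [s for s in table.sample_ids if s in set(gmeta["sample_id"])]
        if len(samples) < 2:
            logger.warning("group %s: fewer than 2 samples, skipped", (group,))
            continue
        gtable = table.select_samples(samples)
        s_bnti, s_rc = np.random.SeedSequence(
            entropy=seed_seq.entropy, spawn_key=(g_idx,)
        ).spawn(2)
        pairs = bnti_all_pairs(
            gtable, dist=dist, reps=reps_bnti, seed=np.random.default_rng(s_bnti),
            weighted=weighted, null_scheme=null_scheme,
        )
        rc = rcbray_all_pairs(gtable, reps=reps_rc, seed=np.random.default_rng(s_rc))
        pairs = pairs.merge(rc, on=["sample_a", "sample_b"])
        all_pairs.append(classify(pairs, bnti_threshold, rc_threshold))
    if not all_pairs:
        raise ValidationError("no group with at least 2 samples")
    classified = pd.concat(all_pairs, ignore_index=True)
    profiles = summarize(classified, meta, group_keys)
    return classified, profiles
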