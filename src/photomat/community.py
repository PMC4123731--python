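"""ARISA community profiles, ordination and structure-function concordance.

Fragment profiles are binned into fixed 2-bp windows anchored at 100 bp
(anonymous OTUs), merged across PCR triplicates by a >=2-of-3 presence
rule, Hellinger-transformed and compared by Bray-Curtis dissimilarity.
Community structure is visualised by non-metric multidimensional scaling
and tested by ANOSIM; the physiology side is ordinated by classical metric
MDS of z-standardised parameter means; the two ordinations are compared by
symmetric Procrustes superimposition with a Monte-Carlo permutation test.

Permutation p-values follow the (1 + more-extreme) / (1 + n_permutations)
convention throughout, and every permutation stream is seeded.
"""

from __future__ import annotations

from itertools import permutations as _it_permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS as _SKMDS

from .datatypes import (
    ANOSIMResult,
    OrdinationResult,
    ProcrustesResult,
    ValidationError,
)

__all__ = [
    "bin_fragments",
    "consensus_profile",
    "hellinger",
    "bray_curtis",
    "nmds",
    "metric_mds_physiology",
    "anosim",
    "procrustes_test",
    "shared_otu_summary",
]


def bin_fragments(profiles: pd.DataFrame, window: float = 2.0,
                  anchor: float = 100.0) -> pd.DataFrame:
    """Bin fragment intensities into fixed consecutive length windows.

    ``profiles`` is a long table (sample, replicate, fragment_bp,
    intensity). Intensities are summed within [anchor + k*window,
    anchor + (k+1)*window) bins and converted to relative abundances per
    replicate. Replicates with no fragments yield an all-zero row and are
    listed in the returned frame's ``attrs['empty_replicates']``.
    """
    if window < 1:
        raise ValidationError("bin window must be >= 1 bp")
    req = {"sample", "replicate", "fragment_bp", "intensity"}
    if not req.issubset(profiles.columns):
        raise ValidationError(f"profiles must have columns {sorted(req)}")
    p = profiles.copy()
    p["bin"] = (anchor + window *
                np.floor((p["fragment_bp"] - anchor) / window)).astype(float)
    table = (
        p.pivot_table(index=["sample", "replicate"], columns="bin",
                      values="intensity", aggfunc="sum", fill_value=0.0)
        .sort_index(axis=1)
    )
    totals = table.sum(axis=1)
    empty = totals == 0
    rel = table.div(totals.where(~empty, 1.0), axis=0)
    rel.attrs["empty_replicates"] = [i for i, e in zip(table.index, empty) if e]
    rel.attrs["window_bp"] = window
    return rel


def consensus_profile(binned: pd.DataFrame, min_presence: int = 2,
                      n_replicates: int = 3) -> pd.DataFrame:
    """Merge replicate rows into one consensus row per sample.

    An OTU bin is retained iff it is nonzero in at least ``min_presence``
    of the ``n_replicates`` replicates; its consensus abundance is the
    mean of the nonzero replicate abundances, all other bins are zeroed.
    """
    rows = {}
    for sample, grp in binned.groupby(level="sample", sort=False):
        if len(grp) != n_replicates:
            raise ValidationError(
                f"sample {sample!r} has {len(grp)} replicates, expected {n_replicates}"
            )
        vals = grp.to_numpy(dtype=float)
        nonzero = (vals > 0).sum(axis=0)
        keep = nonzero >= min_presence
        with np.errstate(invalid="ignore"):
            mean_nz = np.where(keep, vals.sum(axis=0) /
                               np.maximum(nonzero, 1), 0.0)
        rows[sample] = mean_nz
    out = pd.DataFrame.from_dict(rows, orient="index", columns=binned.columns)
    out.index.name = "sample"
    return out


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of relative abundance per row.

    Transformed rows have unit sum of squares, which makes Euclidean
    geometry appropriate for abundance data. All-zero rows are an error.
    """
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError("abundances must be nonnegative")
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = list(table.index[zero])
        raise ValidationError(f"all-zero sample rows: {bad}")
    return pd.DataFrame(np.sqrt(vals / sums[:, None]),
                        index=table.index, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix, d = sum|a-b| / sum(a+b)."""
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError("abundances must be nonnegative")
    d = squareform(pdist(vals, metric="braycurtis"))
    dm = pd.DataFrame(d, index=table.index, columns=table.index)
    if np.isnan(d).any():
        dm.attrs["undefined_pairs"] = int(np.isnan(d).sum() // 2)
    return dm


def nmds(dm: pd.DataFrame, k: int = 2, restarts: int = 16,
         seed: int | None = 0, max_iter: int = 500) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1, best of random starts.

    SMACOF majorisation with isotonic-regression disparity updates; the
    reported stress is the normalised stress-1 of the best restart.
    """
    d = np.asarray(dm, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=True):
        raise ValidationError("dissimilarity matrix must be square symmetric")
    if k < 2:
        raise ValidationError("k must be >= 2")
    import inspect

    if "metric_mds" in inspect.signature(_SKMDS.__init__).parameters:
        kwargs = {"metric": "precomputed", "metric_mds": False,
                  "init": "random"}
    else:  # scikit-learn < 1.9
        kwargs = {"dissimilarity": "precomputed", "metric": False}
    mds = _SKMDS(
        n_components=k, n_init=restarts, max_iter=max_iter, eps=1e-9,
        random_state=seed, normalized_stress=True, **kwargs,
    )
    coords = mds.fit_transform(d)
    stress = float(mds.stress_)
    if not np.isfinite(stress):
        raise ValidationError("NMDS failed to converge in all restarts")
    cols = [f"axis{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.index, columns=cols),
        method="nmds", stress=stress, restarts=restarts, seed=seed,
    )


def metric_mds_physiology(means: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Classical metric MDS of z-standardised physiology means.

    ``means`` is mats x parameters (e.g. a_chl, y_max, i_k, i_max).
    Parameters are standardised to zero mean and unit SD (they carry
    incompatible units); constant columns are dropped with a warning
    recorded in the result. Euclidean distances are double-centred and
    eigen-decomposed; coordinates use the top-k nonnegative eigenvalues.
    """
    if means.shape[0] < 3:
        raise ValidationError("need >= 3 mats")
    vals = means.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(means.columns, sd) if s == 0]
    keep = sd > 0
    z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    d = squareform(pdist(z, metric="euclidean"))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0, None)
    coords = evecs[:, :k] * np.sqrt(pos[:k])[None, :]
    explained = pos / pos.sum() if pos.sum() > 0 else pos
    cols = [f"axis{i + 1}" for i in range(k)]
    res = OrdinationResult(
        coordinates=pd.DataFrame(coords, index=means.index, columns=cols),
        method="metric_mds", explained=explained[:k],
    )
    if dropped:
        res.coordinates.attrs["dropped_constant"] = dropped
    return res


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    """Clarke's R from the rank vector of condensed distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs, so that complete separation gives R = 1.
    """
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    m = n * (n - 1) / 2
    return float((rb - rw) / (m / 2.0))


def _distinct_relabelings(labels: np.ndarray):
    seen = set()
    for perm in _it_permutations(range(len(labels))):
        t = tuple(labels[list(perm)])
        if t not in seen:
            seen.add(t)
            yield np.asarray(t)


def anosim(dm: pd.DataFrame, groups, n_permutations: int = 9999,
           seed: int | None = 0, exact: bool = False) -> ANOSIMResult:
    """Analysis of Similarity: rank-based between- vs within-group test.

    ``groups`` maps each sample (in dm order) to its group label. The
    permutation p-value uses (1 + #{R_perm >= R_obs}) / (1 + n_perm) over
    seeded label permutations; with ``exact=True`` all distinct
    relabelings are enumerated instead and p is the exact proportion with
    R_perm >= R_obs (identity included).
    """
    d = np.asarray(dm, dtype=float)
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if len(labels) != n:
        raise ValidationError("groups length must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or np.any(counts < 2):
        raise ValidationError("need >= 2 groups with >= 2 members each")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same, n)

    if exact:
        count = 0
        total = 0
        for lab in _distinct_relabelings(labels):
            total += 1
            if _anosim_r(ranks, lab[iu[0]] == lab[iu[1]], n) >= r_obs - 1e-12:
                count += 1
        p = count / total
        n_perm = total
    else:
        if n_permutations < 99:
            import warnings

            warnings.warn("fewer than 99 permutations gives a coarse p-value",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        # vectorised over permutations: boolean within-mask per permutation
        perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
        within = perms[:, iu[0]] == perms[:, iu[1]]
        rb = np.where(~within, ranks, np.nan)
        rw = np.where(within, ranks, np.nan)
        m = n * (n - 1) / 2
        r_perm = (np.nanmean(rb, axis=1) - np.nanmean(rw, axis=1)) / (m / 2.0)
        p = (1 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1 + n_permutations)
        n_perm = n_permutations
    return ANOSIMResult(r=r_obs, p=float(p), n_permutations=n_perm,
                        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)})


def _procrustes_stat(a: np.ndarray, b: np.ndarray,
                     allow_reflection: bool = True):
    """Symmetric Procrustes m12^2 after centring and unit-norm scaling."""
    u, s, vt = np.linalg.svd(a.T @ b)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    trace = s.sum()
    return 1.0 - trace ** 2, u, vt, trace


def procrustes_test(
    ord_a: OrdinationResult | pd.DataFrame,
    ord_b: OrdinationResult | pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = 0,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """Symmetric Procrustes concordance of two ordinations with a
    Monte-Carlo permutation test.

    Both configurations are centred and scaled to unit Frobenius norm;
    m12^2 = 1 - (sum of singular values of A'B)^2 and r = sqrt(1 - m12^2).
    The null distribution permutes the row order of the second
    configuration; p = (1 + #{m12^2_perm <= m12^2_obs}) / (1 + n_perm).
    The sample sets (and ordering) of the two ordinations must agree.
    """
    a_df = ord_a.coordinates if isinstance(ord_a, OrdinationResult) else ord_a
    b_df = ord_b.coordinates if isinstance(ord_b, OrdinationResult) else ord_b
    if list(a_df.index) != list(b_df.index):
        raise ValidationError("ordinations cover different sample sets/order")
    if a_df.shape[1] != b_df.shape[1]:
        raise ValidationError("ordinations have different dimensionality")
    a = a_df.to_numpy(dtype=float)
    b = b_df.to_numpy(dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("degenerate (all-coincident) configuration")
    a /= na
    b /= nb
    m2, u, vt, trace = _procrustes_stat(a, b, allow_reflection)
    m2 = float(np.clip(m2, 0.0, 1.0))
    rotation = vt.T @ u.T  # maps b onto a
    r = float(np.sqrt(1.0 - m2))

    p = np.nan
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(b))
            bp = b[perm]
            bp = bp - bp.mean(axis=0)
            m2p, *_ = _procrustes_stat(a, bp, allow_reflection)
            if m2p <= m2 + 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    return ProcrustesResult(
        rotation=rotation, scale=float(trace),
        translation=np.zeros(a.shape[1]), m12_squared=m2, r=r,
        p=float(p), n_permutations=n_permutations,
    )


def shared_otu_summary(site_tables: dict[str, pd.DataFrame]) -> dict:
    """Shared-OTU accounting across sites.

    ``site_tables`` maps each site to its mats x OTU-bin consensus table.
    An OTU is present at a site if it is nonzero in at least one mat of
    that site. Reports the total OTU count over all sites, the ubiquitous
    count (present at every site) with its percentage, the single-site
    count, and pairwise shared percentages (shared / union per site pair).
    """
    if len(site_tables) < 2:
        raise ValidationError("need >= 2 sites")
    presence: dict[str, set] = {}
    for site, table in site_tables.items():
        vals = table.to_numpy(dtype=float)
        present = np.asarray(table.columns)[(vals > 0).any(axis=0)]
        presence[site] = set(present.tolist())
    sites = list(presence)
    all_otus = set().union(*presence.values())
    ubiquitous = set.intersection(*presence.values())
    single_site = {
        o for o in all_otus
        if sum(o in presence[s] for s in sites) == 1
    }
    pairwise = {}
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1:]:
            union = presence[s1] | presence[s2]
            shared = presence[s1] & presence[s2]
            pairwise[f"{s1}-{s2}"] = 100.0 * len(shared) / len(union) if union else 0.0
    total = len(all_otus)
    return {
        "total_otus": total,
        "ubiquitous": len(ubiquitous),
        "ubiquitous_pct": 100.0 * len(ubiquitous) / total if total else 0.0,
        "single_site": len(single_site),
        "pairwise_shared_pct": pairwise,
    }
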