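"""Between-sample phylogenetic dissimilarity, ordination and driver tests.

UniFrac (unweighted and normalized weighted) and PCoA are delegated to
scikit-bio; the permutation statistics (Mantel, ANOSIM) and the BEST/BioEnv
exhaustive environmental-subset search are implemented here so that their
contracts are explicit: Spearman rank correlation on distance-matrix upper
triangles, one-sided (positive-association) permutation p-values with the
add-one rule, seeded RNG, and exhaustive enumeration of all n! relabellings
whenever that is cheaper than the requested number of random permutations.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .alpha import bh_fdr
from .errors import ConfigurationError, ConstantInputError, DatasetError
from .io import ENV_VARIABLES, OtuTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------

def unifrac(table: OtuTable, tree, weighted: bool = False) -> DistanceMatrix:
    """UniFrac distance matrix between all samples.

    Unweighted UniFrac is the fraction of branch length unique to either
    sample's observed leaf set over the branch length of their union;
    weighted UniFrac is the normalized abundance-weighted variant so both
    lie in [0, 1].  Callers should rarefy to a common depth first; unequal
    totals are only logged.
    """
    totals = table.sample_totals()
    if totals.nunique() > 1:
        logger.info("unifrac: sample totals are unequal (%d distinct); "
                    "consider rarefying first", totals.nunique())
    tips = {tip.name for tip in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise DatasetError(f"OTUs missing from tree: {missing[:5]}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    return beta_diversity(metric, table.counts.to_numpy(),
                          ids=table.sample_ids, taxa=table.otu_ids,
                          tree=tree, validate=True, **kwargs)


def pcoa(dm: DistanceMatrix):
    """Principal-coordinate analysis of a distance matrix.

    Returns a scikit-bio ``OrdinationResults``; axes are ordered by
    eigenvalue and negative eigenvalues are retained in ``.eigvals`` rather
    than silently dropped (proportions are computed over the eigenvalue
    sum as reported by scikit-bio).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)
    return _skbio_pcoa(dm, method="eigh")


def env_distance(metadata: pd.DataFrame, variables) -> DistanceMatrix:
    """Euclidean distance on z-standardized environmental variables.

    Each variable is centred and scaled to unit sample variance (ddof=1)
    across samples before computing Euclidean distances, so every variable
    enters on a common scale.
    """
    if isinstance(variables, str):
        variables = [variables]
    variables = list(variables)
    if not variables:
        raise ConfigurationError("env_distance requires >= 1 variable")
    X = metadata[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ConstantInputError(f"constant variables: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(Z, metric="euclidean"))
    return DistanceMatrix(d, ids=list(metadata.index))


# ---------------------------------------------------------------------------
# permutation statistics
# ---------------------------------------------------------------------------

def _upper(dm: DistanceMatrix) -> np.ndarray:
    data = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    iu = np.triu_indices(data.shape[0], k=1)
    return data[iu]


def _perm_iter(n: int, n_perm: int, rng):
    """Yield permutations: all n! if that is <= n_perm, else random draws.

    Returns (iterator, n_drawn, exhaustive_flag).
    """
    if math.factorial(n) <= n_perm:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms, len(perms), True
    perms = (rng.permutation(n) for _ in range(n_perm))
    return perms, n_perm, False


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 9999,
           seed=None) -> tuple[float, float]:
    """Spearman Mantel test between two distance matrices.

    r is the Spearman correlation of the upper triangles; p is the
    one-sided (greater) permutation p-value over row/column relabellings of
    the second matrix, with the add-one rule ``(hits + 1) / (n_perm + 1)``.
    When n! <= `n_perm` all relabellings are enumerated and the p-value is
    exact (without the add-one correction, which only applies to sampling).
    """
    d1, d2, ids = _align(dm1, dm2)
    n = d1.shape[0]
    if n < 4:
        raise ConfigurationError("mantel requires >= 4 samples")
    iu = np.triu_indices(n, k=1)
    x = scipy.stats.rankdata(d1[iu])
    r_obs = _pearson(x, scipy.stats.rankdata(d2[iu]))
    rng = np.random.default_rng(seed)
    perms, n_drawn, exhaustive = _perm_iter(n, n_perm, rng)
    hits = 0
    for p in perms:
        perm_vals = d2[np.ix_(p, p)][iu]
        r_p = _pearson(x, scipy.stats.rankdata(perm_vals))
        if r_p >= r_obs - 1e-12:
            hits += 1
    if exhaustive:
        pval = hits / n_drawn
    else:
        pval = (hits + 1) / (n_drawn + 1)
    return float(r_obs), float(pval)


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ConstantInputError("constant distance ranks")
    return float((a * b).sum() / denom)


def _align(dm1, dm2):
    if not isinstance(dm1, DistanceMatrix):
        dm1 = DistanceMatrix(dm1)
    if not isinstance(dm2, DistanceMatrix):
        dm2 = DistanceMatrix(dm2)
    if set(dm1.ids) != set(dm2.ids):
        raise DatasetError("distance matrices have mismatched sample ids")
    dm2 = dm2.filter(dm1.ids)
    return dm1.data, dm2.data, list(dm1.ids)


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999,
           seed=None) -> tuple[float, float]:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)
    over midranked distances; p is the one-sided permutation p-value of
    group labels (add-one rule; exact enumeration when n! <= `n_perm`).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)
    groups = np.asarray(list(groups))
    n = dm.shape[0]
    if len(groups) != n:
        raise ConfigurationError("group labels must match matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ConfigurationError("anosim requires >= 2 groups")
    if (counts < 2).any():
        raise ConfigurationError("anosim groups must have >= 2 members")
    iu = np.triu_indices(n, k=1)
    ranks = scipy.stats.rankdata(dm.data[iu])
    denom = n * (n - 1) / 4.0

    def stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(groups)
    rng = np.random.default_rng(seed)
    perms, n_drawn, exhaustive = _perm_iter(n, n_perm, rng)
    hits = 0
    for p in perms:
        if stat(groups[np.asarray(p)]) >= r_obs - 1e-12:
            hits += 1
    pval = hits / n_drawn if exhaustive else (hits + 1) / (n_drawn + 1)
    return float(r_obs), float(pval)


# ---------------------------------------------------------------------------
# BEST / BioEnv
# ---------------------------------------------------------------------------

def best_bioenv(dm: DistanceMatrix, metadata: pd.DataFrame, variables=None,
                max_subset: int | None = None,
                max_variables: int = 15) -> pd.DataFrame:
    """Exhaustive environmental-subset search (BEST / BioEnv).

    For every non-empty subset of `variables` (optionally capped at
    `max_subset` members), computes the Spearman correlation between the
    community distance upper triangle and the Euclidean distance of the
    z-scored subset.  Returns a frame with columns ``variables``
    (comma-joined), ``k`` (subset size) and ``rs``, sorted by decreasing
    rs — the layout of the published BEST table.
    """
    variables = list(variables) if variables is not None else [
        v for v in ENV_VARIABLES if v in metadata.columns]
    if len(variables) > max_variables:
        raise ConfigurationError(
            f"{len(variables)} variables would require "
            f"2^{len(variables)}-1 subsets; cap the list at "
            f"{max_variables} or raise max_variables")
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)
    meta = metadata.loc[list(dm.ids)]
    comm = scipy.stats.rankdata(_upper(dm))
    X = meta[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    usable = [i for i, s in enumerate(sd) if s > 0]
    skipped = [variables[i] for i in range(len(variables)) if i not in usable]
    if skipped:
        logger.warning("best_bioenv: skipping constant variables %s", skipped)
    Z = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    names = [variables[i] for i in usable]
    n = Z.shape[0]
    iu = np.triu_indices(n, k=1)
    # per-variable squared coordinate differences; subset distances are
    # sqrt of sums of these, which is monotone so ranks need the sqrt
    sq_diffs = [(Z[:, j][:, None] - Z[:, j][None, :])[iu] ** 2
                for j in range(len(names))]
    rows = []
    kmax = max_subset or len(names)
    for k in range(1, kmax + 1):
        for subset in itertools.combinations(range(len(names)), k):
            d = np.sqrt(sum(sq_diffs[j] for j in subset))
            rs = _pearson(comm, scipy.stats.rankdata(d))
            rows.append({
                "variables": ", ".join(names[j] for j in subset),
                "k": k,
                "rs": rs,
            })
    out = pd.DataFrame(rows).sort_values("rs", ascending=False,
                                         kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-variable Mantel report
# ---------------------------------------------------------------------------

def env_mantel_report(dm_unweighted: DistanceMatrix,
                      dm_weighted: DistanceMatrix | None,
                      metadata: pd.DataFrame, variables=None,
                      n_perm: int = 9999, seed=None
                      ) -> tuple[pd.DataFrame, float | None]:
    """Mantel r/p/q for each environmental variable against UniFrac.

    Returns ``(report, between_matrix_r)`` where the report has one row per
    variable x matrix with BH q-values computed within each matrix family,
    and `between_matrix_r` is the Mantel correlation between the weighted
    and unweighted matrices themselves (None if only one matrix is given).
    """
    variables = list(variables) if variables is not None else [
        v for v in ENV_VARIABLES if v in metadata.columns]
    matrices = {"unweighted": dm_unweighted}
    if dm_weighted is not None:
        matrices["weighted"] = dm_weighted
    rng = np.random.default_rng(seed)
    rows = []
    for name, dm in matrices.items():
        meta = metadata.loc[list(dm.ids)]
        for var in variables:
            try:
                ed = env_distance(meta, [var])
            except ConstantInputError:
                logger.warning("env_mantel_report: %s is constant; skipped",
                               var)
                continue
            r, p = mantel(dm, ed, n_perm=n_perm,
                          seed=int(rng.integers(2 ** 31)))
            rows.append({"matrix": name, "variable": var, "r": r, "p": p,
                         "n": dm.shape[0]})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = np.nan
        for name in matrices:
            mask = report["matrix"] == name
            report.loc[mask, "q"] = bh_fdr(report.loc[mask, "p"].to_numpy())
    between = None
    if dm_weighted is not None:
        between, _ = mantel(dm_unweighted, dm_weighted, n_perm=99,
                            seed=int(rng.integers(2 ** 31)))
    return report, between
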