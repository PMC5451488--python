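"""Within-sample diversity and shared rank-correlation / FDR utilities.

Faith's phylogenetic diversity (PD) is the sum of branch lengths on the
minimal subtree connecting a sample's observed OTUs to the root (the rooted
variant, so a single observed leaf contributes its full root path).  Shannon
entropy is reported in bits (base 2) by default; Simpson is the
1 - sum(p_i^2) form, bounded in [0, 1].

The Spearman helper uses midranks for ties and an exhaustive permutation
p-value for small n (<= 10), falling back to the t approximation otherwise.
Multiple testing within a family is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson

from .errors import ConfigurationError, ConstantInputError, DatasetError
from .io import ENV_VARIABLES, OtuTable

logger = logging.getLogger(__name__)

#: Depth used when rarefying for between-sample (UniFrac) comparisons.
DEFAULT_BETA_RAREFACTION_DEPTH = 17212


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` reads are dropped with a warning.
    Subsampling uses the multivariate hypergeometric distribution, i.e. an
    exact draw of `depth` reads from the sample's read pool.
    """
    if depth <= 0:
        raise ConfigurationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d",
                       len(dropped), depth)
    rows = {}
    for sample in keep:
        counts = table.counts.loc[sample].to_numpy()
        if counts.sum() == depth:
            rows[sample] = counts
        else:
            rows[sample] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=table.otu_ids)
    return OtuTable(out.astype(np.int64))


# ---------------------------------------------------------------------------
# per-sample metrics
# ---------------------------------------------------------------------------

def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of a count vector (default bits)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise DatasetError("shannon undefined for an all-zero count vector")
    return float(_skbio_shannon(counts, base=base))


def simpson(counts) -> float:
    """Simpson diversity 1 - sum(p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise DatasetError("simpson undefined for an all-zero count vector")
    return float(_skbio_simpson(counts))


def faith_pd(presence, tree) -> float:
    """Faith's PD of a set of observed leaves, including the root path."""
    ids = sorted(set(presence))
    if not ids:
        return 0.0
    tips = {tip.name for tip in tree.tips()}
    unknown = [i for i in ids if i not in tips]
    if unknown:
        raise DatasetError(f"OTUs not found as tree leaves: {unknown[:5]}")
    return float(_skbio_faith_pd(np.ones(len(ids)), taxa=ids, tree=tree))


def alpha_diversity_table(table: OtuTable, tree=None, base: float = 2.0,
                          rarefy_depth: int | None = None,
                          seed=None) -> pd.DataFrame:
    """Per-sample observed OTUs, PD (if a tree is given), Shannon, Simpson.

    Metrics default to the full (unrarefied) counts; pass `rarefy_depth`
    to compute them on a single rarefied draw instead.
    """
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed=seed)
    records = {}
    for sample in table.sample_ids:
        counts = table.counts.loc[sample]
        present = list(counts.index[counts > 0])
        rec = {
            "observed_otus": float(len(present)),
            "shannon": shannon(counts.to_numpy(), base=base),
            "simpson": simpson(counts.to_numpy()),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(present, tree)
        records[sample] = rec
    return pd.DataFrame.from_dict(records, orient="index")


# ---------------------------------------------------------------------------
# rank correlation + FDR
# ---------------------------------------------------------------------------

def _rankdata(x):
    return scipy.stats.rankdata(x, method="average")


def spearman(x, y, exact: str | bool = "auto",
             max_exact_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Returns ``(rs, p)``.  The p-value is two-sided: an exhaustive
    permutation p for small samples (n <= `max_exact_n`) and the usual t
    approximation otherwise.  Constant inputs raise
    :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("spearman expects two equal-length vectors")
    n = len(x)
    if n < 3:
        raise ConfigurationError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for constant vector")
    rx, ry = _rankdata(x), _rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    use_exact = exact is True or (exact == "auto" and n <= max_exact_n)
    if use_exact:
        p = _exact_spearman_p(rx, ry, rs)
    else:
        p = _t_approx_p(rs, n)
    return rs, float(p)


def _t_approx_p(rs: float, n: int) -> float:
    if abs(rs) >= 1.0:
        return 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    return 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)


def _exact_spearman_p(rx, ry, rs_obs: float, chunk: int = 200_000) -> float:
    """Two-sided exhaustive permutation p over all orderings of one vector.

    Permutations are streamed in chunks so that n = 10 (3.6M orderings)
    stays within a modest memory footprint.
    """
    n = len(rx)
    rx_c = rx - rx.mean()
    # the permuted vector is a fixed multiset: its centering and norm are
    # permutation-invariant
    ry_c_norm = math.sqrt(((ry - ry.mean()) ** 2).sum())
    denom = math.sqrt((rx_c ** 2).sum()) * ry_c_norm
    n_hits = 0
    n_total = 0
    it = itertools.permutations(ry - ry.mean())
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        rs_null = (block @ rx_c) / denom
        n_hits += int(np.sum(np.abs(rs_null) >= abs(rs_obs) - 1e-12))
        n_total += len(block)
    return n_hits / n_total


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# diversity-environment report
# ---------------------------------------------------------------------------

def welch_ttest(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("t-test requires >= 2 samples per group")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def alpha_env_report(alpha: pd.DataFrame, metadata: pd.DataFrame,
                     variables=None) -> tuple[pd.DataFrame, dict]:
    """Correlate every alpha metric with every environmental variable.

    Returns ``(correlations, richness_ttest)``.  The correlation frame has
    one row per metric x variable with columns ``rs, p, q, n``; q-values are
    BH-adjusted across the whole family.  The t-test compares richness
    (observed OTUs) between vegetated and unvegetated samples.
    """
    if len(alpha) < 3:
        raise ConfigurationError("alpha_env_report requires >= 3 samples")
    variables = list(variables) if variables is not None else [
        v for v in ENV_VARIABLES if v in metadata.columns]
    meta = metadata.loc[alpha.index]
    rows = []
    for metric in alpha.columns:
        for var in variables:
            x = alpha[metric].to_numpy(float)
            y = meta[var].to_numpy(float)
            try:
                # family-level survey: asymptotic p keeps the report
                # consistent across sample sizes (and fast)
                rs, p = spearman(x, y, exact=False)
            except ConstantInputError:
                logger.warning("skipping constant pair %s ~ %s", metric, var)
                continue
            rows.append({"metric": metric, "variable": var, "rs": rs,
                         "p": p, "n": len(x)})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = bh_fdr(report["p"].to_numpy())
    richness = alpha["observed_otus"] if "observed_otus" in alpha.columns \
        else alpha.iloc[:, 0]
    vegetated = meta["vegetation_cover"].to_numpy(float) > 0
    ttest: dict = {"n_vegetated": int(vegetated.sum()),
                   "n_unvegetated": int((~vegetated).sum())}
    t, p = welch_ttest(richness[vegetated], richness[~vegetated])
    ttest.update({"t": t, "p": p})
    return report, ttest


# ---------------------------------------------------------------------------
# simple printed-statistic helpers
# ---------------------------------------------------------------------------

def fold_reduction(high: float, low: float) -> float:
    """Fold change high/low (e.g. PD at the richest vs the poorest site)."""
    if low <= 0:
        raise ConfigurationError("fold reduction needs a positive reference")
    return high / low


def percent_decrease(high: float, low: float) -> float:
    """Percent decrease from `high` down to `low`, on the 0-100 scale."""
    if high <= 0:
        raise ConfigurationError("percent decrease needs a positive baseline")
    return 100.0 * (high - low) / high
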