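"""Co-occurrence network inference and aridity-class topology comparison.

The pipeline follows the co-occurrence workflow standard in soil-microbiome
studies: rare OTUs (< 0.01% of total reads by default) are removed; all-pairs
Spearman correlations of relative abundances are computed; network
deconvolution separates direct from transitive dependencies; a correlation
cutoff is chosen by random-matrix-theory (RMT) thresholding — the smallest
cutoff at which the nearest-neighbour eigenvalue spacing distribution (NNSD)
of the thresholded matrix leaves the Wigner-Dyson (GOE, correlated-noise)
regime and fits the Poisson (modular-signal) law; and edges are retained only
if they jointly pass the correlation cutoff, a Benjamini-Hochberg q-value
cutoff (default 0.01) and a positive deconvolved weight.

Topology is summarised per sample on induced subgraphs: node count (size),
mean degree, mean betweenness, edge count, average shortest-path length over
reachable pairs, and Freeman betweenness centralization (1 on a star, 0 on a
complete graph).  Class summaries report medians per aridity class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .alpha import bh_fdr, spearman
from .errors import ConfigurationError, ConstantInputError, DatasetError
from .io import OtuTable

logger = logging.getLogger(__name__)

#: fraction-of-total-reads cutoff below which an OTU is "rare"
DEFAULT_MIN_FRAC = 1e-4
#: FDR cutoff on edge q-values
DEFAULT_Q_CUTOFF = 0.01

STAT_COLUMNS = ["size", "degree", "betweenness", "edge_count",
                "avg_path_length", "betweenness_centralization"]


# ---------------------------------------------------------------------------
# table preparation and correlation
# ---------------------------------------------------------------------------

def filter_rare(table: OtuTable, min_frac: float = DEFAULT_MIN_FRAC
                ) -> OtuTable:
    """Drop OTUs whose summed count is below `min_frac` of all reads."""
    if not (0 <= min_frac < 1):
        raise ConfigurationError("min_frac must lie in [0, 1)")
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    keep = totals[totals >= min_frac * grand].index
    return table.select_otus(list(keep))


def spearman_matrix(table: OtuTable) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs OTU x OTU Spearman correlations of relative abundances.

    Returns (R, P).  P-values use the two-sided t approximation (sample
    counts in network analyses are far above the exact-permutation regime).
    Constant OTU vectors yield r = 0, p = 1 with a logged note.
    """
    n_samples, n_otus = table.shape
    if n_samples < 4:
        raise ConfigurationError("spearman_matrix requires >= 4 samples")
    ra = table.relative_abundance().to_numpy()
    ranks = scipy.stats.rankdata(ra, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("spearman_matrix: %d constant OTU vectors set to r=0",
                    int(constant.sum()))
    Z = ranks - ranks.mean(axis=0)
    norm = np.sqrt((Z ** 2).sum(axis=0))
    norm[norm == 0] = 1.0
    Z = Z / norm
    R = Z.T @ Z
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    R[np.diag_indices(n_otus)[0][constant], constant] = 1.0
    # two-sided t approximation
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(R, -0.9999999999, 0.9999999999)
        t = rr * np.sqrt((n_samples - 2) / (1.0 - rr ** 2))
        P = 2.0 * scipy.stats.t.sf(np.abs(t), df=n_samples - 2)
    P[np.abs(R) >= 1.0 - 1e-12] = 0.0
    P[constant, :] = 1.0
    P[:, constant] = 1.0
    np.fill_diagonal(P, 0.0)
    return R, P


# ---------------------------------------------------------------------------
# network deconvolution
# ---------------------------------------------------------------------------

def deconvolve(R: np.ndarray, beta: float = 0.99,
               return_alpha: bool = False):
    """Network deconvolution of an observed-dependency matrix.

    The observed matrix G (R with zeroed diagonal, signed entries) is
    modelled as the series G_dir + G_dir^2 + ... of a direct-dependency
    matrix.  G is eigendecomposed, scaled by alpha so that the largest
    transformed eigenvalue magnitude equals `beta`, each eigenvalue mapped
    as lambda_d = lambda / (1 + lambda), and the matrix reassembled.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ConfigurationError("deconvolve expects a square matrix")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ConfigurationError("deconvolve expects a symmetric matrix")
    if not (0 < beta < 1):
        raise ConfigurationError("beta must lie in (0, 1)")
    G = R.copy()
    np.fill_diagonal(G, 0.0)
    if not G.any():
        out = np.zeros_like(G)
        return (out, 1.0) if return_alpha else out
    lam, V = np.linalg.eigh(G)
    lam_pos = lam.max()
    lam_neg = lam.min()
    # alpha such that max |alpha*lam / (1 + alpha*lam)| == beta; the map is
    # increasing in |lam| on both branches, so only the extremes matter
    candidates = []
    if lam_pos > 0:
        candidates.append(beta / ((1 - beta) * lam_pos))
    if lam_neg < 0:
        candidates.append(beta / ((1 + beta) * abs(lam_neg)))
    alpha = min(candidates)
    lam_d = alpha * lam / (1.0 + alpha * lam)
    D = (V * lam_d) @ V.T
    D = (D + D.T) / 2.0
    return (D, alpha) if return_alpha else D


# ---------------------------------------------------------------------------
# RMT thresholding
# ---------------------------------------------------------------------------

def _nnsd(eigvals: np.ndarray, n_knots: int = 15) -> np.ndarray:
    """Unfolded nearest-neighbour spacings (mean ~ 1).

    The empirical cumulative spectral density is smoothed with a cubic
    spline (least-squares fit with knots at eigenvalue quantiles) and the
    eigenvalues mapped through it (spectral unfolding), so spacings are
    measured against the local mean density.
    """
    ev = np.sort(eigvals)
    # collapse numerically identical eigenvalues to avoid zero-width steps
    ev = ev + np.arange(len(ev)) * 1e-12
    n = len(ev)
    cdf = (np.arange(1, n + 1) - 0.5) / n
    k = min(n_knots, max(1, n // 8))
    knots = np.quantile(ev, np.linspace(0, 1, k + 2)[1:-1])
    knots = np.unique(knots[(knots > ev[0]) & (knots < ev[-1])])
    spline = scipy.interpolate.LSQUnivariateSpline(ev, cdf, knots, k=3)
    unfolded = n * spline(ev)
    spacings = np.diff(np.sort(unfolded))
    spacings = spacings[spacings > 0]
    if spacings.size < 5 or spacings.mean() <= 0:
        raise DatasetError("degenerate spectrum: too few positive spacings")
    return spacings / spacings.mean()


def _gof_pvalues(spacings: np.ndarray, n_bins: int | None = None,
                 s_max: float = 3.0) -> tuple[float, float]:
    """Chi-square goodness-of-fit p-values of the NNSD.

    Returns ``(p_poisson, p_goe)`` against the Poisson law exp(-s) and the
    Wigner-Dyson (GOE) surmise (pi*s/2) exp(-pi*s^2/4).
    """
    if n_bins is None:
        n_bins = int(np.clip(len(spacings) // 8, 4, 12))
    edges = np.linspace(0.0, s_max, n_bins)
    edges = np.append(edges, np.inf)
    obs, _ = np.histogram(spacings, bins=edges)
    n = len(spacings)

    def chi2_p(cdf):
        probs = np.diff(cdf(edges))
        exp = probs * n
        # merge sparse bins to keep the chi-square approximation honest
        keep = exp >= 1.0
        o = np.append(obs[keep], obs[~keep].sum())
        e = np.append(exp[keep], exp[~keep].sum())
        if len(o) < 3 or e[-1] <= 0:
            o, e = o[:-1], e[:-1]
        e = e * o.sum() / e.sum()
        stat = ((o - e) ** 2 / e).sum()
        return float(scipy.stats.chi2.sf(stat, df=len(o) - 1))

    poisson_cdf = lambda s: np.where(np.isinf(s), 1.0, 1.0 - np.exp(-s))
    goe_cdf = lambda s: np.where(np.isinf(s), 1.0,
                                 1.0 - np.exp(-np.pi * s ** 2 / 4.0))
    return chi2_p(poisson_cdf), chi2_p(goe_cdf)


def rmt_threshold(R: np.ndarray, grid=None, poisson_alpha: float = 0.05,
                  goe_alpha: float = 0.05, min_spectrum: int = 20
                  ) -> tuple[float, pd.DataFrame]:
    """Choose a correlation cutoff by the RMT Poisson/GOE transition.

    For each candidate cutoff t the matrix is hard-thresholded at |r| >= t,
    restricted to the OTUs that retain at least one edge, eigendecomposed
    and its unfolded NNSD tested against Poisson and GOE.  Keeping all
    non-isolated OTUs (rather than a single connected component) is what
    produces the Poisson signature for modular structure: the superposed
    spectra of independent modules have uncorrelated level spacings.  The
    smallest t whose NNSD fits Poisson (p > `poisson_alpha`) while GOE is
    rejected (p < `goe_alpha`) is returned; if no cutoff qualifies the
    maximum of the grid is returned with a warning.

    Returns ``(threshold, diagnostics)`` where the diagnostics frame lists
    per-candidate spectrum size and both p-values.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if n < 30:
        raise ConfigurationError(
            f"matrix of {n} OTUs is too small for a meaningful spectrum; "
            "supply a fixed threshold instead")
    if grid is None:
        grid = np.round(np.arange(0.50, 1.00, 0.01), 2)
    grid = np.asarray(sorted(grid), dtype=float)
    rows = []
    chosen = None
    for t in grid:
        mask = np.abs(R) >= t
        np.fill_diagonal(mask, False)
        keep = np.flatnonzero(mask.any(axis=0))
        if len(keep) < min_spectrum:
            rows.append({"threshold": t, "n_nodes": len(keep),
                         "p_poisson": np.nan, "p_goe": np.nan})
            continue
        sub = R[np.ix_(keep, keep)].copy()
        sub[np.abs(sub) < t] = 0.0
        np.fill_diagonal(sub, 1.0)
        eigvals = np.linalg.eigvalsh(sub)
        try:
            spacings = _nnsd(eigvals)
            p_poisson, p_goe = _gof_pvalues(spacings)
        except (DatasetError, ValueError):
            p_poisson, p_goe = np.nan, np.nan
        rows.append({"threshold": t, "n_nodes": len(keep),
                     "p_poisson": p_poisson, "p_goe": p_goe})
    diagnostics = pd.DataFrame(rows)
    # a candidate qualifies when Poisson fits while GOE is rejected; the
    # transition must be sustained, not a single-grid-point fluctuation:
    # the candidate and the majority of the next `persist` points qualify
    persist = 4
    ok = ((diagnostics["p_poisson"] > poisson_alpha)
          & (diagnostics["p_goe"] < goe_alpha)).to_numpy()
    for i, t in enumerate(grid):
        if not ok[i]:
            continue
        window = ok[i + 1:i + 1 + persist]
        if window.size == 0 or window.sum() >= np.ceil(0.75 * window.size):
            chosen = float(t)
            break
    if chosen is None:
        chosen = float(grid.max())
        logger.warning("rmt_threshold: no candidate reached the Poisson "
                       "regime; returning grid maximum %.2f", chosen)
    return chosen, diagnostics


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """Undirected co-occurrence network over OTUs.

    Edges carry ``rs`` (Spearman correlation), ``q`` (BH-adjusted p),
    ``deconvolved`` (direct-dependency weight) and ``sign``; nodes may carry
    ``mean_rh`` once :func:`node_environment` has run.
    """

    graph: nx.Graph
    threshold_used: float
    q_cutoff: float
    fraction_positive: float
    diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"otu_a": a, "otu_b": b, **attrs}
            for a, b, attrs in self.graph.edges(data=True)
        ]
        cols = ["otu_a", "otu_b", "rs", "q", "deconvolved", "sign"]
        return pd.DataFrame(rows, columns=cols)

    def node_table(self) -> pd.DataFrame:
        degree = dict(self.graph.degree())
        btw = nx.betweenness_centrality(self.graph, normalized=False)
        rows = []
        for node, attrs in self.graph.nodes(data=True):
            rows.append({"otu": node,
                         "mean_rh": attrs.get("mean_rh", np.nan),
                         "degree": degree[node],
                         "betweenness": btw[node]})
        return pd.DataFrame(rows, columns=["otu", "mean_rh", "degree",
                                           "betweenness"])


def build_network(R: np.ndarray, P: np.ndarray, D: np.ndarray,
                  otu_ids, threshold: float,
                  q_cutoff: float = DEFAULT_Q_CUTOFF,
                  diagnostics: pd.DataFrame | None = None
                  ) -> CooccurrenceNetwork:
    """Assemble the network from correlation, p-value and deconvolved
    matrices.

    An edge (i, j) is retained iff |r_ij| >= `threshold`, its BH q-value
    (computed over the upper-triangle p-value family) is <= `q_cutoff`, and
    its deconvolved weight is positive.  OTUs without any retained edge are
    excluded from the node set.
    """
    if not (0 < threshold <= 1):
        raise ConfigurationError("threshold must lie in (0, 1]")
    R, P, D = (np.asarray(m, dtype=float) for m in (R, P, D))
    n = R.shape[0]
    if not (R.shape == P.shape == D.shape == (n, n)):
        raise ConfigurationError("R, P, D must be conformable square")
    if len(otu_ids) != n:
        raise ConfigurationError("otu_ids length must match matrix size")
    iu = np.triu_indices(n, k=1)
    q = bh_fdr(P[iu])
    keep = (q <= q_cutoff) & (np.abs(R[iu]) >= threshold) & (D[iu] > 0)
    graph = nx.Graph()
    otu_ids = list(otu_ids)
    n_pos = 0
    for idx in np.flatnonzero(keep):
        i, j = iu[0][idx], iu[1][idx]
        r = float(R[i, j])
        sign = 1 if r > 0 else -1
        n_pos += sign > 0
        graph.add_edge(otu_ids[i], otu_ids[j], rs=r, q=float(q[idx]),
                       deconvolved=float(D[i, j]), sign=sign)
    frac_pos = n_pos / keep.sum() if keep.sum() else np.nan
    return CooccurrenceNetwork(graph=graph, threshold_used=float(threshold),
                               q_cutoff=float(q_cutoff),
                               fraction_positive=float(frac_pos)
                               if keep.sum() else np.nan,
                               diagnostics=diagnostics)


def network_pipeline(table: OtuTable, min_frac: float = DEFAULT_MIN_FRAC,
                     q_cutoff: float = DEFAULT_Q_CUTOFF,
                     threshold: float | None = None,
                     rmt_grid=None) -> CooccurrenceNetwork:
    """The full inference chain on one table: filter -> correlate ->
    deconvolve -> RMT-threshold -> prune."""
    filtered = filter_rare(table, min_frac)
    R, P = spearman_matrix(filtered)
    D = deconvolve(R)
    diagnostics = None
    if threshold is None:
        threshold, diagnostics = rmt_threshold(R, grid=rmt_grid)
    return build_network(R, P, D, filtered.otu_ids, threshold,
                         q_cutoff=q_cutoff, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# environment attributes and correlations
# ---------------------------------------------------------------------------

def node_environment(net: CooccurrenceNetwork, table: OtuTable,
                     metadata: pd.DataFrame,
                     variable: str = "AvgSoilRH") -> None:
    """Attach to each node the mean of `variable` over the samples where
    the OTU occurs (count > 0)."""
    rh = metadata.loc[table.sample_ids, variable].to_numpy(float)
    presence = table.presence()
    for node in net.graph.nodes:
        if node not in presence.columns:
            raise DatasetError(f"network node {node} absent from OTU table")
        mask = presence[node].to_numpy()
        net.graph.nodes[node]["mean_rh"] = (
            float(rh[mask].mean()) if mask.any() else np.nan)


def sample_level_stats(net: CooccurrenceNetwork,
                       table: OtuTable) -> pd.DataFrame:
    """Topology statistics of each sample's induced subgraph.

    For each sample, the subgraph of the network induced on the OTUs with
    count > 0 in that sample is measured: size (nodes), mean degree, mean
    betweenness (unnormalized), edge count, average shortest-path length
    over reachable pairs only, and Freeman betweenness centralization.
    """
    presence = table.presence()
    nodes = [n for n in net.graph.nodes if n in presence.columns]
    rows = {}
    for sample in table.sample_ids:
        present = set(presence.columns[presence.loc[sample]])
        sub = net.graph.subgraph([n for n in nodes if n in present])
        rows[sample] = graph_stats(sub)
        if sub.number_of_nodes() == 0:
            logger.warning("sample %s induces an empty subgraph", sample)
    return pd.DataFrame.from_dict(rows, orient="index")[STAT_COLUMNS]


def graph_stats(graph: nx.Graph) -> dict:
    """The six topology statistics of a single graph."""
    n = graph.number_of_nodes()
    if n == 0:
        return {c: 0.0 for c in STAT_COLUMNS}
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    btw = nx.betweenness_centrality(graph, normalized=False)
    btw_vals = np.array(list(btw.values()), dtype=float)
    stats = {
        "size": float(n),
        "degree": float(degrees.mean()),
        "betweenness": float(btw_vals.mean()),
        "edge_count": float(graph.number_of_edges()),
        "avg_path_length": _avg_path_length(graph),
        "betweenness_centralization": _betweenness_centralization(btw_vals),
    }
    return stats


def _avg_path_length(graph: nx.Graph) -> float:
    """Mean shortest-path length over reachable (unordered) pairs only."""
    total = 0.0
    n_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        for d in lengths.values():
            if d > 0:
                total += d
                n_pairs += 1
    return total / n_pairs if n_pairs else 0.0


def _betweenness_centralization(btw_vals: np.ndarray) -> float:
    """Freeman centralization of unnormalized betweenness.

    Normalized against the theoretical maximum attained by a star on the
    same number of nodes: sum of (b_max - b_i) over nodes divided by
    (n - 1)^2 (n - 2) / 2.
    """
    n = len(btw_vals)
    if n < 3:
        return 0.0
    denom = (n - 1) ** 2 * (n - 2) / 2.0
    return float((btw_vals.max() - btw_vals).sum() / denom)


def node_metric_env_correlation(net: CooccurrenceNetwork,
                                sample_stats: pd.DataFrame,
                                metadata: pd.DataFrame,
                                variable: str = "AvgSoilRH") -> pd.DataFrame:
    """The four topology-environment correlations.

    Node level: rs(node mean RH, degree) and rs(node mean RH, betweenness).
    Sample level: rs(sample RH, edge count) and rs(sample RH, size).
    Degenerate (constant) inputs are flagged with NaN rather than raised.
    """
    nodes = net.node_table()
    rh_samples = metadata.loc[sample_stats.index, variable].to_numpy(float)
    pairs = [
        ("degree", "node", nodes["mean_rh"].to_numpy(),
         nodes["degree"].to_numpy(float)),
        ("betweenness", "node", nodes["mean_rh"].to_numpy(),
         nodes["betweenness"].to_numpy(float)),
        ("edge_count", "sample", rh_samples,
         sample_stats["edge_count"].to_numpy(float)),
        ("size", "sample", rh_samples,
         sample_stats["size"].to_numpy(float)),
    ]
    rows = []
    for metric, level, x, y in pairs:
        ok = np.isfinite(x) & np.isfinite(y)
        try:
            rs, p = spearman(x[ok], y[ok], exact=False)
        except (ConstantInputError, ConfigurationError) as exc:
            logger.warning("correlation %s undefined: %s", metric, exc)
            rs, p = np.nan, np.nan
        rows.append({"metric": metric, "level": level, "rs": rs, "p": p,
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aridity-class summaries and subnetworks
# ---------------------------------------------------------------------------

def class_summary(sample_stats: pd.DataFrame,
                  classes: pd.Series) -> pd.DataFrame:
    """Median of each topology statistic per aridity class.

    Medians use the standard midpoint convention.  Classes with no samples
    are omitted with a warning.
    """
    classes = classes.loc[sample_stats.index]
    rows = {}
    for cls in ["arid", "margin", "hyperarid"]:
        members = sample_stats[classes == cls]
        if members.empty:
            logger.warning("class_summary: no samples in class %s", cls)
            continue
        rows[cls] = members.median()
    return pd.DataFrame.from_dict(rows, orient="index")[STAT_COLUMNS]


def class_subnetwork(table: OtuTable, metadata: pd.DataFrame,
                     aridity_class: str,
                     min_frac: float = DEFAULT_MIN_FRAC,
                     q_cutoff: float = DEFAULT_Q_CUTOFF,
                     threshold: float | None = None,
                     rmt_grid=None) -> CooccurrenceNetwork:
    """Re-run the full inference chain on one aridity class's samples,
    recording that class's own RMT threshold."""
    samples = metadata.index[metadata["aridity_class"] == aridity_class]
    samples = [s for s in samples if s in set(table.sample_ids)]
    if len(samples) < 4:
        raise ConfigurationError(
            f"class {aridity_class} has {len(samples)} samples; >= 4 needed")
    sub = table.select_samples(samples).drop_empty_otus()
    return network_pipeline(sub, min_frac=min_frac, q_cutoff=q_cutoff,
                            threshold=threshold, rmt_grid=rmt_grid)
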