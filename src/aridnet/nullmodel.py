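"""Richness-matched resampling null for network connectivity.

Tests whether the loss of connectivity in hyperarid communities is an
artifact of their lower richness: arid and margin samples are rarefied to a
few hundred reads (default 300) so their observed richness drops to the
hyperarid level, the co-occurrence network is rebuilt on each rarefied
draw, per-sample topology statistics are averaged across draws, and class
medians are compared with the untouched hyperarid row.  If the rarefied
arid/margin networks still out-connect the hyperarid one, the connectivity
gradient is not a pure richness effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha import rarefy
from .errors import ConfigurationError
from .io import OtuTable
from .network import (DEFAULT_MIN_FRAC, DEFAULT_Q_CUTOFF, STAT_COLUMNS,
                      build_network, deconvolve, filter_rare,
                      sample_level_stats, spearman_matrix)

logger = logging.getLogger(__name__)

DEFAULT_NULL_DEPTH = 300
DEFAULT_N_REPS = 500


def rarefy_to_reads(table: OtuTable, depth: int = DEFAULT_NULL_DEPTH,
                    seed=None) -> OtuTable:
    """Rarefy every sample to `depth` reads (drop samples below it)."""
    return rarefy(table, depth, seed=seed)


@dataclass
class NullResult:
    """Outcome of the richness-matched resampling null."""

    n_reps: int
    depth: int
    #: per-sample topology statistics averaged across replicates
    per_sample_mean: pd.DataFrame
    #: median of replicate-averaged per-sample statistics, per class
    class_medians: pd.DataFrame
    #: the untouched hyperarid row from the original network
    hyperarid_reference: pd.Series
    #: median observed richness of the rarefied samples, per class
    modified_richness: pd.Series
    #: median observed richness of the original hyperarid samples
    hyperarid_richness: float
    per_rep_stats: list = field(default_factory=list, repr=False)


def run_null(table: OtuTable, metadata: pd.DataFrame,
             n_reps: int = DEFAULT_N_REPS,
             depth: int = DEFAULT_NULL_DEPTH,
             thresholds: dict[str, float] | None = None,
             min_frac: float = DEFAULT_MIN_FRAC,
             q_cutoff: float = DEFAULT_Q_CUTOFF,
             hyperarid_stats: pd.DataFrame | None = None,
             seed=None, keep_rep_traces: bool = False) -> NullResult:
    """Run the richness-matched null for the arid and margin classes.

    Per replicate: the arid+margin samples are rarefied to `depth` reads,
    rare OTUs are re-filtered with the same relative-abundance rule, a
    network is rebuilt per class (reusing the per-class correlation
    `thresholds`; pass the parent networks' values), and per-sample
    topology statistics are computed.  Statistics are then averaged
    across replicates per sample and the class medians of those averages
    are reported next to the original hyperarid row.

    `hyperarid_stats` must hold per-sample statistics of the original
    (unmodified) hyperarid samples, e.g. from
    :func:`aridnet.network.sample_level_stats`; hyperarid samples are
    never resampled.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    classes = metadata.loc[table.sample_ids, "aridity_class"]
    target = {"arid", "margin"}
    for cls in target:
        if (classes == cls).sum() == 0:
            raise ConfigurationError(f"class {cls} has no samples")
    thresholds = thresholds or {}
    rng = np.random.default_rng(seed)

    acc: dict[str, pd.DataFrame] = {}
    traces = []
    for rep in range(n_reps):
        rep_rows = {}
        for cls in sorted(target):
            members = list(classes.index[classes == cls])
            sub = table.select_samples(members)
            rare = rarefy_to_reads(sub, depth,
                                   seed=int(rng.integers(2 ** 31)))
            if rare.shape[0] == 0:
                raise ConfigurationError(
                    f"class {cls} lost all samples at depth {depth}")
            filt = filter_rare(rare.drop_empty_otus(), min_frac)
            thr = thresholds.get(cls, 0.8)
            try:
                R, P = spearman_matrix(filt)
                D = deconvolve(R)
                net = build_network(R, P, D, filt.otu_ids, thr,
                                    q_cutoff=q_cutoff)
                stats = sample_level_stats(net, filt)
            except ConfigurationError:
                stats = pd.DataFrame(0.0, index=filt.sample_ids,
                                     columns=STAT_COLUMNS)
            stats["richness"] = filt.richness().astype(float)
            rep_rows[cls] = stats
        rep_stats = pd.concat(rep_rows.values())
        traces.append(rep_stats if keep_rep_traces else None)
        for sample, row in rep_stats.iterrows():
            if sample not in acc:
                acc[sample] = row.to_frame().T
            else:
                acc[sample] = pd.concat([acc[sample], row.to_frame().T])

    per_sample_mean = pd.DataFrame(
        {sample: frames.mean() for sample, frames in acc.items()}).T
    cls_of = classes.loc[per_sample_mean.index]
    class_medians = per_sample_mean.groupby(cls_of).median()
    modified_richness = per_sample_mean["richness"].groupby(cls_of).median()
    class_medians = class_medians[STAT_COLUMNS]

    if hyperarid_stats is not None and len(hyperarid_stats):
        hyper_ref = hyperarid_stats[STAT_COLUMNS].median()
    else:
        hyper_ref = pd.Series(np.nan, index=STAT_COLUMNS)
    hyper_samples = classes.index[classes == "hyperarid"]
    hyper_rich = float(table.select_samples(list(hyper_samples))
                       .richness().median()) if len(hyper_samples) else np.nan

    return NullResult(
        n_reps=n_reps, depth=depth,
        per_sample_mean=per_sample_mean,
        class_medians=class_medians,
        hyperarid_reference=hyper_ref,
        modified_richness=modified_richness,
        hyperarid_richness=hyper_rich,
        per_rep_stats=[t for t in traces if t is not None],
    )


def richness_check(null_result: NullResult,
                   tolerance: float = 0.2) -> pd.DataFrame:
    """Compare reduced arid/margin richness with the hyperarid reference.

    Flags a class as ``matched`` when its median rarefied richness lies
    within `tolerance` (relative) of the original hyperarid median — the
    sanity check that the resampling really equalized richness.
    """
    ref = null_result.hyperarid_richness
    rows = []
    for cls, value in null_result.modified_richness.items():
        ratio = value / ref if ref else np.nan
        rows.append({
            "class": cls,
            "modified_richness": value,
            "hyperarid_richness": ref,
            "ratio": ratio,
            "matched": bool(abs(ratio - 1.0) <= tolerance)
            if np.isfinite(ratio) else False,
        })
    return pd.DataFrame(rows)
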