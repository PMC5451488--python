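"""Taxon-level abundance gradients along the aridity axis.

Counts are collapsed to a taxonomic rank, converted to per-sample relative
abundances (RA), and correlated (Spearman) with an environmental variable
(soil relative humidity by default), with BH-FDR control within the rank
family.  Strongly responding phyla (|rs| > 0.6, q < 0.02 by default) feed
a row-normalized heat-map matrix; a configurable list of nitrogen-cycling
genera (N2 fixers and nitrifiers) gets a dedicated detection/correlation
report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .alpha import bh_fdr, spearman
from .errors import ConfigurationError, ConstantInputError
from .io import OtuTable, TAXONOMY_RANKS

logger = logging.getLogger(__name__)

#: genera commonly associated with N2 fixation or nitrification
DEFAULT_GUILD_GENERA = [
    "Bradyrhizobium", "Mesorhizobium", "Nitrososphaera", "Nitrospira",
    "Frankia", "Sinorhizobium", "Rhizobium", "Azospirillum",
    "Nitrobacter", "Nitrosomonas", "Nitrosospira",
]

UNASSIGNED = "Unassigned"


def collapse_taxonomy(table: OtuTable, taxonomy: pd.DataFrame,
                      rank: str) -> pd.DataFrame:
    """Sum counts by `rank` label and convert to per-sample fractions.

    OTUs missing from the taxonomy (or with an empty label) are pooled
    into ``Unassigned``, so fractions sum to exactly 1 per sample.
    """
    if rank not in TAXONOMY_RANKS:
        raise ConfigurationError(
            f"unknown rank {rank!r}; expected one of {TAXONOMY_RANKS}")
    labels = []
    for otu in table.otu_ids:
        if otu in taxonomy.index:
            label = str(taxonomy.loc[otu, rank]).strip()
            labels.append(label if label and label != "nan" else UNASSIGNED)
        else:
            labels.append(UNASSIGNED)
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank)).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ConfigurationError("cannot collapse: sample with zero total")
    return grouped.div(totals, axis=0)


def taxon_env_correlation(collapsed: pd.DataFrame, metadata: pd.DataFrame,
                          variable: str = "AvgSoilRH",
                          rs_cut: float = 0.6,
                          q_cut: float = 0.02) -> pd.DataFrame:
    """Spearman correlation of each taxon's RA with `variable`.

    Returns one row per taxon with ``rs, p, q, detected_sites, flagged``;
    q-values are BH-adjusted across the rank family and taxa passing
    |rs| > `rs_cut` and q < `q_cut` are flagged.  Taxa absent everywhere
    (or with constant RA) are excluded with a note.
    """
    if len(collapsed) < 3:
        raise ConfigurationError("need >= 3 samples")
    env = metadata.loc[collapsed.index, variable].to_numpy(float)
    rows = []
    for taxon in collapsed.columns:
        ra = collapsed[taxon].to_numpy(float)
        if not ra.any():
            logger.info("taxon %s absent everywhere; excluded", taxon)
            continue
        try:
            rs, p = spearman(ra, env, exact=False)
        except ConstantInputError:
            logger.info("taxon %s has constant RA; excluded", taxon)
            continue
        detected = int((ra > 0).sum())
        rows.append({"taxon": taxon, "rs": rs, "p": p,
                     "detected_sites": detected,
                     "max_ra": float(ra.max()),
                     "min_ra": float(ra.min())})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = bh_fdr(report["p"].to_numpy())
        report["flagged"] = (report["rs"].abs() > rs_cut) & \
            (report["q"] < q_cut)
    return report


def heatmap_matrix(gradients: pd.DataFrame, collapsed: pd.DataFrame,
                   metadata: pd.DataFrame,
                   min_site_ra: float = 0.001,
                   variable: str = "AvgSoilRH"
                   ) -> pd.DataFrame:
    """Row-normalized RA matrix of the flagged taxa.

    Rows are the flagged taxa whose maximum site RA exceeds `min_site_ra`,
    ordered by decreasing rs; columns are samples ordered by `variable`;
    each row is divided by its maximum so the row maximum is exactly 1.
    """
    if "flagged" not in gradients.columns or not len(gradients):
        logger.warning("no gradient flags available; empty heat map")
        return pd.DataFrame()
    keep = gradients[(gradients["flagged"])
                     & (gradients["max_ra"] > min_site_ra)]
    keep = keep.sort_values("rs", ascending=False)
    if keep.empty:
        logger.warning("no taxon passes the heat-map filters")
        return pd.DataFrame()
    order = metadata.loc[collapsed.index, variable].sort_values().index
    mat = collapsed.loc[order, keep["taxon"]].T
    return mat.div(mat.max(axis=1), axis=0)


def nitrogen_guild_report(table: OtuTable, taxonomy: pd.DataFrame,
                          metadata: pd.DataFrame,
                          guild_genera=None,
                          variable: str = "AvgSoilRH") -> pd.DataFrame:
    """Detection and RH response of nitrogen-cycling guild genera.

    For each genus: number of samples where it was detected, RA range
    (formatted as e.g. ``0% to 1.2% RA``), and its Spearman correlation
    with `variable` (with BH q across the guild family).  Genera never
    detected are reported as ``not detected``.
    """
    guild_genera = list(guild_genera) if guild_genera is not None \
        else list(DEFAULT_GUILD_GENERA)
    if not guild_genera:
        raise ConfigurationError("guild list is empty")
    collapsed = collapse_taxonomy(table, taxonomy, "genus")
    env = metadata.loc[collapsed.index, variable].to_numpy(float)
    rows = []
    pvals, pidx = [], []
    for i, genus in enumerate(guild_genera):
        candidates = [c for c in collapsed.columns
                      if c == genus or c.endswith(genus)]
        if not candidates:
            rows.append({"genus": genus, "detected_sites": 0,
                         "ra_range": "not detected",
                         "rs": np.nan, "p": np.nan})
            continue
        ra = collapsed[candidates].sum(axis=1).to_numpy(float)
        detected = int((ra > 0).sum())
        if detected == 0:
            rows.append({"genus": genus, "detected_sites": 0,
                         "ra_range": "not detected",
                         "rs": np.nan, "p": np.nan})
            continue
        ra_range = format_ra_range(ra.min(), ra.max())
        try:
            rs, p = spearman(ra, env, exact=False)
        except ConstantInputError:
            rs, p = np.nan, np.nan
        rows.append({"genus": genus, "detected_sites": detected,
                     "ra_range": ra_range, "rs": rs, "p": p})
        if np.isfinite(p):
            pvals.append(p)
            pidx.append(i)
    report = pd.DataFrame(rows)
    report["q"] = np.nan
    if pvals:
        report.loc[pidx, "q"] = bh_fdr(np.asarray(pvals))
    return report


def format_ra_range(lo: float, hi: float) -> str:
    """Format a relative-abundance range as e.g. ``0% to 1.2% RA``."""

    def fmt(x):
        pct = 100.0 * x
        if pct == 0:
            return "0%"
        return f"{pct:.2g}%"

    return f"{fmt(lo)} to {fmt(hi)} RA"
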