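"""Reading, writing and validation of the standard dataset formats.

A dataset comprises four files:

* an OTU count table (TSV, OTUs as rows, first column ``#OTU ID``),
* per-sample environmental metadata (TSV, one row per soil pit),
* a rooted phylogenetic tree over the OTU ids (newick with branch lengths),
* an OTU taxonomy table (TSV, semicolon-delimited greengenes-style lineages).

In memory the count table is held samples x OTUs; on disk the amplicon
convention of OTUs-as-rows is used.  Counts are always integers; relative
abundances are derived downstream, never stored.

Samples are classified into three aridity classes following the field rules
for the Atacama transects: vegetated sites are *arid*; unvegetated sites
with shallow salt accumulation (nitrate > 20 or sulfate > 500 umol/g dry
soil in the 10-20 cm increment) are *hyperarid* unless a hydrologic (salar)
override applies; everything else is *margin*.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ConfigurationError, DatasetError

logger = logging.getLogger(__name__)

#: Metadata columns expected on every per-sample record (Table-S1-style).
METADATA_COLUMNS = [
    "site_id",
    "elevation",
    "pH",
    "EC",
    "SOC",
    "AvgSoilRH",
    "HighSoilRH",
    "LowSoilRH",
    "PercSoilRH100",
    "AvgSoilT",
    "HighSoilT",
    "LowSoilT",
    "vegetation_cover",
    "shallow_nitrate",
    "shallow_sulfate",
    "salar_override",
]

#: Continuous environmental variables used in driver analyses.
ENV_VARIABLES = [
    "elevation",
    "pH",
    "EC",
    "SOC",
    "AvgSoilRH",
    "HighSoilRH",
    "LowSoilRH",
    "PercSoilRH100",
    "AvgSoilT",
    "HighSoilT",
    "LowSoilT",
    "vegetation_cover",
]

TAXONOMY_RANKS = ["domain", "phylum", "class", "order", "family", "genus"]
RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__"]

ARIDITY_CLASSES = ["hyperarid", "margin", "arid"]

#: Minimum per-sample read total required to retain a sample.
DEFAULT_MIN_READS = 16660


class OtuTable:
    """Integer count matrix, samples x OTUs, with unique string ids.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = sample ids, columns = OTU ids.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise DatasetError("duplicate sample ids in OTU table")
        if counts.columns.has_duplicates:
            raise DatasetError("duplicate OTU ids in OTU table")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise DatasetError("OTU table contains non-integer counts")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise DatasetError("OTU table contains negative counts")
        counts = counts.astype(np.int64)
        counts.index.name = None
        counts.columns.name = None
        self.counts = counts

    # -- identifiers ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- derived views --------------------------------------------------
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def richness(self) -> pd.Series:
        """Observed OTUs per sample."""
        return (self.counts > 0).sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.sample_totals()
        if (totals == 0).any():
            raise DatasetError("cannot form relative abundances: empty sample")
        return self.counts.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    # -- subsetting ------------------------------------------------------
    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)])

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts[list(otu_ids)])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} samples x {m} OTUs)"


@dataclass
class Dataset:
    """A cross-referenced dataset ready for analysis."""

    table: OtuTable
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    tree: TreeNode
    warnings: list[str] = field(default_factory=list)

    def class_counts(self) -> pd.Series:
        return self.metadata["aridity_class"].value_counts()


# ---------------------------------------------------------------------------
# aridity classification
# ---------------------------------------------------------------------------

def classify_aridity(record, nitrate_cut: float = 20.0,
                     sulfate_cut: float = 500.0) -> str:
    """Assign one of ``hyperarid`` / ``margin`` / ``arid`` to a sample record.

    Rules, applied in order:

    1. any vegetation cover -> ``arid``;
    2. shallow nitrate > `nitrate_cut` or shallow sulfate > `sulfate_cut`
       (umol per g dry soil, 10-20 cm depth), without a salar override ->
       ``hyperarid`` (salt accumulation is the long-term hyperaridity
       indicator; salar-influenced sites are excluded because their sulfate
       is hydrologic, not climatic);
    3. otherwise ``margin``.

    `record` may be a mapping or a pandas Series with fields
    ``vegetation_cover``, ``shallow_nitrate``, ``shallow_sulfate`` and
    optionally ``salar_override``.
    """
    try:
        veg = float(record["vegetation_cover"])
        nitrate = float(record["shallow_nitrate"])
        sulfate = float(record["shallow_sulfate"])
    except (KeyError, TypeError, ValueError) as exc:
        raise DatasetError(f"missing or invalid classification field: {exc}")
    salar = bool(record["salar_override"]) if "salar_override" in record else False
    if veg > 0:
        return "arid"
    if (nitrate > nitrate_cut or sulfate > sulfate_cut) and not salar:
        return "hyperarid"
    return "margin"


def classify_metadata(metadata: pd.DataFrame, nitrate_cut: float = 20.0,
                      sulfate_cut: float = 500.0) -> pd.DataFrame:
    """Return a copy of `metadata` with an ``aridity_class`` column."""
    out = metadata.copy()
    out["aridity_class"] = [
        classify_aridity(row, nitrate_cut, sulfate_cut)
        for _, row in metadata.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table_lines(path) -> str:
    """Strip leading '# ' comment lines (but keep the '#OTU ID' header)."""
    text = Path(path).read_text()
    kept = [
        line for line in text.splitlines()
        if not (line.startswith("#") and not line.startswith("#OTU ID"))
    ]
    return "\n".join(kept)


def read_otu_table(path) -> OtuTable:
    """Read a TSV OTU table (OTUs as rows, first column ``#OTU ID``)."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"OTU table not found: {path}")
    df = pd.read_csv(_io.StringIO(_read_table_lines(path)), sep="\t",
                     index_col=0)
    try:
        return OtuTable(df.T)
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}")


def write_otu_table(table: OtuTable, path, header_comment: str | None = None):
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = table.counts.T.rename_axis("#OTU ID")
        out.to_csv(fh, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"metadata file not found: {path}")
    df = pd.read_csv(_io.StringIO(_read_table_lines(path)), sep="\t",
                     index_col=0)
    if df.index.has_duplicates:
        raise DatasetError(f"{path}: duplicate sample ids in metadata")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: metadata missing columns {missing}")
    df["salar_override"] = df["salar_override"].astype(bool)
    _validate_metadata_ranges(df, path)
    return df


def _validate_metadata_ranges(df: pd.DataFrame, path):
    for col in ("AvgSoilRH", "HighSoilRH", "LowSoilRH", "PercSoilRH100"):
        vals = df[col].to_numpy(float)
        if ((vals < 0) | (vals > 100)).any():
            raise DatasetError(f"{path}: {col} outside [0, 100]")
    if (df["LowSoilRH"] > df["AvgSoilRH"] + 1e-9).any() or \
            (df["AvgSoilRH"] > df["HighSoilRH"] + 1e-9).any():
        raise DatasetError(f"{path}: RH ordering Low <= Avg <= High violated")
    if (df["LowSoilT"] > df["AvgSoilT"] + 1e-9).any() or \
            (df["AvgSoilT"] > df["HighSoilT"] + 1e-9).any():
        raise DatasetError(f"{path}: T ordering Low <= Avg <= High violated")


def write_metadata(metadata: pd.DataFrame, path,
                   header_comment: str | None = None):
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = metadata.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    """Read OTU -> lineage TSV; lineages are ``k__X; p__Y; ...`` strings."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"taxonomy file not found: {path}")
    df = pd.read_csv(_io.StringIO(_read_table_lines(path)), sep="\t",
                     index_col=0, header=0)
    if df.index.has_duplicates:
        raise DatasetError(f"{path}: duplicate OTU ids in taxonomy")
    lineages = df.iloc[:, 0].astype(str)
    rows = {}
    for otu, lineage in lineages.items():
        fields = [f.strip() for f in lineage.split(";")]
        ranks = []
        for i, prefix in enumerate(RANK_PREFIXES):
            value = fields[i] if i < len(fields) else prefix
            if value.startswith(prefix):
                value = value[len(prefix):]
            ranks.append(value)
        rows[otu] = ranks
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=TAXONOMY_RANKS)


def write_taxonomy(taxonomy: pd.DataFrame, path,
                   header_comment: str | None = None):
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("#OTU ID\ttaxonomy\n")
        for otu, row in taxonomy.iterrows():
            lineage = "; ".join(
                prefix + str(row[rank])
                for prefix, rank in zip(RANK_PREFIXES, TAXONOMY_RANKS)
            )
            fh.write(f"{otu}\t{lineage}\n")


def read_tree(path) -> TreeNode:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"tree file not found: {path}")
    tree = TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        raise DatasetError(f"{path}: tree is unrooted (root has "
                           f"{len(tree.children)} children)")
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise DatasetError(f"{path}: duplicate leaf names in tree")
    return tree


def write_tree(tree: TreeNode, path):
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def load_dataset(otu_path, metadata_path, tree_path, taxonomy_path=None,
                 min_reads: int = DEFAULT_MIN_READS,
                 nitrate_cut: float = 20.0,
                 sulfate_cut: float = 500.0) -> Dataset:
    """Load, cross-reference and validate a dataset.

    Samples whose read total falls below `min_reads` are dropped with a
    warning, as are OTUs that are absent from the tree and samples missing
    from the metadata.  Every retained sample receives an aridity class.
    """
    if min_reads < 0:
        raise ConfigurationError("min_reads must be >= 0")
    table = read_otu_table(otu_path)
    metadata = read_metadata(metadata_path)
    tree = read_tree(tree_path)
    taxonomy = (read_taxonomy(taxonomy_path) if taxonomy_path is not None
                else pd.DataFrame(columns=TAXONOMY_RANKS))
    warnings: list[str] = []

    tip_names = {tip.name for tip in tree.tips()}
    missing_tree = [o for o in table.otu_ids if o not in tip_names]
    if missing_tree:
        warnings.append(f"dropped {len(missing_tree)} OTUs absent from tree")
        logger.warning(warnings[-1])
        keep = [o for o in table.otu_ids if o in tip_names]
        table = table.select_otus(keep)

    missing_meta = [s for s in table.sample_ids if s not in metadata.index]
    if missing_meta:
        warnings.append(
            f"dropped {len(missing_meta)} samples without metadata")
        logger.warning(warnings[-1])
        table = table.select_samples(
            [s for s in table.sample_ids if s in metadata.index])

    totals = table.sample_totals()
    low = totals[totals < min_reads]
    if len(low):
        warnings.append(
            f"dropped {len(low)} samples below read threshold {min_reads}: "
            + ", ".join(map(str, low.index)))
        logger.warning(warnings[-1])
        table = table.select_samples(list(totals[totals >= min_reads].index))

    metadata = metadata.loc[table.sample_ids]
    metadata = classify_metadata(metadata, nitrate_cut, sulfate_cut)
    if taxonomy_path is not None:
        extra = [o for o in taxonomy.index if o not in set(table.otu_ids)]
        taxonomy = taxonomy.drop(index=extra)
    return Dataset(table=table, metadata=metadata, taxonomy=taxonomy,
                   tree=tree, warnings=warnings)


def write_dataset(dataset: Dataset, out_dir,
                  header_comment: str | None = None) -> dict[str, Path]:
    """Write all dataset components to `out_dir`; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out_dir / "otu_table.tsv",
        "metadata": out_dir / "metadata.tsv",
        "tree": out_dir / "tree.nwk",
        "taxonomy": out_dir / "taxonomy.tsv",
    }
    write_otu_table(dataset.table, paths["otu_table"], header_comment)
    meta = dataset.metadata.drop(columns=["aridity_class"], errors="ignore")
    write_metadata(meta, paths["metadata"], header_comment)
    write_tree(dataset.tree, paths["tree"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"], header_comment)
    return paths
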