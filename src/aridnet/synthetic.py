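"""Synthetic aridity-gradient community generator.

Emulates the statistical structure the downstream analyses assume, so every
stage of the pipeline can be exercised and validated without the original
sequencing data:

* a monotone soil-relative-humidity (RH) gradient across sites, with
  environmental covariates tied to it (elevation rises along the gradient,
  temperature falls with elevation, vegetation appears only above an RH
  cutoff, shallow nitrate/sulfate accumulate only below an RH cutoff);
* OTU "niches" (RH optima) whose distribution is skewed toward the humid
  end, so observed richness declines with aridity;
* planted co-occurrence blocks: groups of OTUs sharing a niche and a
  per-sample latent log-normal factor, giving high positive within-block
  rank correlations; block niches concentrate at the humid end so network
  density tracks RH;
* signed phylum-level responses realized through niche placement (e.g. the
  Actinobacteria-like phylum concentrates at the dry end), yielding
  monotone phylum abundance gradients;
* integer counts drawn multinomially from the kernel-derived relative
  abundances at a log-normal sequencing depth.  Spearman-based downstream
  statistics are invariant to the compositional closure this imposes.

All outputs are pure functions of the design (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ConfigurationError
from .io import (Dataset, OtuTable, TAXONOMY_RANKS, classify_metadata)

# phylum pool: (name, domain, signed RH response, sampling weight)
PHYLA = [
    ("Actinobacteria", "Bacteria", -1, 0.30),
    ("Chloroflexi", "Bacteria", 0, 0.10),
    ("Gemmatimonadetes", "Bacteria", 0, 0.07),
    ("Firmicutes", "Bacteria", 0, 0.06),
    ("Acidobacteria", "Bacteria", +1, 0.12),
    ("Proteobacteria", "Bacteria", +1, 0.14),
    ("Planctomycetes", "Bacteria", +1, 0.08),
    ("Verrucomicrobia", "Bacteria", +1, 0.06),
    ("Nitrospirae", "Bacteria", +1, 0.03),
    ("Crenarchaeota", "Archaea", +1, 0.04),
]

# nitrogen-cycling guild genera planted into high-RH proteobacterial /
# nitrifier niches (the classic nitrifiers Nitrobacter, Nitrosomonas and
# Nitrosospira are deliberately never planted, emulating their absence
# from hyperarid-gradient surveys)
GUILD_PLACEMENTS = [
    ("Bradyrhizobium", "Proteobacteria", 2),
    ("Mesorhizobium", "Proteobacteria", 2),
    ("Rhizobium", "Proteobacteria", 1),
    ("Sinorhizobium", "Proteobacteria", 1),
    ("Azospirillum", "Proteobacteria", 1),
    ("Frankia", "Actinobacteria", 1),
    ("Nitrospira", "Nitrospirae", 2),
    ("Candidatus Nitrososphaera", "Crenarchaeota", 2),
]


@dataclass
class GradientDesign:
    """Parameters of a synthetic aridity-gradient experiment.

    The defaults describe a 13-site transect sampled with triplicate soil
    pits (39 samples, the scale of a real two-transect desert survey),
    spanning soil RH from 2% (hyperarid core) to 78% (vegetated arid
    slope), with 1500 OTUs of which 12 blocks of 24 are planted
    co-occurrence modules.
    """

    n_sites: int = 13
    pits_per_site: int = 3
    rh_range: tuple[float, float] = (2.0, 78.0)
    n_otus: int = 1500
    n_blocks: int = 12
    block_size_range: tuple[int, int] = (6, 30)
    block_rh_niches: tuple[float, ...] | None = None
    depth_lognormal_params: tuple[float, float] = (np.log(2.0e4), 0.1)
    niche_skew: tuple[float, float] = (3.5, 0.8)
    seed: int = 0
    # environmental noise (multiplies all within-site noise terms)
    env_noise_sd: float = 1.0
    # niche kernel widths, percent RH (flat-top window half-scale for
    # blocks, graded dry -> humid so dry modules have narrow, staggered
    # activity windows)
    block_kernel_width_range: tuple[float, float] = (8.0, 16.0)
    background_kernel_width: float = 16.0
    # dry-end specialists track RH tightly; humid generalists are broader
    background_width_range: tuple[float, float] = (16.0, 16.0)
    # log-scale variation
    block_factor_sd: float = 2.0       # amplitude of the block latent field
    block_noise_sd: float = 0.08       # member-specific residual
    background_noise_sd: float = 1.8   # background OTU residual
    abundance_scale_sd: float = 1.5    # across-OTU abundance heterogeneity
    block_scale_boost: float = 1.2     # log-scale mean boost of block OTUs
    # internal geometry of the planted modules, in units of member
    # spacing: each member's latent loading is a Gaussian bump over a
    # within-block "community axis", so members connect to roughly
    # `reach` neighbours on each side.  Dry-end modules are thin chains
    # (the weakly bridged islands of the hyperarid core); humid modules
    # are wide, densely connected webs
    block_reach_range: tuple[float, float] = (1.2, 12.0)
    # members are staggered along the RH axis around the block optimum so
    # that activity windows (and hence zero patterns) grade with position
    # on the community axis instead of being identical across the block
    block_niche_spread: float = 18.0
    veg_rh_cutoff: float = 40.0
    salt_rh_cutoff: float = 20.0

    def __post_init__(self):
        lo, hi = self.rh_range
        if not (0.0 < lo < hi < 100.0):
            raise ConfigurationError(
                "rh_range must satisfy 0 < low < high < 100")
        if self.n_sites < 3:
            raise ConfigurationError(
                "n_sites must be >= 3 so all aridity classes are populated")
        if self.pits_per_site < 1:
            raise ConfigurationError("pits_per_site must be >= 1")
        if self.n_otus < 2:
            raise ConfigurationError("n_otus must be >= 2")
        if self.n_blocks < 0 or min(self.block_size_range) < 2:
            raise ConfigurationError(
                "n_blocks must be >= 0 and block sizes >= 2")
        if self.n_blocks and self.block_sizes().sum() > self.n_otus:
            raise ConfigurationError(
                "planted blocks cannot cover more OTUs than n_otus")
        if self.block_rh_niches is not None:
            if len(self.block_rh_niches) != self.n_blocks:
                raise ConfigurationError(
                    "block_rh_niches must have one optimum per block")
            if any(not (lo <= v <= hi) for v in self.block_rh_niches):
                raise ConfigurationError(
                    "block_rh_niches must lie inside rh_range")
        mu, sd = self.depth_lognormal_params
        if sd < 0:
            raise ConfigurationError(
                "depth_lognormal_params sd must be >= 0")

    def block_niches(self) -> np.ndarray:
        """Per-block RH optima, spread over the whole gradient."""
        if self.block_rh_niches is not None:
            return np.asarray(self.block_rh_niches, dtype=float)
        lo, hi = self.rh_range
        span = hi - lo
        return np.linspace(lo + 0.08 * span, hi - 0.02 * span,
                           max(self.n_blocks, 1))

    def _block_z(self) -> np.ndarray:
        lo, hi = self.rh_range
        return np.clip((self.block_niches() - lo) / (hi - lo), 0.0, 1.0)

    def block_sizes(self) -> np.ndarray:
        """Per-block member counts, graded from the dry to the humid end:
        hyperarid modules are small, arid modules large (richer, more
        densely co-occurring humid communities)."""
        m_lo, m_hi = self.block_size_range
        z = self._block_z()
        return np.round(m_lo + (m_hi - m_lo) * z).astype(int)

    def block_reaches(self) -> np.ndarray:
        """Per-block connectivity reach (member-spacing units).

        A sigmoid in niche position: modules of the hyperarid core are
        thin chains, everything above the hyperarid-margin transition is
        a densely connected web.
        """
        r_lo, r_hi = self.block_reach_range
        z = self._block_z()
        return r_lo + (r_hi - r_lo) / (1.0 + np.exp(-(z - 0.25) / 0.07))

    def block_kernel_widths(self) -> np.ndarray:
        """Per-block flat-top window scale, percent RH."""
        w_lo, w_hi = self.block_kernel_width_range
        z = self._block_z()
        return w_lo + (w_hi - w_lo) * z


@dataclass
class GroundTruth:
    """The planted structure behind a synthetic dataset."""

    block_membership: dict[str, int | None]
    otu_rh_niche: dict[str, float]
    phylum_effect: dict[str, int]
    sample_gradient: dict[str, float]

    def block_of(self, otu: str):
        return self.block_membership.get(otu)

    def is_within_block_pair(self, otu_a: str, otu_b: str) -> bool:
        a = self.block_membership.get(otu_a)
        b = self.block_membership.get(otu_b)
        return a is not None and a == b

    def to_json(self, path):
        payload = {
            "block_membership": self.block_membership,
            "otu_rh_niche": self.otu_rh_niche,
            "phylum_effect": self.phylum_effect,
            "sample_gradient": self.sample_gradient,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(design: GradientDesign) -> pd.DataFrame:
    """Per-pit environmental metadata along the gradient.

    Site-mean AvgSoilRH is linear across sites; elevation rises along the
    transect while temperature falls with elevation; vegetation cover is
    positive only above `veg_rh_cutoff`; shallow nitrate and sulfate are
    high only below `salt_rh_cutoff`.  Deterministic given the design.
    """
    rng = np.random.default_rng([design.seed, 1])
    lo, hi = design.rh_range
    site_rh = np.linspace(lo, hi, design.n_sites)
    noise = design.env_noise_sd
    rows = {}
    for s in range(design.n_sites):
        elev_site = 900.0 + 350.0 * s
        for p in range(design.pits_per_site):
            sample_id = f"S{s:02d}P{p}"
            rh = float(np.clip(site_rh[s] + rng.normal(0, 1.2) * noise,
                               0.5, 99.5))
            elev = elev_site + rng.normal(0, 25.0) * noise
            avg_t = 30.0 - 0.005 * elev + rng.normal(0, 0.4) * noise
            veg = 0.0
            if site_rh[s] > design.veg_rh_cutoff:
                veg = max(0.5, (site_rh[s] - design.veg_rh_cutoff) * 0.9
                          + rng.normal(0, 1.0) * noise)
            salty = site_rh[s] < design.salt_rh_cutoff
            nitrate = (30.0 + rng.normal(0, 3.0) * noise) if salty \
                else max(0.0, 2.0 + rng.normal(0, 1.0) * noise)
            sulfate = (700.0 + rng.normal(0, 40.0) * noise) if salty \
                else max(0.0, 50.0 + rng.normal(0, 10.0) * noise)
            rows[sample_id] = {
                "site_id": f"SITE{s:02d}",
                "elevation": round(elev, 1),
                "pH": round(8.2 - 0.010 * rh + rng.normal(0, 0.1) * noise, 3),
                "EC": round(6.0 * np.exp(-rh / 15.0)
                            + max(0.0, rng.normal(0.2, 0.1) * noise), 4),
                "SOC": round(max(0.17, 0.3 + 0.16 * veg
                                 + rng.normal(0, 0.2) * noise), 3),
                "AvgSoilRH": round(rh, 6),
                "HighSoilRH": round(min(100.0, rh + 18.0), 6),
                "LowSoilRH": round(max(0.0, rh * 0.35), 3),
                "PercSoilRH100": round(float(np.clip(
                    (rh - 30.0) * 1.4 + rng.normal(0, 2.0) * noise,
                    0.0, 100.0)), 3),
                "AvgSoilT": round(avg_t, 3),
                "HighSoilT": round(avg_t + 12.0, 3),
                "LowSoilT": round(avg_t - 10.0, 3),
                "vegetation_cover": round(veg, 3),
                "shallow_nitrate": round(nitrate, 3),
                "shallow_sulfate": round(sulfate, 3),
                "salar_override": False,
            }
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample_id"
    return meta


# ---------------------------------------------------------------------------
# community structure (niches, blocks, taxonomy) — shared across outputs
# ---------------------------------------------------------------------------

def _community_structure(design: GradientDesign):
    """Deterministic niches, block membership and taxonomy for the design."""
    rng = np.random.default_rng([design.seed, 2])
    lo, hi = design.rh_range
    n = design.n_otus
    otu_ids = [f"OTU{i:05d}" for i in range(n)]

    niches = np.empty(n)
    block_of = np.full(n, -1, dtype=int)
    block_niches = design.block_niches()
    block_sizes = design.block_sizes() if design.n_blocks else []
    lo, hi = design.rh_range
    idx = 0
    for b in range(design.n_blocks):
        m = block_sizes[b]
        offsets = (np.linspace(0.0, 1.0, m) - 0.5) * design.block_niche_spread
        for k, i in enumerate(range(idx, idx + m)):
            block_of[i] = b
            niches[i] = float(np.clip(block_niches[b] + offsets[k], lo, hi))
        idx += m
    # background niches: a humid-skewed Beta pool, so richness declines
    # toward the hyperarid core
    n_bg = n - idx
    a_sk, b_sk = design.niche_skew
    niches[idx:] = lo + (hi - lo) * rng.beta(a_sk, b_sk, size=n_bg)

    # phylum conditional on niche position: positive-response phyla are
    # drawn preferentially at the humid end, negative at the dry end
    names = [p[0] for p in PHYLA]
    effects = {p[0]: p[2] for p in PHYLA}
    domains = {p[0]: p[1] for p in PHYLA}
    weights = np.array([p[3] for p in PHYLA])
    z = (niches - lo) / (hi - lo)
    phylum = []
    for i in range(n):
        tilt = np.array([
            1.0 if e == 0 else (0.15 + z[i] if e > 0 else 1.15 - z[i])
            for e in (effects[nm] for nm in names)])
        pr = weights * tilt
        phylum.append(names[rng.choice(len(names), p=pr / pr.sum())])
    phylum = np.array(phylum)

    taxonomy = pd.DataFrame(index=pd.Index(otu_ids, name="#OTU ID"),
                            columns=TAXONOMY_RANKS, dtype=object)
    taxonomy["domain"] = [domains[p] for p in phylum]
    taxonomy["phylum"] = phylum
    taxonomy["class"] = [f"{p}_c1" for p in phylum]
    taxonomy["order"] = [f"{p}_o1" for p in phylum]
    taxonomy["family"] = [f"{p}_f1" for p in phylum]
    taxonomy["genus"] = [f"g{i % 97:02d}" for i in range(n)]

    # plant guild genera on humid-adapted members of their host phyla
    for genus, host, n_wanted in GUILD_PLACEMENTS:
        candidates = [i for i in range(n)
                      if phylum[i] == host and z[i] > 0.55
                      and block_of[i] < 0]
        order = sorted(candidates, key=lambda i: -z[i])
        for i in order[:n_wanted]:
            taxonomy.iloc[i, TAXONOMY_RANKS.index("genus")] = genus

    membership = {otu_ids[i]: (int(block_of[i]) if block_of[i] >= 0
                               else None) for i in range(n)}
    truth_niche = {otu_ids[i]: float(niches[i]) for i in range(n)}
    return otu_ids, niches, block_of, taxonomy, membership, truth_niche, \
        effects


def simulate_taxonomy(design: GradientDesign) -> pd.DataFrame:
    """The OTU taxonomy table implied by the design (rank columns)."""
    return _community_structure(design)[3]


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(design: GradientDesign) -> TreeNode:
    """Rooted binary tree with positive branch lengths and phylum clades.

    Leaves are the design's OTU ids; OTUs of the same phylum always form a
    clade.  A rooted binary tree over n leaves has exactly n - 1 internal
    nodes.
    """
    if design.n_otus < 2:
        raise ConfigurationError("simulate_tree requires n_otus >= 2")
    rng = np.random.default_rng([design.seed, 3])
    otu_ids, _, _, taxonomy, _, _, _ = _community_structure(design)
    phylum = taxonomy["phylum"]

    def blen():
        return float(rng.exponential(0.05) + 0.01)

    def join_all(nodes: list[TreeNode]) -> TreeNode:
        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            a.length, b.length = blen(), blen()
            parent = TreeNode(children=[a, b])
            nodes = [nd for k, nd in enumerate(nodes)
                     if k not in (int(i), int(j))]
            nodes.append(parent)
        return nodes[0]

    clades = []
    for ph in phylum.unique():
        leaves = [TreeNode(name=o) for o in otu_ids if phylum[o] == ph]
        clades.append(join_all(leaves))
    root = join_all(clades)
    root.length = None
    return root


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def expected_relative_abundance(design: GradientDesign,
                                metadata: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected relative abundances (kernel + scale only)."""
    otu_ids, niches, block_of, _, _, _, _ = _community_structure(design)
    scales = _abundance_scales(design, block_of)
    rh = metadata["AvgSoilRH"].to_numpy(float)
    W = _kernel_weights(design, niches, block_of, rh) * scales
    W = W / W.sum(axis=1, keepdims=True)
    return pd.DataFrame(W, index=metadata.index, columns=otu_ids)


def _kernel_weights(design, niches, block_of, rh):
    """Niche response kernels.

    Background OTUs follow a Gaussian kernel of RH-to-niche distance.
    Planted blocks use a flat-top (quartic-exponent) kernel: nearly
    constant inside the activity window, dropping to effectively zero
    outside it, so a module is either "on" or "off" in a sample and its
    members' within-window abundance ranks are governed by the shared
    latent factor rather than by a graded environmental response.
    """
    d = rh[:, None] - niches[None, :]
    is_block = block_of >= 0
    lo, hi = design.rh_range
    z = (niches - lo) / (hi - lo)
    w_lo, w_hi = design.background_width_range
    widths = w_lo + (w_hi - w_lo) * np.clip(z, 0.0, 1.0)
    w = np.empty_like(d)
    w[:, ~is_block] = np.exp(
        -0.5 * (d[:, ~is_block] / widths[~is_block]) ** 2)
    if is_block.any():
        bw = design.block_kernel_widths()[block_of[is_block]]
        w[:, is_block] = np.exp(
            -0.5 * (d[:, is_block] / bw[None, :]) ** 4)
    return w


def _abundance_scales(design, block_of):
    rng = np.random.default_rng([design.seed, 4])
    scales = np.exp(rng.normal(0.0, design.abundance_scale_sd,
                               size=design.n_otus))
    # block members get a common boost so modules are well sampled and
    # their rank correlations are not washed out by counting noise
    scales[block_of >= 0] = np.exp(
        rng.normal(design.block_scale_boost, 0.3,
                   size=int((block_of >= 0).sum())))
    return scales


def simulate_counts(design: GradientDesign, metadata: pd.DataFrame
                    ) -> tuple[OtuTable, GroundTruth]:
    """Multinomial counts for every sample in `metadata`.

    Expected relative abundance is a Gaussian kernel of the distance
    between sample RH and OTU niche, modulated by a shared per-block
    log-normal latent factor (planting positive within-block rank
    correlations) and OTU-level log-normal noise; sequencing depth is drawn
    from the design's log-normal.  Deterministic given (design, metadata).
    """
    required = {"AvgSoilRH"}
    if not required <= set(metadata.columns):
        raise ConfigurationError(
            "metadata must come from simulate_environment (AvgSoilRH "
            "column missing)")
    rng = np.random.default_rng([design.seed, 5])
    otu_ids, niches, block_of, _, membership, truth_niche, effects = \
        _community_structure(design)
    scales = _abundance_scales(design, block_of)
    rh = metadata["AvgSoilRH"].to_numpy(float)
    n_samples = len(metadata)
    W = _kernel_weights(design, niches, block_of, rh) * scales

    is_block = block_of >= 0
    eps_sd = np.where(is_block, design.block_noise_sd,
                      design.background_noise_sd)
    eps = rng.normal(0.0, 1.0, size=W.shape) * eps_sd[None, :]
    latent = np.zeros_like(W)
    if design.n_blocks:
        sizes = design.block_sizes()
        reaches = design.block_reaches()
        for b in range(design.n_blocks):
            members = np.flatnonzero(block_of == b)
            latent[:, members] = design.block_factor_sd * _block_field(
                len(members), reaches[b], n_samples, rng)
    W = W * np.exp(latent + eps)

    mu, sd = design.depth_lognormal_params
    depths = np.maximum(1, np.round(
        rng.lognormal(mu, sd, size=n_samples))).astype(int)
    probs = W / W.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(depths[j], probs[j]) for j in range(n_samples)])
    table = OtuTable(pd.DataFrame(counts, index=metadata.index,
                                  columns=otu_ids))
    truth = GroundTruth(
        block_membership=membership,
        otu_rh_niche=truth_niche,
        phylum_effect=dict(effects),
        sample_gradient={s: float(v) for s, v in
                         zip(metadata.index, rh)},
    )
    return table, truth


def _block_field(m: int, reach: float, n_samples: int, rng) -> np.ndarray:
    """Unit-variance latent field over a block's internal community axis.

    Members sit at positions 0..m-1; knots along the axis carry i.i.d.
    standard-normal values per sample and each member mixes them through
    an L2-normalized Gaussian bump of width `reach` (member-spacing
    units).  Member pairs at distance d then correlate as roughly
    exp(-d^2 / (4 reach^2)): members within ~reach of each other
    co-occur tightly, distant members weakly — a chain for small reach, a
    dense web for large reach.
    """
    positions = np.arange(m, dtype=float)
    spacing = max(reach / 1.5, 0.5)
    knots = np.arange(-2.0 * reach, (m - 1) + 2.0 * reach + 1e-9, spacing)
    B = np.exp(-0.5 * ((positions[None, :] - knots[:, None]) / reach) ** 2)
    norms = np.sqrt((B ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    B = B / norms
    V = rng.normal(size=(n_samples, len(knots)))
    return V @ B


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(design: GradientDesign
                     ) -> tuple[Dataset, GroundTruth]:
    """Generate metadata, counts, taxonomy and tree; classify samples."""
    metadata = simulate_environment(design)
    table, truth = simulate_counts(design, metadata)
    taxonomy = simulate_taxonomy(design)
    tree = simulate_tree(design)
    metadata = classify_metadata(metadata)
    dataset = Dataset(table=table, metadata=metadata, taxonomy=taxonomy,
                      tree=tree)
    return dataset, truth
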