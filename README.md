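# aridnet

Analysis pipeline for soil microbiome surveys along aridity gradients:
within- and between-sample diversity versus soil climate, exhaustive
environmental-driver selection, OTU co-occurrence network inference with
multiple-testing control, network deconvolution and random-matrix-theory
(RMT) thresholding, aridity-class network topology comparison, a
richness-matched resampling null, and taxon–aridity abundance gradients.
It is aimed at microbial ecologists working with 16S amplicon OTU tables
from desert or dryland transects, where the central questions are *which
climatic variables structure the community* and *whether drier communities
are less connected*.

A fully synthetic data generator reproduces the statistical structure such
a survey assumes — a monotone soil-relative-humidity (RH) gradient,
declining richness with aridity, planted co-occurrence modules whose
density tracks RH, and signed phylum-level abundance responses — with the
planted structure serialized as ground truth, so every stage of the
pipeline is testable without the original sequencing data.

## Methods at a glance

* **Alpha diversity** — Faith's phylogenetic diversity
  (PD = Σ branch lengths of the minimal rooted subtree spanning the
  observed taxa), Shannon *H* = −Σ pᵢ log₂ pᵢ, Simpson 1 − Σ pᵢ²;
  Spearman rank correlations *r*ₛ against environmental variables with
  Benjamini–Hochberg FDR (*q*) control.
* **Beta diversity** — unweighted and normalized weighted UniFrac on
  rarefied counts, principal-coordinate analysis, seeded one-sided Mantel
  and ANOSIM permutation tests, and BEST/BioEnv: an exhaustive search over
  all 2ᵏ − 1 subsets of z-scored environmental variables for the subset
  whose Euclidean distances best rank-correlate with community
  dissimilarity.
* **Co-occurrence network** — rare OTUs (< 0.01 % of reads) removed;
  all-pairs Spearman correlations of relative abundances; network
  deconvolution (spectral transform λ_d = λ/(1+λ) separating direct from
  transitive dependencies); correlation cutoff chosen where the
  nearest-neighbour eigenvalue spacing distribution of the thresholded
  matrix leaves the Wigner–Dyson (GOE) regime and fits the Poisson law;
  edges kept only if |rₛ| ≥ cutoff, *q* ≤ 0.01 and deconvolved weight > 0.
  Per-sample induced subgraphs are summarized by size, mean degree, mean
  betweenness, edge count, average shortest-path length (reachable pairs)
  and Freeman betweenness centralization, with medians per aridity class.
* **Richness-matched null** — arid and margin samples repeatedly rarefied
  to 300 reads (richness reduced to the hyperarid level), networks rebuilt
  per replicate, statistics averaged per sample across replicates and
  compared with the untouched hyperarid row.
* **Aridity classes** — vegetated sites are *arid*; unvegetated sites with
  shallow nitrate > 20 or sulfate > 500 µmol·g⁻¹ (10–20 cm) are
  *hyperarid* unless a hydrologic (salar) override applies; the rest are
  *margin*.

## Worked example

```bash
aridnet --seed 1 --out-dir demo --set "design={'n_otus': 400}" all
```

writes `demo/` with the dataset (`data/`), `alpha.tsv`, UniFrac matrices,
`mantel_report.tsv`, `best.tsv`, `edges.tsv`, `class_summary.tsv`,
`null_summary.tsv`, `taxa_gradients.tsv`, `nitrogen_guilds.tsv` and a
checksummed `manifest.json`. The same analyses are available as library
calls; on the default synthetic gradient at seed 1 the pipeline prints,
via `scripts/acceptance.py` (see below):

```
richness_vs_rh_spearman        0.861   # richness falls with aridity
mantel_unifrac_vs_rh           0.799   # RH drives phylogenetic turnover
anosim_vegetation_R            0.620   # vegetated vs unvegetated samples
rmt_threshold_global           0.80    # RMT correlation cutoff
fraction_positive_edges        100.0 % # co-occurrences are positive
planted_edge_precision         84.2 %  # retained edges inside true modules
actinobacteria_vs_rh_spearman  -0.879  # the dry-adapted phylum
```

Interpretation: richness and phylogenetic composition track soil relative
humidity; the network's retained edges are overwhelmingly positive
co-occurrences and recover the planted modules; the dominant dry-adapted
phylum declines in relative abundance as RH rises — the qualitative
signature expected of an aridity-gradient soil survey.

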