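# Methods

This note documents the models, numerical choices and known limitations of
`aridnet`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## The analysis model

The pipeline treats an aridity-gradient soil survey as four linked
questions.

**Does diversity track soil climate?** Within-sample diversity is
quantified as observed OTUs, Faith's PD (sum of branch lengths of the
minimal rooted subtree spanning the observed taxa — the rooted variant, so
a single taxon contributes its full root path), Shannon entropy in bits
(base 2; configurable, since the convention differs between toolkits) and
Simpson 1 − Σp². Alpha metrics are computed on unrarefied counts by
default with a rarefaction-depth knob, because diversity–environment rank
correlations are insensitive to proportional depth differences while
rarefaction discards data. Correlations use Spearman's rₛ with midranks;
the scalar helper computes an exhaustive two-sided permutation p for
n ≤ 10 (streamed in chunks, so n = 10's 3.6 M orderings are feasible) and
the t approximation otherwise. Families of tests are corrected with
Benjamini–Hochberg FDR. Group contrasts (vegetated vs unvegetated
richness) use Welch's unequal-variance t test.

**Which variables drive compositional turnover?** Between-sample
dissimilarity is unweighted and normalized weighted UniFrac on counts
rarefied to a common depth (default 17,212 reads, the convention for this
survey design; the pipeline clamps to the smallest sample when the data
are shallower). Ordination is metric PCoA; negative eigenvalues are
reported, never silently dropped. The Mantel statistic is the Spearman
correlation of distance-matrix upper triangles with a one-sided
(positive-association) permutation p using the add-one rule and a seeded
generator; when n! does not exceed the requested permutation count the
relabellings are enumerated and the p-value is exact. ANOSIM follows the
standard rank formulation R = (r̄_between − r̄_within)/(n(n−1)/4).
BEST/BioEnv evaluates every non-empty subset of z-scored (ddof = 1)
environmental variables — exactly 2ᵏ − 1 subsets, capped at 15 variables —
and ranks subsets by rₛ between community and environmental distances.
Squared per-variable coordinate differences are precomputed once, so the
exhaustive search is O(2ᵏ · n²) additions.

**Are drier communities less connected?** Co-occurrence analysis removes
OTUs carrying < 0.01 % of total reads (read as a fraction of reads — the
only dimensionally coherent reading; knob exposed), computes all-pairs
Spearman correlations of relative abundances (constant vectors are set to
r = 0, p = 1 with a log note), and distinguishes direct from transitive
dependencies by network deconvolution: the observed matrix (diagonal
zeroed, signed) is eigendecomposed, scaled by α so the largest transformed
eigenvalue magnitude equals β = 0.99, each eigenvalue mapped as
λ_d = λ/(1+λ), and reassembled. The mapping is invertible
(λ = λ_d/(1−λ_d)), which the tests exploit as a spectrum-recovery check.

The correlation cutoff is chosen by RMT thresholding: for each candidate
cutoff the matrix is restricted to OTUs retaining at least one edge,
hard-thresholded, eigendecomposed, the spectrum unfolded (cubic
least-squares spline with knots at eigenvalue quantiles fitted to the
empirical cumulative spectral density), and the nearest-neighbour spacing
distribution tested by chi-square against Poisson e^{−s} and the GOE
surmise (πs/2)e^{−πs²/4}. The chosen cutoff is the smallest at which
Poisson fits (p > 0.05), GOE is rejected, **and** the acceptance persists
over the following grid points (3 of the next 4): single-grid-point
acceptance is chi-square noise and produced unstable cutoffs. Two
deliberate departures from a more naive reading are documented here
because they matter: (i) the spectrum uses *all* non-isolated OTUs, not
one connected component — the Poisson signature of modularity comes from
superposing independent module spectra, and a single module alone shows
GOE-like level repulsion; (ii) persistence, as above. Edge retention
requires all three of |rₛ| ≥ cutoff, BH q ≤ 0.01 (computed over the
upper-triangle family) and positive deconvolved weight; retained edges
keep their sign and the positive fraction is reported, not filtered.

Topology is summarized per sample on the global network's induced
subgraph over the OTUs present in that sample: node count, mean degree,
mean unnormalized betweenness, edge count, mean shortest-path length over
reachable pairs only (finite on fragmented graphs, matching how
"island"-topology networks are tabulated), and Freeman betweenness
centralization Σ(b_max − bᵢ) normalized by the star-graph maximum
(n−1)²(n−2)/2, so a star scores 1 and a complete graph 0. Class summaries
are midpoint medians per aridity class. Per-class subnetworks re-run the
whole inference chain on one class's samples and record that class's own
RMT threshold; the class-level topology table, however, is computed from
the global network's induced subgraphs — at a dozen samples per class a
class-internal correlation matrix could not pass a BH q ≤ 0.01 filter at
realistic edge counts, so the global reading is the coherent one.

**Is hyperarid disconnection a richness artifact?** The null model
rarefies arid and margin samples to 300 reads (dropping none by
construction of the defaults), re-applies the same rare-OTU rule per
replicate, rebuilds the class networks reusing each class's parent
threshold (re-running RMT hundreds of times is costly and the cutoff is a
property of the community, not of one rarefied draw; a full re-threshold
flag exists), and aggregates as average-across-replicates-then-
median-across-samples. Hyperarid samples are never resampled. A richness
check verifies the rarefied classes actually reached the hyperarid
richness level (default tolerance 20 %).

**Which taxa respond?** Counts are collapsed to a rank (unassigned OTUs
pooled so per-sample fractions sum to 1 exactly), correlated with soil RH,
BH-corrected within the rank family, and flagged at |rₛ| > 0.6, q < 0.02.
The heat-map matrix keeps flagged phyla with site RA > 0.1 %, rows ordered
by decreasing rₛ and normalized to unit row maximum, columns ordered by
RH. A configurable nitrogen-cycling guild list (default: the 11 named
N₂-fixing and nitrifying genera; the list is documented as open-ended)
is reported with detection counts, RA ranges and RH correlations.

## The synthetic generator

`GradientDesign` defaults describe a 13-site transect with triplicate
pits (39 samples — the scale of a real two-transect desert survey; at 30
samples the pure sampling-noise tail of ~10⁶ OTU pairs overlaps any
attainable correlation cutoff), soil RH spanning 2–78 %, 1500 OTUs and 12
planted modules. Per-sample metadata tie the covariates together:
elevation rises along the transect, temperature falls with elevation,
vegetation cover is positive only above 40 % RH, shallow nitrate/sulfate
are high only below 20 % RH — so the synthetic classes reproduce the
field classification rules.

Counts are multinomial draws at log-normal depth from kernel-derived
relative abundances; Spearman-based statistics downstream are invariant
to this compositional closure. Background OTUs follow Gaussian RH niches
drawn from a humid-skewed Beta(3.5, 0.8) pool (richness therefore falls
with aridity) with log-normal abundance scales (sd 1.5) and residual
noise (sd 1.8). Phylum identity is drawn conditional on niche position,
which realizes signed, monotone phylum–RH abundance responses
(an Actinobacteria-like phylum concentrates at the dry end); guild genera
are planted on humid-adapted members of their host phyla, with the three
classic nitrifiers deliberately never planted.

Planted modules have an internal *community axis*: members load on a
Gaussian-bump latent field over the axis, so member pairs correlate as
≈ exp(−d²/4·reach²) in positions. The reach grades sigmoidally with the
module's niche — hyperarid-core modules are thin chains (the weakly
bridged "islands" of dry-soil networks), humid modules are wide, densely
connected webs — and module sizes grade from 10 to 30 members. Member
niches are staggered ±9 % RH around the module optimum with a flat-top
(quartic) activity window, so presence patterns grade along the axis
instead of being identical across a module. All outputs are pure
functions of (design, seed); ground truth (module membership, niches,
phylum effects, sample gradient) is serialized as JSON.

What the generator does *not* emulate: sequencing error and chimeras,
compositional interactions beyond closure, spatial autocorrelation
between neighbouring sites, depth-resolved geochemistry, and negative
biotic associations (planted correlations are positive, matching the
observation that dryland co-occurrences are overwhelmingly positive).
Passing tests therefore demonstrate that the pipeline recovers structure
of this idealized form, not that it is robust to every artifact of real
amplicon data.

## Numerical choices

Seeds: every stochastic step takes an explicit seed; the pipeline derives
stage seeds as fixed offsets from the master seed, and derived seeds stay
below 2³¹. Rarefaction uses the exact multivariate hypergeometric
distribution. Ties: midranks everywhere; medians are midpoints of central
order statistics. Permutation p-values use the add-one rule except under
exhaustive enumeration, where they are exact. Degenerate inputs are
contracts, not crashes: constant vectors raise a typed error in scalar
statistics, are flagged (r = 0, p = 1) in the correlation matrix, and
produce NaN-with-warning in survey reports; empty induced subgraphs yield
zero statistics with a warning.

## Known limitations

* **Shared-zero inflation.** Under global rank correlation, any two OTUs
  confined to the dry end of the gradient share most of their tied zero
  ranks and correlate strongly regardless of their dynamics within dry
  samples. This is a known artifact of correlation-based co-occurrence
  networks on presence-sparse data, and it biases hyperarid induced
  subgraphs toward denser, shorter-path topology than their within-class
  dynamics warrant. At the default scale the directional class contrasts
  hold; at aggressive scale-downs (150 OTUs, 30 samples) the margin class
  retains only ~6 samples and the full monotone ordering of path length
  across all three classes is not reliably recovered.
* **Small-class nulls.** The BH q ≤ 0.01 edge filter is far more
  destructive at 6 rarefied samples than at 12–18; richness-matched null
  edge counts for very small classes are conservative.
* **RMT at small n.** The spacing tests need a few dozen eigenvalues;
  below ~30 OTUs the procedure refuses and asks for a fixed threshold.
* **Weighted UniFrac** (normalized) is not guaranteed metric; triangle
  violations are possible and are logged, not fatal.
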