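# Methods

## The problem

Surface-ocean phytoplankton fix carbon; a fraction of that carbon sinks out
of the mixed layer in particles (the biological carbon pump). Which taxa are
exported, and in what kind of particle, determines sinking speed and
remineralisation depth — parameters that biogeochemical models need but that
bulk flux measurements cannot resolve. Comparing 18S rRNA gene ASV
communities among surface seawater, bulk sediment-trap material and
individually isolated sinking particles (>300 µm, picked from polyacrylamide
gel layers) turns presence/absence set algebra into an export-mechanism
assay:

* **Export detection.** A phytoplankton ASV detected in pooled surface
  seawater counts as exported if it is also detected in any trap sample
  (bulk or isolated particle). Heterotrophs are excluded from this call,
  because their presence at depth can reflect colonisation rather than
  export. Within each functional group, the exported ASVs' share of pooled
  surface reads measures how much of that group's standing stock the
  exported taxa represent.
* **Size partitioning.** Bulk trap samples contain sinking material of all
  sizes plus zooplankton "swimmers"; isolated particles are the >300 µm
  size class. A bulk-detected ASV also found in at least one isolated
  particle sank (at least partly) in large particles; one found only in
  bulk is inferred to have sunk in the small fraction (<300 µm particles,
  single cells, or swimmers). This analysis needs both sample types, so a
  station without bulk samples raises an error rather than a partial
  answer.
* **Degradation.** Particles isolated 1–2 days after trap recovery lose
  detectable ASVs at taxon-specific rates. Richness is computed on a
  presence/absence transform of the non-rarefied table restricted to ASVs
  with ≥ 10 reads dataset-wide (rarer ASVs are indistinguishable from
  noise in a presence call); loss is measured per delayed particle against
  the mean richness of immediately isolated particles of the same class
  and deployment, then summarised as mean ± SD across particles. The
  baseline is class- and deployment-matched because particle classes differ
  systematically in richness; cells with a zero baseline are dropped with a
  warning rather than poisoning the whole summary.
* **Carbon scaling.** Within a functional group, relative read abundance is
  used as a proxy for relative biomass, so group biomass B_g
  (HPLC-derived, mixed-layer-integrated, mmol C m⁻²) times the exported
  read share gives exported biomass E_g. Each exported ASV's share is
  routed to the large or small size fraction; an ASV seen in an isolated
  particle counts as large even if absent from bulk, since direct
  observation outranks the bulk-only inference. POC flux per particle type
  is an external input (an image-based flux model) and is passed through
  unchanged.

## Community statistics

Rarefaction draws each sample down to a common depth (default 31 993 reads)
without replacement — a single multivariate-hypergeometric draw per sample
with a recorded seed; samples below the depth are dropped and reported.
Bray–Curtis dissimilarities come from `scipy.spatial.distance`. PERMANOVA
uses the distance-based sum-of-squares decomposition
(SS_total = N⁻¹ Σ_{i<j} d²_ij; SS_within = Σ_g n_g⁻¹ Σ_{i<j∈g} d²_ij),
which is exact for arbitrary dissimilarities without embedding samples in
coordinates. The permutation p-value uses the +1 convention,
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so it never returns zero; an
`exact=True` mode enumerates all label permutations (counting the identity),
used for small-n verification. Pairwise tests run on the pair's sub-matrix
with Bonferroni adjustment p_adj = min(1, p·C). Welch t-tests
(Satterthwaite df) and classical one-way ANOVA back the genus-level
contrasts and richness comparisons; the strict α = 0.001 for genus
contrasts and α = 0.05 for ANOVA are configuration values, and no further
multiplicity correction is applied to the genus scan.

Floating-point ties in the permutation count are resolved generously
(F_perm ≥ F_obs − 1e-12 counts as extreme), which is conservative for p.

## The synthetic-data generator

`simulate()` produces datasets with the mechanisms the analyses assume,
plus the ground truth to check recovery against:

* Taxa belong to functional groups, each with a PR2-style lineage template
  (covering every classification-rule branch, including the
  Dinoflagellata-but-not-Syndiniales special case), a Dirichlet
  concentration for within-group surface proportions, a surface read
  weight, a log-uniform cell-size range, an export probability and a decay
  rate λ (d⁻¹).
* An exported taxon is packaged into the large (>300 µm) fraction with
  probability 1 / (1 + (s / s₀)^k) for cell size s — a logistic decreasing
  in log size (midpoint s₀ = 50 µm, steepness k = 2), encoding the
  observed inversion: small cells ride large fecal pellets, the largest
  cells (Coscinodiscus-like, 0.5–1 mm) sink within the small fraction.
* Isolated particles draw reads only from exported-large taxa; a particle
  isolated after delay d first drops each taxon independently with
  probability 1 − exp(−λ_g d) (degradation acts on detectability, i.e.
  presence, not on read counts, matching the richness-loss observable).
  Bulk samples mix all exported taxa with swimmer taxa — heterotroph-only
  contaminants absent from seawater and isolated particles — at a
  configured read fraction (default 0.15).
* Reads are multinomial at configured depths after per-sample Dirichlet
  overdispersion.

The `paperlike` fixture reproduces the study layout: 3 stations, 40
seawater samples (13/13/14), 6 bulk samples (none at Station 1, so the
size-partition error path is exercised), ~80 isolated particles of 4
classes with Station-3 delays of 0/1/2 days across two deployments, and
group weights putting ~80% of reads in heterotrophs. Default decay rates
(dinoflagellates 0.9 d⁻¹, diatoms 0.4 d⁻¹, chlorophytes 0) produce the
qualitative ordering reported for the field data: severe dinoflagellate
loss, intermediate diatom loss, chlorophytes essentially unaffected. Read
depths (60 k seawater/bulk, 40 k particle) keep every sample above the
31 993-read rarefaction depth and make presence detection essentially
complete at λ = 0, which is what lets the recovery tests demand exactness.

What the generator does **not** emulate: sequence-level artefacts (PCR
bias, chimeras), copy-number variation between taxa (reads are treated as
proportional to abundance within a group), depth-structured seawater
communities, preservation chemistry, and particle colonisation at depth.
Passing recovery tests therefore show the *algorithms* are correct under
the stated mechanisms, not that real amplicon data satisfy those
mechanisms.

## Numerical and design choices

* Presence means ≥ 1 pooled read by default (`min_reads_per_asv`
  configurable) — the definitions are presence-based; the knob exists for
  sensitivity analysis.
* Seawater pooling spans all depths and size fractions within a station;
  Station-3 deployments are pooled for the main analyses, with the
  deployment-consistency check (per-group |Δ exported read share| between
  deployments) as the robustness companion.
* Surface read shares are pooled-unweighted across mixed-layer samples
  (no depth weighting).
* The feature-table reader auto-detects QIIME2-style ASV-rows orientation
  via the `#OTU ID` header; lineages are padded/truncated to exactly 8
  ranks; rank matching is exact, case-sensitive string equality after
  trimming, because fuzzy matching would hide data errors.
* The default photosynthetic rule set lists the groups used throughout
  (Bacillariophyta separate from Other_Ochrophyta, Dinoflagellata minus
  Syndiniales, Chlorophyta, Hacrobia) and is deliberately an editable YAML
  config, not a constant: it is an auditable approximation of a full
  photosynthetic-lineage table, not a canonical one.
* Saturation curves draw one random particle ordering per replicate and
  evaluate prefix unions: monotonicity in n then holds exactly within each
  replicate, and the value at n is distributed as a uniform size-n subset,
  so Monte-Carlo means converge to the exhaustive C(N,n) subset average.
* Problem sizes in the test suite and acceptance script (e.g. 1 000
  random set-algebra instances, 200–400 null simulations for calibration,
  100 seeds for decay ordering, 199–999 permutations) were chosen as the
  smallest sizes at which the checked distributional statements have
  negligible Monte-Carlo ambiguity.

## Known limitations

* Export detection is presence-based and station-pooled; it cannot see
  depth structure or quantify per-particle loads.
* The small-fraction inference is indirect: "bulk-only" conflates <300 µm
  particles, free cells and swimmers. The generator marks swimmers so the
  tests can quantify that conflation; the field analysis cannot.
* Decay rates are generator parameters only; inferring λ from field data
  is out of scope.
* Relative reads are an imperfect biomass proxy (rRNA copy number varies
  enormously, especially among dinoflagellates); the carbon budget is
  therefore group-internal and should be read as a scaling framework, not
  a measurement.
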