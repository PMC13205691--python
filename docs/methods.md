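# Methods

`dietvirome` implements the statistics layer of a diet-intervention gut
virome analysis: given abundance tables for phages and bacteria, sample
metadata, taxon annotations (lifestyle, species names), HGT event tables and
gene-level abundance tables, it computes lifestyle dynamics, phage-host
association statistics, phage-mediated HGT classification and auxiliary
metabolic gene (AMG) screens. Upstream sequence processing (QC, assembly,
viral identification, lifestyle prediction, HGT detection) is out of scope:
those results enter as inputs.

## Abundance model

Two abundance scales are used. Coverage-style normalization is

    abundance = mapped_reads / (L × N) × 1e10

with `L` the target length (bp) and `N` the sample's total read count; the
1e10 factor keeps typical gut-metagenome values in a readable range. The
quantity is linear in mapped reads and undefined for `L = 0` or `N = 0`.
Relative abundance divides each sample column by its column sum; an all-zero
column stays zero. Units travel with the matrix as explicit metadata
(`read_count`, `relative_fraction`, `relative_percent`, `normalized_1e10`),
and threshold-bearing operations check them: the taxon retention filter
(keep a taxon when its maximum relative abundance exceeds 0.2 in the
matrix's declared unit, or it is detected in ≥ 1% of samples) refuses count
matrices rather than silently reinterpreting the threshold. Maximum — not
mean — relative abundance is used for the first disjunct; the alternative is
one keyword argument away.

Community convergence between two sample sets is measured with Bray-Curtis
dissimilarity, Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ). Because unbalanced group sizes bias
distance comparisons, the shift procedure subsamples an equal number of
samples per side without replacement, records the median of all inter-group
pairwise distances, and tests them against the within-baseline-group
distances of the same draw with a two-sided Wilcoxon rank-sum test; this is
repeated (100 iterations by default) under a caller-supplied seed. The
comparison baseline (inter-group vs within-pre) is a design choice — the
procedure only fixes that a rank-sum test is applied to the distance sets —
and is configurable.

## Host linking

Phage-host candidates come from nomenclature: the species-name string of a
phage (`s__Bacteroides_phage_42`) carries its putative host genus as the
first capitalized genus-like token preceding a phage designator token
(`phage`, `virus`, `siphovirus`, ...). Parsing is case-sensitive and exact;
names with no designator or no capitalized token yield no link, and names
with more than one capitalized candidate are linked to the first but flagged
ambiguous. crAssphages are special-cased: any name containing "crass"
(case-insensitive) is assigned host genus *Bacteroides* (phylum
Bacteroidetes), since the clade is a well-characterized *Bacteroides* phage
group whose names do not encode a host. Pair formation emits every
(phage, bacterium) combination whose genera match exactly; output is
canonically sorted, so it is independent of input order.

## Lytic-lysogenic index (LLI)

The LLI compares virulent (obligately lytic) to temperate phage abundance.
Three formulations serve three scopes:

* **Community** — the ratio of total virulent to total temperate relative
  abundance in a sample, optionally pseudocounted. Phages with unknown
  lifestyle are excluded. Group summaries report both mean and median; the
  headline percent change uses the mean.
* **Per vOTU** — `|log2((v + 0.1)/(t + 0.1))|` with the 0.1 pseudocount
  fixed by definition. The day-0 to day-10 change statistic is
  `log10(LLI_d10 / LLI_d0 + 1)`; note its no-change baseline is log10(2)
  ≈ 0.301, not 0, a property kept verbatim. A conventional log10-ratio
  variant (baseline 0) is available via `convention="log_ratio"`. A zero
  day-0 LLI leaves the ratio undefined; the record is skipped with a
  warning rather than imputed.
* **Per host genus** — the median over the genus' phages of
  `(v + 1)/(t + 1)`, with the temporal shift reported as
  `log10(LLI_d10 / LLI_d0)`: positive means a shift toward lytic dominance.

Group comparisons of LLI values use Kruskal-Wallis with the standard tie
correction, Dunn's pairwise z tests on pooled ranks (tie-corrected),
Benjamini-Hochberg adjustment within the pairwise family, and a
compact-letter display at adjusted p < 0.05 built from maximal cliques of
the "not significantly different" graph. Keys with fewer than two groups of
n ≥ 5 are excluded with a logged reason.

## Phage-bacterium association statistics

Each linked pair's association is Spearman's ρ on abundances within a group
stratum, average ranks for ties. The p value is an exact permutation p for
n ≤ 9 and the t approximation otherwise; constant vectors are skipped with
a warning. Benjamini-Hochberg adjustment is applied within each stratum's
family (the strata are analyzed separately throughout), with a global-family
option. Interaction-strength change between control and intervention
compares the |ρ| sets by Wilcoxon rank-sum: "Increased"/"Decreased" when the
intervention median is above/below the control median with p < 0.05,
otherwise "non-significant" — equal medians are non-significant regardless
of p. Rank-sum tests use the exact null when both sides have n ≤ 25 and the
pooled data are tie-free, otherwise the normal approximation with continuity
correction.

Per-project trend voting defines a taxon's direction in a project as the
sign of (median intervention − median control) abundance; zero differences
are excluded. A phage's overall trend is "increasing" when strictly more
projects increase than decrease, "decreasing" in the mirror case, and
"indeterminate" on ties or empty votes. Concordance counts, over projects
shared by a phage and its host, same-direction versus opposite-direction
changes, and reports N_concordant / (N_concordant + N_discordant); the score
is undefined (flagged, not faked) without shared projects.

The differential-abundance screen used to nominate diet-associated bacteria
is a deliberately transparent surrogate: Kruskal-Wallis p < 0.05 across
groups plus a log10 between-group mean-difference effect gate (default 0.5,
about a 3-fold mean difference). It is labeled `surrogate_screen` in output;
externally supplied calls (e.g. from LDA-effect-size tools) bypass it
verbatim and are labeled `provided`.

## Mobilome

An HGT event is phage-mediated when its transferred gene aligns to a phage
contig with nucleotide identity strictly > 90% and E-value strictly < 1e-5;
the best qualifying hit by bit score is recorded. The screen is
deterministic, and loosening either threshold can only grow the flagged set.
Frequency changes versus a baseline are reported as fold change and percent
change on raw event counts (a per-sample rate is available but not the
default, since events are not normalized by sample number upstream).
Donor/recipient role bias per genus is a strict-majority label over event
tallies.

HGT-enzyme trajectories summarize integrase/recombinase/transposase
abundance as per-(class, group, day) medians; "continuously increasing"
requires strictly increasing medians over the ordered days, and a group
missing a day leaves the flag undefined.

Signed log10 abundance changes follow the convention
`+log10(b − a)` for increases and `−log10(|b − a|)` for decreases (0 when
equal). This is sign-unstable for |b − a| < 1, where the log of a small
positive difference is negative; it is kept as the default for fidelity,
with a `stabilized` alternative `sign(b − a) · log10(|b − a| + 1)` that is
sign-faithful at all magnitudes.

The AMG reversal filter retains KEGG orthologs whose day-0 → day-10 change
is significant (rank-sum, p < 0.05) in both the HFD and FUC groups, then
selects, independently at each post-baseline day d, those with (1) a
positive HFD percent change versus its own day-0 median and (2) a FUC
median below the HFD median at day d. One record is emitted per (KO,
evaluated day); output is ordered by pathway, then descending day-10 HFD
up-regulation, then KO id. The cross-kingdom homolog filter keeps alignment
hits with E-value < 1e-5 and bit score strictly > 90, then the first
surviving record per query id in input order.

## Synthetic study generator

The generator emulates a three-arm mouse study — CON, HFD, FUC; 6 subjects
per group; sampling days 0/10/14/18 — and plants every signal the pipeline
is meant to detect, recording the truth for recovery scoring:

* **Abundances** are log-normal (σ = 0.5 on the log scale) around per-taxon
  baselines. Defaults: 200 phages, 60 bacteria, 12 linked pairs.
* **Correlations**: each linked phage-bacterium pair shares a Gaussian
  latent factor with Pearson weight `r = 2 sin(π ρ_s / 6)`, the exact
  Gaussian-copula inverse of the target Spearman ρ_s (default 0.8); because
  Spearman is invariant under the monotone log-normal marginals, the planted
  population Spearman is exact and no numerical calibration is needed.
* **Lifestyle composition**: per-(group, day) virulent relative-abundance
  fractions (CON 0.7 throughout; HFD 0.7 → 0.5 after baseline; FUC
  intermediate at 0.65) are realized exactly per sample by rescaling the
  virulent block. Correlation-planted phages are drawn from the temperate
  block, so this rescaling cannot distort the planted correlations.
* **Diet-associated bacteria**: 5 taxa carry a 10-fold HFD effect on
  post-baseline days.
* **HGT**: 300 events with the phage-mediated fraction set to the
  study-wide observed proportion (476/7115 ≈ 6.7%); mediated genes receive
  alignment hits passing the identity/E-value screen, half of the rest
  receive decoy hits failing it, so the screen recovers the planted labels
  exactly.
* **Gene tables**: mobility-enzyme medians follow planted per-(class,
  group) trends (2-fold steps across days; only FUC increasing by default),
  and KO tables realize planted reversal effects (HFD 3-4-fold up, FUC
  2-2.5-fold down) for five amino-acid-metabolism orthologs next to five
  null controls, with σ = 0.3 gene-level noise.

A single seed drives a `SeedSequence`-spawned stream per table, so adding a
table leaves earlier tables byte-identical. The generator reproduces the
study's *statistical design*, not real data: taxa are exchangeable apart
from planted effects, noise is homoscedastic log-normal, repeated measures
on a subject are independent draws, and compositional coupling between taxa
is absent. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the declared model, not performance on real
metagenomes.

## Numerical and design notes

* Problem sizes in the test suite and acceptance script are scaled to small
  synthetic studies (20-60 taxa per kingdom, 50 recovery seeds, 200 null
  replicates), chosen so the full suite completes in well under a minute
  while keeping Monte Carlo rates stable.
* Repeated measures (the same mouse across days) are pooled as independent
  samples within a group stratum, matching the upstream analysis
  convention; this is a documented limitation, not a recommendation.
* All rank tests use average ranks for ties. Wilcoxon rank-sum tests are
  exact for tie-free data with n ≤ 25 per side; Spearman p values are exact
  permutation values for n ≤ 9.
* The pipeline is a pure function of (inputs, config, seed); every stage
  writes its outputs before the next starts, and a failed stage is recorded
  in `report.json` without discarding completed outputs.
* Known limitations: nomenclature-based host linking misses phages whose
  names carry no host genus and cannot resolve genus homonyms; the
  surrogate differential screen is not an LDA-effect-size replication; the
  verbatim signed-log-change convention is sign-unstable below unit
  differences (use `stabilized` when that matters).
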