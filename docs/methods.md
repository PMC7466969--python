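# Methods

## The screening model

The screen treats "bacterial origin" as a conjunction of three independent
lines of evidence, applied to every annotated gene model.

**Best-hit taxonomy.** Homology hits (BLAST-tabular rows with a
subject → (taxonomy group, superkingdom) map) are filtered at an E-value
cutoff of 10⁻¹⁰; the cutoff is a named parameter everywhere it appears.
The per-gene call is *fungal* if any passing fungal hit exists (a single
fungal homolog vetoes candidacy, however weak relative to the bacterial
hits), *other* if any passing non-fungal non-bacterial hit exists
(candidacy requires hits to bacteria *only*), *bacterial* if only
bacterial hits pass, and *none* otherwise.  The donor taxon is taken from
the single best passing hit — minimum E-value, ties broken by maximum bit
score and then input order; the top-ten taxa list is reported but does not
influence the call.  Candidacy is deliberately not monotone in the
cutoff: tightening it can drop a gene's fungal veto hit while a stronger
bacterial hit survives, so the only monotonicity we assert (and test) is
among genes whose hits are bacterial-only.

**Coverage z-score.** z = (mean depth over the gene span − scaffold
per-base mean) / scaffold per-base SD.  Depth is genomic, so the mean is
taken over the full gene span, introns included.  The scaffold statistics
include the candidate's own bases, and the SD is the population SD
(ddof = 0); both choices are exposed (`ddof` switch) and documented because
either convention is defensible.  Retention is strict: |z| < 2.  A
scaffold with uniform coverage has SD 0 and cannot witness deviation; its
genes get z = 0 with a warning rather than an error.  Genes whose depth
tracks their scaffold — including every gene of a uniformly high-coverage
contaminant scaffold — pass this filter; it only catches *locally* deviant
depth (chimeric joins, collapsed repeats, spliced-in contigs).

**Genomic context.** A candidate is retained iff at least one fungal-call
gene lies anywhere upstream or downstream on the same scaffold.  This is
the complement of the coverage filter: it removes entire contaminant
scaffolds (all-bacterial neighborhoods), including single-gene scaffolds,
which vacuously have no fungal neighbor.  On noise-free data the coverage
and context filters examine disjoint evidence and therefore commute.

## Composition statistics

Per-gene features: GC content (N bases excluded from numerator and
denominator), intron count and normalized intron length (total intron nt
divided by the gene-model *span*, not the CDS), overlapping 5-mer counts
divided by CDS length (windows containing N are skipped; the denominator
stays the full length), and in-frame codon counts divided by CDS length
(so the 64-vector sums to exactly 1/3).  Groups for the contrasts are
*hgt* (retained candidates), *neighbor_fungal* (fungal-call genes sharing
a scaffold with a retained candidate) and *all_fungal* (the remaining
fungal-call genes); the three are disjoint levels of one factor.

The tests are computed from their defining formulas — ANOVA from the
between/within sum-of-squares decomposition, Tukey HSD from the
studentized-range statistic with the pooled within-group mean square
(Tukey–Kramer form for unequal n), Kruskal–Wallis from mid-ranks with the
Σ(t³−t) tie correction — with SciPy used only for the F, χ² and
studentized-range distribution functions.  Degenerate inputs are explicit:
zero within-group variance with unequal means reports F = ∞, p = 0; a
fully tied sample makes H undefined and raises.  PCA centers but does not
scale columns (features share a scale after length normalization; a
`scale` switch exists), uses SVD, orders components by variance, and fixes
signs so the largest-magnitude loading entry of each component is
positive.  Group separation in PC space is assessed by a permutation test
on the distance between group centroids in the first two score columns.

## Secondary-metabolism census

The ledger unit is the SM core gene with a fine class from a closed
vocabulary (NRPS, NRPS-like, PKS, PKS-like, NRPS–PKS hybrid, TC, DMAT);
prediction tables from two sources merge by union, with class conflicts
resolved in favor of the antiSMASH-style table and logged.  Counts pool
NRPS with NRPS-like and PKS with PKS-like only at presentation.  The
transfer cross-tabulation reports n/m with percentages always recomputed
from the counts; the packaged census tables for the three *Basidiobolus*
isolates contain two printed cells whose percentage or total disagrees
with the per-gene roster, and the roster counts are treated as
authoritative throughout.

Clade placement takes a supplied tree (no inference), roots it at the
given outgroup, and assigns each query tip to the smallest named clade
whose reference-tip MRCA contains it, or "unassigned".  Reference sets
must be pairwise disjoint with ≥ 2 tips; assignment is invariant to tip
order and to rerooting along the outgroup edge.  TPM uses annotated
transcript length as effective length (count-level inputs; no
fragment-length correction): TPMg = 10⁶ · (cg/lg) / Σ(c/l).  The
expression flag marks SM genes reaching the minimum TPM of the supplied
housekeeping set.

## Plate-assay quantification

Siderophore activity is the yellow area of a CAS plate in cm².  The dish
is detected as the largest bright, near-circular connected region and its
equivalent diameter mapped to the known physical diameter (default
5.5 cm), which makes the measurement invariant to uniform image rescaling.
Yellow is an HSV band — hue 40–70°, saturation ≥ 0.25 by default — exposed
as parameters because the assay literature specifies only "yellow";
the defaults separate the Fe–CAS teal (hue ≈ 186°) from the iron-stripped
yellow (hue ≈ 50°) with a wide margin.  Strain comparison reuses the ANOVA
and Tukey implementations.

## The synthetic generator

The generator emulates the study conditions, not a particular genome:
multi-scaffold assemblies whose genes carry a truth label (fungal / hgt /
contaminant), with sequence, structure, depth, homology and SM-label
emitters that are each bit-deterministic under the seed.

* **Base composition.** CDS are drawn codon-wise from stop-free codon
  tables parameterized by a per-gene GC target; the stop-exclusion bias is
  inverted by a precomputed calibration curve so realized GC hits the
  target in expectation (calibration error < 10⁻⁴).  Group means default
  to 0.4865 (fungal), 0.4911 (transferred) and 0.488 (neighbors).
  Per-gene GC is drawn Normal(group mean, `gc_sd`) with `gc_sd` = 0.08:
  binomial base sampling alone (SD ≈ 0.017 at typical CDS lengths) would
  make the ~0.005 group differences detectable in any pairwise contrast at
  the cohort sizes used, whereas real genomes show broad between-gene GC
  dispersion; 0.08 is the value at which a three-group Tukey test at 5000
  genes per cohort distinguishes the transferred-vs-genome contrast but
  not the transferred-vs-neighbor one, the qualitative pattern the screen
  is meant to corroborate.  Because the two mean gaps (0.0046 and 0.0031)
  are close, that pattern is intrinsically marginal at these sizes and
  seed-dependent; tests assert it at the suite's fixed seed.
* **Codon regimes.** A fixed codon-preference tilt vector, scaled by
  `composition_separation`, applies to transferred genes only.  At 0 (the
  default) the groups differ only through GC — the non-separable regime in
  which 5-mer/codon PCA shows no centroid separation; positive values give
  a separable regime for power checks.
* **Intron model.** Zero-inflated Poisson with rates fixed at λ = 3.0
  (fungal) and λ = 1.5 (transferred) and the inflation mass solved from
  the configured intronless fractions (0.36 / 0.61), which yields medians
  2 and 0.  Intron lengths are 50 + Geometric(1/50) nt; exon boundaries
  are uniform cuts of the CDS.
* **Coverage.** Per-base Poisson at `mean_depth` (default 50×);
  contaminant scaffolds are scaled by `contaminant_depth_multiplier`
  (default 4×) and a configurable count of transferred genes gets locally
  scaled depth (default multiplier 5×) to plant z-filter failures.
* **Homology.** Fungal genes receive 1–3 fungal hits, transferred and
  contaminant genes bacterial-only hits from their planted donor (default
  donor weights 0.45/0.20/0.20/0.15 over Proteobacteria, Firmicutes,
  Actinobacteria, Bacteroidetes); all E-values fall below the screening
  cutoff.  A `noise_fraction` of fungal genes additionally receives
  bacterial hits, which the fungal veto absorbs.
* **Plates.** Teal dish, centered yellow disk of the requested radius,
  Gaussian speckle (σ = 5 grey levels), dish diameter 5.5 cm.

What the generator does **not** emulate: read-level data (depth is drawn,
not mapped), homology score structure (E-values are uniform in log space,
not alignment-derived), paralogy and gene families, GC isochores or
strand asymmetry, and assembly chimerism beyond block-scaled depth.
Passing tests therefore demonstrate the correctness and calibration of the
screen's logic and statistics under the stated generative model, not its
sensitivity or specificity on real assemblies.

## Problem sizes and numerical choices

Default simulated genomes are 10 scaffolds × 20 genes (200 genes, CDS
100–500 codons); calibration cohorts use 5000 genes per group for the GC
and intron contrasts and 300 per group for the 5-mer PCA permutation test
(999 permutations).  The ANOVA type-I calibration uses 1000 replicates of
three null groups of 10.  Plate images default to 40 px/cm (100 px/cm
where the analytic-disk comparison is made; measured area is then within
2% of πr²).  Tukey p-values come from SciPy's studentized-range CDF
(documented accuracy well below the 10⁻⁶ reported precision).  PCA
reconstruction is exact to < 10⁻⁸ by construction of the SVD.

## Known limitations

* The context filter keys on calls, not distances; a transfer on a short
  scaffold whose only neighbors are other transfers is removed.
* The coverage filter assumes one depth regime per scaffold; it has no
  window-level model.
* Clade assignment requires the outgroup to be monophyletic in the input
  tree and at least one reference clade per named group.
* Dish detection assumes one plate per image against a dark background;
  concatenated multi-plate sheets must be split upstream.
* The census treats gene identifiers as globally unique across a run;
  colliding IDs between genomes must be prefixed by the caller.
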