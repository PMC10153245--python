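# Methods

This note documents the models, algorithms, and numerical choices behind
`lysoscape`, and what the synthetic cohorts do and do not establish about
real data.

## The detection model

The detector treats prophage discovery as ORF-level classification over
compositional features, followed by region assembly and verification.

**Features.** For every protein-coding feature (GenBank CDS when present,
otherwise ORFs called as maximal ATG→stop frames ≥ 90 bp on both strands),
five statistics are computed over a window of up to 30 ORFs centred on it
and truncated at contig ends:

- *median ORF length* (bp) — phage genes are short and densely packed;
- *same-strand run fraction* — the longest single-strand run in the window
  divided by the window length; phage cassettes are transcribed
  predominantly from one strand;
- *phage k-mer score* — the window mean of the per-ORF fraction of k-mer
  positions (k = 12) found in a marker vocabulary; this stands in for a
  "phage-like word" signal learned from phage gene databases;
- *GC-skew and AT-skew deviation* — window means of the per-ORF skews
  (G−C)/(G+C), (A−T)/(A+T) minus the whole-genome baseline; spans with no
  G+C (or A+T) content are assigned skew 0.

A 500-tree random forest (scikit-learn, fixed `random_state`) is trained on
these five features with labels from simulator ground truth (an ORF is
"phage" when its midpoint lies inside a planted cassette). The decision
threshold defaults to 0.5 on the forest's class probability; raising it can
only shrink the kept prophage DNA, which is tested as a monotonicity
property. The thread count never affects predictions.

**Region assembly.** Maximal runs of phage-predicted ORFs become candidate
regions; up to 2 consecutive host-predicted ORFs are tolerated inside a run
(prophages carry non-viral cargo), and runs are trimmed to phage-predicted
ORFs at both ends. Runs with fewer than 5 phage-predicted genes are
reported but discarded (`too_few_genes`).

**Boundary refinement.** Within ±2,000 bp of each predicted boundary the
two flank windows are searched (seed-and-extend, exact matches only) for
the longest direct-repeat pair ≥ 10 bp with one copy per window — the
attL/attR scar of integration. The longest pair wins; equal lengths are
broken by the smallest total boundary displacement, then by position for
determinism. Boundaries snap to the outer edges of the two copies. Note a
consequence of exact-match search over 4 kbp windows: a chance 12-mer
repeat appears in such window pairs with probability near one, so a
planted 12 bp att pair is *usually but not always* the winner; on synthetic
cohorts roughly two thirds of recovered regions snap exactly, and the rest
land within the flank window. Region-level recovery is therefore scored at
50% reciprocal overlap.

**Verification.** A candidate is kept only if it retains ≥ 5 genes and
shows phage evidence: ≥ 1 ORF whose annotation contains a phage token
(`phage`, `prophage`, `integrase`, `capsid`, `tail`, `terminase`, `portal`;
configurable), or ≥ 1 hit from the hit provider. The provider is pluggable:
the reference implementation looks ORFs up against the marker k-mer
vocabulary (≥ 2 marker positions = hit); an adapter scans translated ORFs
against user-supplied profile HMMs with an E-value threshold (default
1e-5). `verified_bp_fraction` is the fraction of region bp covered by ORFs
with hits. Discarded candidates are always reported with their reason.

## The synthetic cohort generator

The generator produces cohorts with exactly the contrasts the detector
uses, plus ground truth, so recovery can be scored without real data.

- **Backbone**: i.i.d. sequence at a target GC (default 0.50), with
  host-like CDS blocks — gene lengths ~N(900, 150²) bp (≥ 300), intergenic
  gaps ~N(120, 40²), strands alternating in blocks of 3–7 genes.
- **Prophage cassettes**: genes ~N(600, 100²) bp with 90% on a common
  strand; base composition skewed (GC skew +0.25, AT skew −0.20 relative
  to the backbone); marker 12-mers substituted at one per 150 bp on
  average; an exact direct repeat (12 bp) at both ends. A configurable
  fraction of phage genes (default 25%) carries a phage-token product
  annotation.
- **Lengths**: log-normal, parameterised by (mode, sd) per mixture
  component — single component with mode 20 kbp and sd 8 kbp by default,
  giving the characteristic tailed decay past the peak; per-taxon mixtures
  are expressed as weighted components. Draws are clipped to
  [4 kbp, 150 kbp].
- **Planting**: cassettes are inserted at intergenic gap midpoints of the
  largest contig, ≥ 2.5 kbp from contig edges and ≥ 5 kbp apart, until the
  planted total is within ±15% of `target_density × host bp` (target
  density 2.4% by default; the contract is ±20%). Density is defined as
  prophage bp per host bp with prophages excluded from the denominator, so
  the backbone length is the denominator by construction.
- **Cohort structure**: lysogeny is Bernoulli(0.94) per genome; genome
  lengths are N(2.3 Mbp, 0.2 Mbp²) or uniform over a configurable range;
  metadata rows mimic the PATRIC/GTDB fields (ISO isolation date, country,
  rank-prefixed lineage, MAG flag).
- **MAG degradation**: each planted prophage is excised with probability
  2/3 (configurable) and the contig is split at the excision point,
  emulating binning pipelines that drop phage-like contigs; ground truth is
  updated. This makes the expected MAG density (1 − loss) × the isolate
  density, which is what the MAG-effect analyses recover.
- **Marker vocabulary**: 256 random 12-mers drawn from a dedicated
  `marker_seed` (default shared across cohorts). It plays the role of a
  shared phage-gene database: a detector trained on one cohort can verify
  regions in another only because both plant words from the same
  vocabulary.

All randomness flows from the spec seed through spawned `numpy`
SeedSequences (layout, planting, sequence realisation, and MAG loss use
separate streams), so runs are bit-identical and coordinate-only cohorts
(`sequences=False`) share their ground truth with fully realised ones.

**What passing tests do not show.** The generator has no codon structure,
no real phage genes, no transposon decay of prophages, no shared ancestry
between cassettes, and its backbone is compositionally homogeneous. Detector
performance on these cohorts measures the machinery (windowing, forest,
assembly, refinement, verification), not expected accuracy on real
assemblies, where prophage/host contrast is weaker and degraded elements
blur boundaries.

## Statistics

- **Density and binning**: per-genome summaries carry
  `density = prophage_bp / genome_bp` (host bp excluding prophages; the
  denominator counts only contigs retained by the assembly filter, i.e. the
  universe the detector saw). Genome-size bins are left-closed right-open
  from 0 to 1.2 × 10⁷ bp in 1.4 × 10⁶ bp steps; since the range is not a
  whole multiple of the step, the final bin is truncated at the maximum and
  genomes at or beyond it are excluded with a logged count. Binned means
  are computed over lysogens only by default.
- **Dip test**: the dip statistic is the minimum sup-distance between the
  empirical CDF and any unimodal CDF, computed exactly by the iterative
  modal-interval algorithm (greatest convex minorant / least concave
  majorant with pooled slopes). It satisfies dip ≥ 1/(2n), with equality
  for perfectly unimodal samples. The p-value is Monte-Carlo: the
  proportion of dips from `n_boot` (default 2,000) uniform(0,1) samples of
  the same size exceeding the observed dip; uniform is the asymptotically
  least-favourable unimodal null. Samples beyond 80,000 values are
  subsampled. The test suite verifies the statistic against an in-repo
  exhaustive oracle that solves the defining minimisation as linear
  programs over unimodal CDF values (one LP per modal placement, including
  jumps at the mode), with 100 frozen oracle values at n ≤ 200 checked to
  1e-9 and live LP runs at small n. Type-I calibration over many replicates
  of a common sample size reuses one simulated null table — the null
  distribution depends only on n — which keeps the 500-replicate
  calibration tractable.
- **KDE**: Gaussian kernel with Scott's rule by default (the bandwidth rule
  is configurable); the grid pads the sample range by six bandwidths so the
  estimate integrates to 1 within 1e-3; the reported mode is the grid
  argmax.
- **Regressions and comparisons**: OLS with a two-sided slope test
  (`scipy.stats.linregress`) for time trends and verified-fraction
  analyses; two-sided Mann–Whitney U for MAG vs isolate density.
- **Dates**: isolation dates normalise to decimal years as
  `year + (day_of_year − 1)/365`; bare years map to mid-year (+0.5) and
  year-month strings to the 15th — unbiased within the stated granularity.
  Parsing is total (unparseable → missing) and idempotent on its own
  rendered output.
- **Dereplication**: one genome per GTDB species label, chosen uniformly
  under a seed; genomes with missing species are excluded.

## Energetics

The model assumes maintenance cost is proportional to the DNA replicated,
so prophages at density *d* consume a fraction *d* of the maintenance
budget: `prophage_atp_per_hr = maintenance × d` and
`atp_per_bp_per_hr = maintenance × d / genome_bp`. With the defaults
(0.2 × 10⁹ ATP hr⁻¹, d = 0.024, 5.1 × 10⁶ bp) the per-bp figure is
4.8 × 10⁶ / 5.1 × 10⁶ ≈ 0.94. An often-quoted intermediate value of
6.6 × 10⁶ ATP hr⁻¹ is inconsistent with these inputs (0.2 × 10⁹ × 0.024 =
4.8 × 10⁶) while the final 0.94 is not; the implementation computes
strictly from the formula. The per-bp rate divides by the *total* genome
length, i.e. it is a cost per genomic base pair, not per prophage base
pair. Transcription and translation costs are outside the model.

## Problem sizes and design choices

The shipped analyses use cohort sizes chosen to make the statistical
contracts sharp at small compute: 4 training genomes (~9,000 ORFs) for the
forest; 50 genomes (~2.3 Mbp each) for detector recovery scored at 50%
reciprocal overlap; 200 coordinate-only lysogens spanning 2–10 Mbp for the
density-uniformity recovery; 400 coordinate-only genomes for the MAG
effect, where the ±20% band on the 1/3 density ratio is then a ≥ 4-sd
margin; 500 replicates at n = 100 for dip type-I calibration and n = 1,000
for power. Coordinate-only mode exists precisely so the distributional
analyses need not pay for sequence realisation.

Known limitations: the detector's five-feature reconstruction fixes the
window aggregation (median/mean/longest-run) that upstream tools leave
unspecified; the marker-score is a transparent stand-in for learned
phage-word models; att search is exact-match only, so diverged repeats are
not found; and insertion sites are restricted to intergenic gaps of the
largest contig, which real integrases do not respect.
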