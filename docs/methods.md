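# Methods

This note records the models, conventions and numerical choices behind
`rabmab`, and what the synthetic validation does and does not demonstrate
about real screening data.

## Repertoire annotation

**Germline assignment.** Each query chain is globally aligned to every
reference of its chain class (Needleman–Wunsch via Biopython's
`PairwiseAligner`; match +1, mismatch −1, gap open −5, gap extend −1, all
configurable).  The winning reference minimizes the *replacement count* —
the number of aligned columns with differing residues — rather than the
alignment score, because replacement counting is the downstream statistic.
Ties break deterministically by reference order.  A brute-force Hamming
argmin over all references serves as the oracle in tests for ungapped
queries.

**Region delineation.** There is no community-unique CDR definition for
rabbit V domains, and numbering servers are not reproducible dependencies,
so regions are derived from sequence anchors: CDR3 is the stretch strictly
between the last cysteine preceding the J motif and the first J-motif
residue (`W` of `W-G-x-G` for heavy chains, `F` of `F-G-x-G` for kappa);
FR4 is the J motif onward.  CDR1/CDR2 are fixed Kabat-style intervals on
the germline (heavy [25, 35) and [49, 65); kappa [23, 34) and [49, 56),
0-based half-open) mapped onto the query through the alignment.  These
boundaries are a documented stand-in for whichever scheme a given lab's
annotation workbook uses; all coordinates are 0-based half-open
internally.  Sequences missing an anchor are flagged as annotation
failures and retained in the dataset but excluded from region statistics.

**Replacement counting.** Only substitutions count; alignment columns
containing an indel are skipped, because "replacement mutations" are
substitutions by definition.  FR4 is excluded (J-encoded).  CDR3 is also
excluded by default: the CDR3 junction is created by V(D)J recombination
rather than inherited from the germline V segment, so differences there
are not somatic replacements.  A comparison against the germline's own
CDR3 stretch can be enabled with `include_cdr3=True` where a
whole-domain count is wanted.  On synthetic repertoires the default
convention recovers the generator's planted replacement counts exactly.

## Clonotype clustering

Two clones are linked when both CDR-H3s and both CDR-L3s have equal
length and each chain differs by at most `threshold` (default 2)
replacements.  Cross-length similarity is deliberately excluded — a length
difference is an indel, not a replacement.  Clusters are connected
components of this relation (single linkage), chosen because clonotype
membership is defined by relatedness to *some* cluster member; a stricter
complete-linkage variant is available.  Percent-unique figures use
half-up integer rounding; funnel percentages use half-up 1-decimal
rounding.  Published per-animal tables occasionally mix rounding
conventions; this package documents and applies its own rule rather than
reverse-engineering any particular spreadsheet.

## Screening-funnel calibration

Thresholds are calibrated per assay channel in three steps:

1. **Outlier trimming.** Remove points above `median + k·MAD·1.4826`
   (default k = 6), re-evaluate once on the retained sample.  The rule is
   intentionally blunt — it is meant to strip the "obviously sticking out"
   positives before distribution fitting — and the removed indices are
   returned for audit.  A zero MAD (constant input) disables trimming.
2. **Johnson SU fit.** The four-parameter Johnson SU family
   (X = ξ + λ·sinh((Z−γ)/δ), δ, λ > 0) is fitted by maximum likelihood,
   started from the quantile-matching construction of Slifker & Shapiro.
   Because step 1 removes *every* point above some bound, the retained
   sample is upper-truncated; the likelihood therefore includes the
   truncation term n·log F(c) with c the smallest removed value.  Without
   this term the fitted 99% quantile is biased low by ~3% on heavy-tailed
   backgrounds; with it, recovery on pure background is within 0.5% at
   n = 10⁵, and within ~2% of the true quantile when 5% strong positives
   are spiked in (they are trimmed in step 1).
3. **Threshold.** The fitted 99% quantile,
   ξ + λ·sinh((z₀.₉₉−γ)/δ).  A sorted-sample plot with the threshold line
   is exportable; on well-behaved screens the threshold sits at the sharp
   kink where background gives way to binders.

The funnel applies ordered gates with fixed denominators: IgG positivity
(fraction of all wells), Fc-counterscreen binding and antigen binding
(fractions of IgG-positive wells; Fc binders are excluded from the binder
set), cross-species binding (human binders also clearing the cyno/murine
cut-offs), and biochemical inhibition (fraction of human binders).  Every
percentage is emitted with its numerator and denominator.  Gate counts are
monotone non-increasing along the main funnel path by construction.
Inhibition values are stored unclipped; the ≥40% rule is applied at gate
time.  Four-parameter IC50 fitting is out of scope (standard curve-fitting
software handles it).

## Epitope binning

Competition matrices are oriented rows = first (captured) antibody.  Rows
are normalized to [0, 1] by their no-competition reference (row maximum by
default, or an explicit control column); low values mean competition.

Ward's minimum-variance clustering is implemented via the Lance–Williams
recurrence on squared Euclidean distances between row profiles, with the
height convention h(i,j) = √(2·nᵢnⱼ/(nᵢ+nⱼ))·‖cᵢ−cⱼ‖ (for two singletons,
the plain Euclidean distance).  Merge ties break by smallest original leaf
index.  The implementation is verified against (a) a brute-force
implementation that recomputes the Ward objective from raw points at every
step and (b) scipy's `linkage(method="ward")`.

The group count automates manual dendrogram inspection: cut at the largest
relative gap (h[m+1]−h[m])/h[m] between successive merge heights; when no
positive gap exists (all heights equal) the convention is k = 1; a manual
override is accepted.  PCA of the row profiles (first three components)
provides a visual/quantitative confirmation via a between/within centroid
separation score, and clustering the transposed matrix (columns instead of
rows) gives an adjusted-Rand agreement diagnostic.  Ordered pairs whose
two orientations differ by more than 0.3 on the normalized scale are
flagged as asymmetric binders, oriented so the competing direction comes
first.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analyses assume,
with ground-truth labels carried alongside every record:

* **Repertoires** — 227 clones from 3 animals over 4 bleeds by default.
  CDR3 lengths follow a truncated discrete Gaussian on 4–19 with mean 11.4
  and sd 2.7; somatic replacements are Poisson (mean 13 per V region)
  placed uniformly over non-anchor, non-CDR3 positions; a quarter of
  clones sit in shared-clonotype lineages of 2–5 members that share
  germline and animal and differ by ≤2 CDR3 replacements per chain from
  their founder.  Residue pools exclude cysteine and the chain's J-motif
  residue so every sequence is annotatable, and anchor motifs occur
  exactly once.
* **Panels** — Johnson SU optical-density background (γ=−1.5, δ=1.8,
  ξ=0.04, λ=0.02; 99% quantile ≈ 0.12 OD, the range where real calibrated
  cut-offs fall), log-normal IgG concentrations, planted binder /
  cross-reactive / Fc-binder / inhibitor subsets at campaign-realistic
  rates, ODs clipped at zero.
* **Competition matrices** — 16 antibodies in 6 planted groups by default;
  same-group ordered pairs draw around a low within-signal, different-group
  pairs around a high between-signal, with Gaussian noise and optional
  one-directional asymmetric overrides.

Deliberate simplifications: no per-position mutability profile (real
somatic hypermutation is hot-spot driven; no published profile was
available to emulate), no nucleotide-level simulation, codon structure,
insertions/deletions within CDR3 lineages, sequencing error, or
plate/batch effects.  Consequently, passing tests demonstrate that the
*algorithms* are correct under their stated assumptions — e.g. that
clustering recovers planted clonotypes, or that calibration recovers a
known quantile — not that those assumptions hold for any particular real
screen.  Raw screening data from real campaigns are not redistributable,
so OD-level published figures (average IgG concentrations, the specific
calibrated cut-off values, specific correlation coefficients, a specific
16-antibody grouping) are validated by these parameter-recovery properties
rather than re-derived number for number.

## Numerical conventions and edge cases

* Population (n-denominator) standard deviations by default; sample sd via
  `ddof=1`.  Strata with n < 2 report sd as undefined (`nd`).
* Hydropathy uses the Kyte–Doolittle scale (the field default when none is
  specified); the scale is a replaceable table.
* Goodness of fit of generated CDR3 lengths against the configured law is
  tested by chi-square over well-populated cells (the length law is
  discrete, where a Kolmogorov–Smirnov test would be invalid).
* All generators and the pipeline funnel their randomness through one
  seeded NumPy generator per call; identical configs give bit-identical
  outputs, and campaign runs record a config hash and seed in
  `provenance.json`.
* Problem sizes in the test suite and acceptance script (10⁵ draws for
  calibration recovery, 20 planted matrices for binning recovery, 50×227
  clones for length statistics) were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably below the tolerance being checked.

## Known limitations

* CDR1/CDR2 boundaries are scheme-approximate; absolute per-region counts
  depend on the chosen intervals even though totals are stable.
* The clonotype definition ignores indels within CDR3; a lineage that
  gained or lost a residue would be split.
* The gap rule for the epitope group count assumes one dominant scale
  separation; gradated competition landscapes may need the manual
  override.
* `remove_outliers` trims only the upper tail; assays where positives are
  *low* signals (competition formats) must be sign-flipped before
  calibration.
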