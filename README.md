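# rabmab

Analytics for rabbit B-cell monoclonal-antibody discovery campaigns.

High-throughput B-cell cloning platforms sort single antigen-specific B
cells from the peripheral blood of immunized rabbits, culture them, and
screen each culture supernatant in a battery of plate assays before the
cognate VH/VL pair is amplified, cloned and re-expressed.  `rabmab`
implements the computational layer of such a campaign for the scientists
who run it:

* **Repertoire annotation** — assign each VH/VL amino-acid sequence to its
  closest germline V reference (e.g. the rabbit heavy-chain allotypes
  VH1a1/VH1a3) by global alignment, delineate framework and CDR regions
  from the conserved anchors (the framework-3 cysteine and the J motifs
  `W-G-x-G` / `F-G-x-G`), and count somatic replacement mutations per
  region.
* **Clonotype diversity** — cluster clones whose CDR-H3 *and* CDR-L3 each
  differ by at most 2 replacements (single-linkage closure), split the
  repertoire into unique vs clustered antibodies, and tabulate diversity
  per animal and bleed.
* **Screening-funnel gating** — calibrate per-assay positivity cut-offs by
  upper-tail outlier trimming followed by a maximum-likelihood Johnson SU
  fit, X = ξ + λ·sinh((Z−γ)/δ), whose 99% quantile is the threshold; then
  run the ordered gates (IgG⁺ → Fc counterscreen → human/cyno/murine
  binding → inhibition) and report counts with exact percentages.
* **Epitope binning** — normalize a pairwise cross-competition ELISA
  matrix, cluster competition profiles with Ward's minimum-variance method
  (Lance–Williams recurrence), pick the group count at the largest relative
  merge-height gap, confirm by PCA, and flag asymmetric binders.
* **Synthetic campaigns** — generators for repertoires, plate panels and
  competition matrices with ground-truth labels, so every stage can be
  validated end to end without access to screening data.

## Worked example

```python
import dataclasses
from rabmab import (
    CompetitionSimConfig, PanelSimConfig, RepertoireSimConfig,
    annotate_repertoire, apply_funnel, bin_epitopes, calibrate_threshold,
    cluster_clonotypes, generate_competition, generate_germline_set,
    generate_panel, generate_repertoire,
)
from rabmab.funnel import FunnelConfig
from rabmab.repstats import cdr3_length_stats, replacement_stats

germlines = generate_germline_set(seed=1)
repertoire = generate_repertoire(RepertoireSimConfig(n_clones=227, seed=1), germlines)
clones = annotate_repertoire(repertoire.to_dict("records"), germlines)

lengths = cdr3_length_stats(clones)["overall"]
repl = replacement_stats(clones)["overall"]
print(f"CDR-H3 length: {lengths.mean:.1f} +/- {lengths.sd:.1f}")
print(f"VH replacements: {repl.mean:.1f} +/- {repl.sd:.1f}")

clustering = cluster_clonotypes(clones, threshold=2)
print(f"unique clones: {100 * len(clustering.unique_ids) / len(clones):.0f}%")

panel = generate_panel(PanelSimConfig(n_wells=20000, seed=2))
cal = calibrate_threshold(panel["od_hu"].to_numpy())
report = apply_funnel(panel, dataclasses.replace(FunnelConfig(), hu_pos=cal.threshold))
print(f"threshold {cal.threshold:.3f}")
print(report.to_text())

matrix, truth = generate_competition(CompetitionSimConfig(seed=3, noise_sd=0.15))
print(f"epitope groups: {bin_epitopes(matrix).k}")
```

prints

```
CDR-H3 length: 11.7 +/- 2.5
VH replacements: 13.3 +/- 3.6
unique clones: 75%
threshold 0.121
Screening funnel
----------------------------------------------------------------
total wells: 20000
igg_positive     2583  (12.9% of total_wells)
fc_binders        389  (15.1% of igg_positive)
hu_binders        480  (18.6% of igg_positive)
cyno_binders      404  (15.6% of igg_positive)
mu_binders        119  (4.6% of igg_positive)
inhibitors         67  (14.0% of hu_binders)
pcr_eligible     2560  (99.1% of igg_positive)
avg IgG over IgG-positive wells: 0.462 ug/ml
epitope groups: 6
```

The simulated repertoire reproduces the hallmarks of a real campaign:
CDR-H3 lengths around 11.4±2.7 residues, about 13 heavy-chain replacement
mutations per clone, roughly three quarters of clones carrying unique
CDR3 pairs, a calibrated optical-density cut-off near 0.12, and six
recoverable epitope groups among 16 competing antibodies.

A `rabmab` console script exposes the same stages as subcommands
(`simulate`, `annotate`, `clonotype`, `stats`, `calibrate`, `funnel`,
`correlate`, `epibin`, `campaign`); `rabmab campaign --config campaign.yaml`
runs the full pipeline and writes every report with a provenance record.

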