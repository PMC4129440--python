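# Methods

## The problem

In a disomic yeast strain, every gene on the duplicated chromosome is
present in two copies instead of one, so the neutral expectation for its
transcript and protein is a log2 ratio (disome / wild type) of 1.0.
Dosage compensation shows up as proteins falling well below that
expectation while their mRNA does not. The package quantifies this at four
levels: single measurements (attenuation calls), the whole distribution
(two-Gaussian decomposition), complexes (subunit summaries and
enrichment), and shared strain-level responses (signatures).

## Peptide-to-protein quantification

SILAC peptides are kept when both heavy and light signal-to-noise are
≥ 2, or when either channel reaches ≥ 5; a protein's log2 ratio is the
median of its peptides' log2(H/L) ratios. (Whether the median is taken on
the ratio or the log-ratio scale only matters for even peptide counts; we
use log ratios.) TMT reporter intensities are multiplied by the MS3 ion
accumulation time (undoing the instrument's normalization), corrected for
reporter-channel isotopic overlap by solving the impurity linear system
(default impurity matrix: identity, since empirical values are
instrument-specific; a 6×6 TSV can be supplied), and filtered to
denormalized intensity ≥ 20 in the reference/zero-timepoint channel and in
at least four of six channels. Protein TMT ratios are
log2(Σ numerator / Σ denominator) over peptides — an intensity-weighted
average, so bright peptides dominate dim noisy ones. Rollup is invariant
to rescaling all of a protein's intensities.

Matrices are normalized per strain by subtracting the median log2 ratio of
genes *not* on that strain's duplicated chromosome (most proteins sit at
1:1; duplicated genes are genuinely elevated and would bias the factor).
The median is used rather than the mean for robustness to signature tails.
The operation is idempotent and equivariant under global shifts; wild-type
control columns are centered on all genes.

## Distribution fits

Log2 ratios are binned at 0.1 log2 units over [−2, 3] (extended when data
fall outside) into relative frequencies, and fit by nonlinear least
squares to a Gaussian-mixture density scaled by the bin width:
`bw·[p·N(μ₁,σ) + (1−p)·N(μ₂,σ)]`. Two numerical choices matter:

- **Area normalization.** Fitting the mixing fraction p instead of two
  free amplitudes forces the curve to integrate to the total probability
  mass. With free amplitudes the low component of an overlapping mixture
  (separation ~2 SD) can trade amplitude against location, which biased
  recovered means by up to +0.05 with RMSE ≈ 0.09 in simulation; the
  normalized form is unbiased with RMSE ≈ 0.02 at n ≈ 2,600.
- **Shared component SD (default).** With unconstrained SDs the
  two-component histogram fit is weakly identifiable at the separations
  seen in this problem (means ~0.5 apart, SD ~0.25). Both dosage
  populations are measured by the same platform, so a common σ is the
  natural default; `equal_sd=False` restores the unconstrained fit.

Fits use 8 multistarts (means seeded at the 0.25/0.75 data quantiles with
deterministic jitter; best residual sum of squares wins) under bounds, and
report R² over bin heights and Pearson mode skewness (median − mean)/SD
(sample SD, n−1). Model comparison prefers two components only when
ΔR² ≥ 0.005 *and* the component means are ≥ 1 pooled SD apart, ties going
to one component. The ΔR² threshold separates the measured gain of a
second component on unimodal Gaussian samples (< 0.002, pure overfitting)
from its gain on genuinely bimodal dosage data (> 0.01); 0.005 is the
log-midpoint. An EM mixture fit (scikit-learn) serves as an independent
cross-check in the tests, never as the implementation.

## Attenuation calls

A duplicated gene is attenuated when its log2 ratio ≤ reference − 0.6,
boundary inclusive. The reference is the fixed expectation 1.0 (cutoff 0.6
≈ 3 wild-type/wild-type SDs of 0.2), or per-strain the observed mean of
that strain's duplicated genes — the form needed for strains whose overall
dosage response deviates from twofold. Calls are monotone in the cutoff
and invariant under strain renaming. Missing values are excluded, never
imputed. Note the single-measurement sensitivity ceiling: if attenuated
proteins sit at N(0.46, 0.2), no caller thresholding at 0.4 can exceed
sensitivity Φ(−0.3) ≈ 0.38, although specificity is ≈ 0.999; calling is
reliable in aggregate (distribution fits, enrichment), not per gene.

## Complex analysis

Enrichment of a gene set among attenuated genes is the upper-tail
hypergeometric probability with the background equal to duplicated genes
actually measured in the dataset (not the genome). A gene in several
complexes contributes to each complex's summary but counts once in
enrichment sets. Per complex, each subunit contributes the measurement
from the strain where its gene is duplicated (the mean across strains if
duplicated in several); complexes need ≥ 3 quantified subunits in every
dataset considered. A complex is attenuated when the subunit mean is
≤ 0.6; subunits themselves partition at the same cutoff into attenuated
and stable.

## Signatures

Weighted Pearson correlation uses weighted means and variances, with the
pair weight for two gene rows being the product of their per-strain
weights; binary weights reduce it exactly to Pearson on the retained
subset. Gene rows are clustered agglomeratively (average linkage by
default; the linkage is configurable since the reference implementation's
internals are unspecified) on distance 1 − r, after zeroing the weights of
each strain's duplicated-chromosome measurements — otherwise the dominant
cluster is the trivial "own chromosome up twofold" block. Undefined
correlations (no shared weight, zero variance) get distance 1.

The consistently-up signature has two extraction modes, both documented
approximations to a visual cluster selection: *threshold* (default) keeps
genes whose weighted measurements exceed 0 in every strain and whose
weighted mean is ≥ 0.2 — the mean floor is what keeps the expected null
count below one gene per study at 4,800 genes and noise SD 0.2; *cluster*
picks the dendrogram node (size ≥ 10) maximizing the minimum per-strain
cluster mean. Projections of fixed gene sets report per-strain mean and
SEM over measured genes and are linear in the matrix. Signature intensity
is correlated against the size of each strain's duplicated chromosome —
bp length when provided, else gene count (only monotonicity of the size
measure matters).

For matched strain pairs, genes are binned on the first matrix at
log2 ±0.4 into up / down / unchanged, and each bin compared by a paired t
test over shared genes (paired, because the two measurements of a gene in
disome and disome-*ubp6Δ* are matched). Turnover slopes are per-gene least
squares of log2 ratio against time over the 0/90/300 s inhibition
timecourse, with pairwise-complete fallback for missing cells; the default
planted slope of 4.8e-4 log2/s corresponds to ~+10% protein in 300 s.

## Synthetic data: the stated world

The generator emulates the deposited study structure so every stage runs
offline with known truth. Defaults are the studied conditions, not knobs:

- 4,800 genes on 16 chromosomes whose sizes span a ~3-fold range; 33% of
  genes in disjoint complexes of 2–80 subunits including one 79-member
  ribosome-like complex; 12 disomes (chromosomes 1, 2, 5, 8–16).
- Measurement noise: additive N(0, 0.2) on log2 ratios in the rich-medium
  (TMT-like) condition and N(0, 0.35) in the synthetic-medium (SILAC-like)
  condition — the wild-type/wild-type SDs of the two platforms.
  Peptide-level noise is multiplicative on the intensity scale.
- Duplicated genes at μ = 1.0; attenuated genes at μ = 0.46 (the 1.4-fold
  attenuated complex-subunit population; the frequently quoted ~1.6-fold
  is the blended observable of the whole duplicated set, and planting it
  would make complex-level attenuation unreachable by construction).
- Attenuation is complex-coherent: about half of the complexes are
  attenuated-type (all subunits unstable except one stable scaffold), the
  rest carry exactly one unstable subunit, and the ribosome-like complex
  is fully unstable — reproducing the observed pattern of ~half the
  complexes attenuated, almost all complexes harboring at least one
  unstable subunit, and ribosome/nucleosome lacking stable scaffolds.
  Non-complex genes are attenuated at rate 88/1650 ≈ 0.053, the rate that
  leaves ~88 attenuated non-complex proteins per study (a free parameter
  of the world; nothing downstream is sensitive to it).
- The 92-gene APS is planted in the protein layer only (it is
  posttranscriptional), with per-strain shift = coefficient × duplicated
  chromosome gene count; the coefficient is set so the smallest duplicated
  chromosome yields +0.4. The ESR shifts its up/down sets by +0.4/−0.6 ×
  esr_scale on all layers; esr_scale defaults to 0.3 in rich medium
  (damped ESR) and 1.0 in synthetic medium, where the APS is absent —
  matching where the signature was and was not detectable.
- One integer seed per generator call; sub-streams are derived
  deterministically, so studies are reproducible cell-for-cell.

What the generator does *not* emulate: peptide-level missingness beyond
planted filter violations, correlated (batch) noise, paralog sharing, or
partial-chromosome aneuploidy. A green test therefore establishes
correctness of the estimators under the stated world, not robustness to
those artifacts.

## Known limitations

- The two-component fit reports component means/SDs but no confidence
  intervals; use the EM cross-check pattern from the tests if intervals
  are needed.
- Per-gene attenuation calls at a single measurement are low-sensitivity
  by construction (see above).
- The cluster extraction mode scores only contiguous dendrogram nodes; a
  signature split across two branches is found by the threshold mode but
  not by cluster mode.
- Weighted-correlation distance matrices are computed in O(n²·strains)
  blocks; clustering beyond ~10⁴ gene rows is memory-hungry.
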