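# Methods

`icefp` re-implements, as a tested library, the analysis chain used to ask
whether bacterial and archaeal communities trapped in first-year Arctic
winter sea ice changed over a three-month sampling series: community
fingerprinting (ARISA for *Bacteria*, T-RFLP for *Archaea*) from raw
electropherograms through OTU binning and presence/absence statistics, plus
clone-library phylotype and diversity analysis and the cross-matching of the
two data types. Because raw field traces of this kind are rarely deposited,
the package also contains a forward model (`icefp.synth`) that generates
electropherograms and clone libraries with the latent structure the analysis
assumes, so the entire pipeline can be exercised and calibrated end to end.

## Electropherogram processing (`icefp.trace`)

A trace is a vector of fluorescence values (RFU) at uniform scan indices,
one per dye channel.

* **Low-pass filter.** Hard frequency cutoff via forward/inverse real FFT,
  default 0.1 × Nyquist; the DC component is always kept. A hard cutoff was
  chosen over a smooth window for idempotence (filtering twice equals
  filtering once), which is asserted as a property test. Its Gibbs ringing
  around tall peaks stays far below the peak-calling threshold at realistic
  noise levels.
* **Baseline noise.** RMS by iterative peak masking: points with |signal|
  above 3 × the current RMS estimate are excluded and the RMS re-estimated
  until the mask stabilises (≤ 50 iterations). This is robust while peaks
  occupy a minority of scans, which holds for fingerprints of a few dozen
  fragments over 10⁴–10⁵ scans.
* **Peak calling.** Local maxima with height strictly greater than 5 × the
  baseline RMS (the threshold multiple is configurable); no two apexes
  within one nominal peak width (default 10 scans). Flat-topped runs of ≥ 3
  points within 0.5% of the detector ceiling are flagged saturated, with the
  apex at the plateau midpoint.
* **Saturation recovery.** For saturated peaks, a Gaussian is least-squares
  fitted to the non-clipped flank points (initial centre at the plateau
  midpoint, initial width from the plateau width). The fitted amplitude
  replaces the observed height only if the fit converges and is at least the
  plateau value; otherwise the peak is returned unchanged with a diagnostic.
  At least 5 flank points are required.
* **Size calibration.** Monotone piecewise-linear interpolation between
  internal-ladder anchors, then a constant dye-offset correction (default
  −7 bp for ARISA, reflecting the migration difference between the sample
  and ladder fluorophores; 0 for T-RFLP, where both channels run the same
  chemistry in this design). Peaks outside the anchored range are flagged
  and excluded by default rather than extrapolated.

The observation that baseline noise is below 1.0% of a profile's cumulative
peak height is recorded in the profile metadata as a QC indicator, not
enforced as a filter.

## OTU binning (`icefp.binning`)

Profiles whose cumulative peak height falls below 1 × 10⁴ RFU (ARISA) or
8 × 10⁴ RFU (T-RFLP) are removed (retention uses ≥ at the printed value).
Binning is performed on the pooled peak set across samples — required for
OTUs to be comparable between samples — with size-dependent distance
cut-offs: 1 bp on [70, 700) bp, 2 bp on [700, 1200) bp, 4 bp at ≥ 1200 bp.
Peaks below 70 bp are excluded and logged.

The binning algorithm is deterministic height-ranked greedy seeding: peaks
are visited in order of decreasing height (ties toward the smaller fragment,
then sample id); a peak whose distance to every existing seed is ≥ the
cut-off at its size becomes a new seed; finally every peak joins its nearest
seed (ties toward the smaller seed length). A bin's representative length is
the height-weighted mean of its members; within a sample, member heights are
summed, so total signal is conserved exactly. Whether the published 1/2/4 bp
values are bin widths or maximum intra-bin distances is ambiguous; they are
implemented as a seed radius, and the test suite pins this choice against a
plain-loop reference on ~10³ random instances.

The presence/absence filter retains an OTU column iff its relative height
(fraction of the sample's cumulative height) exceeds 1.0% (ARISA) or 0.25%
(T-RFLP) in at least one sample; within retained columns, any non-zero
height counts as presence. A per-cell thresholding mode is available behind
a config flag (`presence_per_cell`).

## Community statistics (`icefp.commstats`)

* **Sørensen similarity** Cs = 2C/(A+B) on presence sets; undefined (error)
  for two empty sets.
* **Similarity to reference**: Cs of every sample against the first sample
  of the series; the reference's self-similarity is excluded from trend
  tests (it is constant by construction).
* **Trend tests**: Pearson correlation against calendar day with the
  two-sided p-value from the t transform at n−2 df; for richness, the
  first-order partial correlation controlling for the profile's cumulative
  peak height (t transform at n−3 df). Raw cumulative height is used by
  default; `log_covariate=True` switches to its logarithm. α = 0.05
  two-sided throughout. Degenerate inputs (zero variance, |r| with the
  covariate = 1) yield a flagged, non-significant result rather than an
  exception.
* **Group-average clustering**: hand-written UPGMA on the similarity scale
  (merge the pair with the highest mean between-cluster similarity over the
  original coefficients), with ties broken toward the lexicographically
  smallest sample-id pair so the dendrogram is reproducible. scipy's
  average-linkage serves as an independent oracle in the tests, not as the
  implementation, because SIMPROF needs each node's sample set and a fixed
  tie-break.
* **SIMPROF**: at a node with samples S, the observed profile is the sorted
  vector of pairwise similarities within S; the expected profile is the mean
  sorted vector over 999 permutations that shuffle each OTU column
  independently across S; π = Σ|observed − expected|; the p-value is the
  add-one fraction of 999 further permuted π values ≥ the observed π.
  Identical rows give p = 1 by convention. Testing proceeds from the root
  and recurses into a node's children only when that node is significant at
  the 95% confidence level (PRIMER-style). The 999/999 permutation counts
  are PRIMER defaults; the source analysis states only the confidence level.

## Clone libraries (`icefp.clones`)

* **Identity** is fractional identity over alignment columns free of gaps
  and Ns in both sequences; input must be pre-aligned (de-novo alignment is
  out of scope). Identity-based distance is the default wherever a distance
  matrix is accepted; an externally computed evolutionary-distance matrix
  (e.g. from a substitution model) can be passed instead.
* **Phylotypes**: complete-linkage clustering stopped strictly below the
  distance threshold, so ">98% similarity" means pairs at exactly 98% are
  not merged (thresholds: 98% bacteria, 99% archaea).
* **Subtypes**: within a phylotype, members are grouped by predicted
  fingerprint fragment length; groups separated by more than 0.5 bp are
  distinct subtypes.
* **Diversity**: observed richness; Chao1 S_obs + F1²/(2F2), switching to
  the bias-corrected S_obs + F1(F1−1)/(2(F2+1)) only when F2 = 0 (avoids
  division by zero); Shannon H = −Σ p ln p (natural log); Good's coverage
  1 − F1/N.
* **LIBSHUFF**: homologous coverage C_X(D) is the fraction of library-X
  clones with another X clone within distance D; heterologous C_XY(D) uses
  the other library, always excluding the clone itself — so comparing a
  library with itself gives ΔC = Σ_D (C_X − C_XY)² = 0 exactly. The grid
  runs from 0 to the maximum observed distance in steps of 0.01; p-values
  are add-one permutation fractions over label shuffles (999 by default),
  reported in both directions.
* **Fragment prediction**: ARISA length is measured from the labelled
  forward primer's annealing position to the end of the reverse-primer site
  inclusive; T-RFLP length is the distance from the labelled primer's 5'
  end to the first HpyCH4III cut (AC N^GT), found via Biopython's
  restriction machinery; clones without a site are flagged "uncut" at the
  full amplicon length.
* **Dye offset**: the integer shift in [−15, 15] bp maximising the
  covariance between the 1-bp-binned OTU height histogram and the predicted-
  length frequency histogram; ties go to the smaller |shift|, and a flat
  covariance profile is flagged with offset 0. Matching uses corrected OTU
  lengths: ≤ 1 bp is a tight match, ≤ 2.5 bp putative, else unmatched.

## Synthetic data (`icefp.synth`)

The generator plants exactly the structure the analysis is designed to
detect, at the magnitudes the field study reported:

* **Community law.** Core OTUs appear in every sample with mean relative
  abundances on a geometric profile (ratio 0.85) normalised to the core
  signal fraction; transient OTUs appear independently per sample with a
  fixed presence probability. Per-OTU heights carry mean-one lognormal
  multiplicative noise (σ = 0.35). A skewed multiplicative law matches the
  observed dominance of a few taxa; the geometric ratio keeps the smallest
  core OTU (~1.6% of signal) above the 1% ARISA presence threshold, as the
  universal detection of all core OTUs in the real data implies. Transient
  heights are drawn around mean/presence-probability so that mean
  abundances sum to 1 while the expected core share still equals the
  configured fraction.
* **Calibration of the defaults.** With n_c always-present core OTUs and
  n_t transients at presence probability p, the expected Sørensen similarity
  between two samples is (n_c + n_t p²)/(n_c + n_t p). The bacterial ARISA
  design (11 samples, n_c = 14 at 77.5% of signal) uses n_t = 13, p = 0.5,
  giving a planted mean similarity of ~84% and richness ~19–24; the archaeal
  T-RFLP design (21 samples, n_c = 17 at 88%) uses n_t = 20, p = 0.45
  (~81%, richness ~22–30). These solve the closed form for the reported
  values and were fixed before any pipeline run.
* **Forward trace model.** Each OTU is a Gaussian peak (σ = 1 bp at 10
  scans/bp) of amplitude abundance × signal scale (10⁵ RFU for ARISA,
  1.5 × 10⁵ for T-RFLP), centred at the true length plus a +7 bp dye offset
  in the sample channel; the ladder channel renders the size standard
  unshifted. i.i.d. Gaussian baseline noise (RMS 30 RFU) is added and the
  signal clipped at the detector ceiling (65535 RFU for ARISA; 3 × 10⁴ for
  T-RFLP, low enough that the strongest archaeal fragments genuinely clip
  and exercise Gaussian recovery). Scan rate, peak width and noise level are
  free parameters — the instrument's values were never published — and are
  documented defaults in `SynthTraceConfig`.
* **Clone libraries** are multinomial draws from the OTU abundances. Each
  phylotype's gene is the shared ancestor mutated at 5% of sites (pairwise
  identity ≈ 90%, safely below both clustering thresholds); within a
  phylotype, clones differ at 0.2% of sites (≈ 99.6%, above both). Spacer
  lengths (ARISA) or planted restriction sites (T-RFLP) make each clone's
  predicted fragment equal its OTU's length. Mutating a random ancestor is
  simpler than evolutionary simulation and sufficient to exercise threshold
  clustering; it does not produce realistic phylogenies, rate heterogeneity
  or chimeras, so passing tests say nothing about alignment or tree quality
  on real data.

**What the generator does not emulate** — and what green tests therefore do
not demonstrate about field data: size-dependent dye mobility (the offset is
constant), heteroscedastic or correlated detector noise, PCR amplification
bias between taxa, pull-up between dye channels, and partial restriction
digestion. The planted-truth recovery results show the analysis chain is
internally consistent at the reported effect sizes, not that those
magnitudes are instrument-independent.

## Numerical and policy choices

* Boundary conventions: QC retention uses ≥ at the printed cut-off; binning
  joins strictly within the cut-off; presence requires strictly greater than
  the threshold; phylotype merging requires strictly greater than the
  identity threshold.
* Permutation p-values are add-one ((1+k)/(n+1)), never exactly zero.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  fixed seeds give bit-identical outputs, asserted in tests down to the
  bytes of the written TSVs.
* Problem sizes in the test suite and acceptance script: 20 seeds for the
  full-pipeline recovery studies, 200 community-level replicates for the
  null-behaviour calibration, 500 replicates × 100 permutations for the
  LIBSHUFF type-I check, ~10³ random instances for the binning oracle.
  These sizes give sampling errors comfortably below the tolerances being
  checked while keeping a full run in minutes on one core.

## Known limitations

* No multi-dye spectral deconvolution, basecalling or proprietary trace
  formats (traces enter as plain scan/RFU tables; a converter is the
  caller's responsibility).
* No ordination or ANOSIM/PERMANOVA; the temporal question is answered with
  trend tests, clustering and SIMPROF only.
* LIBSHUFF's default distance is raw identity distance, not a
  substitution-model distance; supply an external matrix for the latter.
* The greedy binning is order-independent given heights, but a different
  height ranking (e.g. after different saturation handling) can change bin
  seeds near the cut-off boundary.
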