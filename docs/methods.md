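# Methods

This note records the models, conventions and numerical choices behind
`breathflow`, and what the synthetic cohort does and does not emulate.

## Signal model and conventions

Retention time is minutes everywhere; readers convert from declared
seconds. Single-quadrupole data are handled at unit mass: the intensity
observed at m/z *x* accrues to bin round(*x*), ties rounding half up.
All downstream stages operate on the resulting EIC matrix, so profile
and centroid input are equivalent after binning.

Spectra are stored base-peak-1000 (the most intense ion at relative
intensity 1000). For comparison they are embedded on a fixed grid of
integer m/z positions covering the half-open range [38, 450) — exactly
412 positions — and scaled to unit Euclidean norm, which is what makes
the dot product a bounded similarity in [0, 1]. The half-open convention
is deliberate: an inclusive 38–450 range would have 413 positions; the
half-open reading reproduces the 412-position vector this workflow is
built around, and the last integer m/z is far outside any spectrum the
pipeline produces, so the choice has no numerical consequence.

## Route 1: matched-filter features and cliques

Peak picking convolves each EIC with a zero-area negated Gaussian
second derivative. Defaults: fwhm 0.05 min (3 s), S/N 5 against a
per-EIC robust noise estimate (1.4826 × MAD of the filter response),
grouping bandwidth 2 s, group support ≥ 50% of samples. These are
deliberately user-tunable configuration values, not constants; the
right values depend on scan rate and column. The integration window
runs to the response's zero crossings; overlapping peaks are cut at the
response minimum between apexes. The feature intensity is the maximum
raw intensity in the window ("maxo").

RT alignment picks anchor groups — one m/z, present in ≥ 90% of
samples, robust RT spread (1.4826 × MAD) ≤ 2 × fwhm — and fits each
sample's deviation from the anchor medians with a low-order polynomial
(constant below 3 anchors, linear below 8, else quadratic). The spread
criterion is robust rather than a plain range so that one systematically
shifted sample (a column change, an injection offset) does not
disqualify exactly the anchors needed to correct it.

Cross-sample grouping is deterministic gap-based single linkage: within
one m/z, RTs are split where neighbours are more than the bandwidth
apart. This is simpler than a kernel-density grouping and exactly
reproducible, and it agrees with exhaustive single-linkage clustering
on small instances by construction.

Clique grouping runs per sample on the unaligned features (the
pseudo-compound step consumes the peak-detection output directly):
edges require co-elution within 0.05 min and EIC-shape cosine ≥ 0.8
over the union of the two integration windows; pseudo-compounds are
connected components after pruning. Per-sample groupings are lifted to
cohort level by majority vote: two feature groups share a compound iff
they were co-grouped in more than half of the samples where both occur.
The majority-vote reconciliation is this package's own rule — some rule
is needed to turn one annotation per sample into one compound list per
subset, and majority vote is the least-assuming deterministic choice.
Members drifting more than twice the RT tolerance from the compound
median are split out to keep compounds co-eluting.

## Route 2: segment-wise deconvolution

Runs are partitioned at the ramp boundaries (defaults 10.00 and
38.67 min; segment 1 owns its right edge) and segments are processed
independently, so results are invariant to segment order.

Compound detection floors intensities below the noise threshold
(default 200 counts), finds apexes in every EIC, and clusters apexes of
different ions that coincide in RT (gap ≤ 0.75 × the peak sigma in
scans). A cluster of ≥ 4 distinct ions is a candidate. Detection
through per-ion apex clustering rather than total-ion-current maxima is
intentional: two co-eluting compounds two sigma apart produce a
*unimodal* TIC, but their ion apexes still separate cleanly.

Spectrum extraction assigns each candidate a Gaussian elution model of
the configured sigma (default 0.02 min) at its apex. An ion belongs to
a candidate when its EIC correlates ≥ 0.9 with that candidate's model —
the gate is against the candidate's own elution model rather than the
local TIC shape, because the TIC of overlapping compounds is a mixture
that neither pure profile matches. Loadings for all ions of overlapping
candidates are solved jointly by non-negative least squares against all
local models; the compound's area is the model area times the summed
loadings, which for an isolated Gaussian equals the compound's total
ion current integral.

Alignment greedily clusters compounds by descending area (RT within
0.05 min after a per-sample median-shift correction, spectral dot
≥ 0.7, at most one member per sample per cluster); the consensus
spectrum is the area-weighted mean rescaled to base peak 1000. Missing
compounds are recovered by integrating the top-3 consensus ions over
± 3 sigma around the consensus RT, background-subtracted at the window
edges, scaled up by the spectral weight the top ions carry.

## Merge, duplicates, normalization

The relative-intensity protocol for clique compounds is applied
verbatim: per-feature averages across all samples (filled values
included), base feature at exactly 1000, others proportional. Tied
maxima all receive 1000.

Thresholds follow the printed rules exactly, with a 1e-9 numerical
guard so constructed boundary cases behave as printed despite binary
float representation: the compound filter requires dot strictly
greater than 0.7 for the best-matching deconvolved compound of at least
one clique compound; duplicates require dot > 0.8 and |ΔRT| ≤ 0.05 min,
plus area Pearson > 0.75 where per-sample areas exist (the
deconvolution side). With fewer than three shared samples the
correlation is undefined and the pair is not flagged. Deduplication
keeps the larger member (total area, or summed average intensity on
the clique side).

The normalization denominator — "the intensity values of a feature
across all samples" — is read as the **sum** of the feature's values
over the subset's samples before taking log10: it is the only reading
that yields one number per feature without further assumptions. The
`mean` (log of the mean) and `sumlog` (sum of per-sample logs) readings
are implemented behind a config switch. Values below 1 count are
floored to 1 before the logarithm; features whose denominator is not
positive are dropped with a warning.

## Identification

The match factor is a weighted cosine with weights m¹·I^0.5 over the
ion union, on a percent scale — 100 for proportional spectra, 0 for
disjoint ion sets, symmetric. The retention index uses van den
Dool/Kratz piecewise-linear interpolation between anchors with
RI(Cn) ≡ 100·n, extrapolating (with a warning) from the terminal pair
outside the anchor span; the RI error denominator is the library
entry's RI. Candidate selection and the best-entry rule follow the
thresholds listed in the README. The alkane-anchoring cascade applies
its six filters in order; the outlier filter fits RT against carbon
number by Theil–Sen regression and drops residuals beyond 3 × the
scaled MAD, with the residual scale floored at 0.002 min so a gross
outlier is caught even when the remaining ladder is perfectly
collinear.

## The synthetic cohort

The generator produces what the pipeline must survive, with known
ground truth: Gaussian elution (sigma 0.02 min) sampled every
0.005 min over the three-ramp program (≈ 20 scans across a peak), unit-
mass fragment spectra with 5–25 ions in m/z 38–450 and a recorded
molecular ion, a flat baseline (100 counts) with additive truncated
Gaussian noise (sd 30), log-normal abundances across samples (median
base-peak apex 5 × 10⁴, log-sd 0.5), a constant +0.3 min shift for the
second group (the column change), per-sample injection shifts
(sd 0.03 min, correctable by alignment) and per-compound per-sample RT
jitter (sd 0.02 min, not correctable — the scale of GC
injection-to-injection variability), the two ubiquitous sampling-bag
artifacts in every breath sample, alkanes C7–C12 in the mother panels,
and per-group alkane-ladder and VOC standard runs. The alkane retention
scale is piecewise linear in carbon number with slope breaks at the
ramp changes; compound ground-truth RIs are interpolated on it.

What it does **not** emulate, and what that means for the tests: peak
tailing and fronting, detector saturation, spectral skew across a peak,
chemical noise and column bleed, and the 3–4 decade dynamic range of
real breath chromatograms with many compounds at the detection limit.
Consequently the deconvolution route is cleaner here than on real data
— in particular it essentially never over-segments, so its raw compound
list contains no duplicate pairs, and the duplicate-*reduction* clause
of the recovery test cannot show a strict decrease on that route (a
fraction cannot drop below zero); the reduction is demonstrated on the
clique route, where per-sample grouping does produce duplicates. A
passing suite therefore shows that the stages implement their contracts
and that the merge logic prunes what the cohort does produce; it does
not certify performance on real chromatographic pathology.

Problem sizes: the demonstration cohort is 2 groups × (3 mothers,
3 children, 2 room-air) breath runs plus standards, 20 random planted
compounds, 9 224 scans × 413 m/z bins per run. These sizes were chosen
so a full end-to-end run stays in the tens of seconds on one core while
every stage still sees realistic geometry (three ramps, boundary-
straddling compounds, multi-sample units).

## Known limitations

Clique reconciliation and the deconvolution internals are re-designs to
the same contracts as the packages they stand in for, not line-by-line
ports; exact per-compound outputs will differ from those tools. The
identification output is a putative annotation — confirming an identity
requires reference standards. The mzML reader covers MS1 spectra with
32/64-bit float arrays (zlib or uncompressed), which is what converter
output of single-quadrupole data contains; exotic encodings are out of
scope.
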