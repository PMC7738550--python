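# breathflow

Open preprocessing for untargeted exhaled-breath volatilomics by
TD-GC/q-MS: from raw profile-mode chromatograms (mzML/mzXML) to a
normalized feature matrix and putatively identified compounds.

Breath biomarker studies acquire full-scan EI chromatograms of volatile
organic compounds and must turn them into a compound × sample table
before any statistics. Two families of tools exist for this and they
disagree by construction: *feature-centric* pipelines detect single-ion
peaks and group them into pseudo-compounds, while *compound-centric*
pipelines deconvolve overlapping elution profiles into spectra directly.
`breathflow` runs both routes independently and cross-validates them
against each other, which prunes unreliable detections and compound
duplications that either route alone produces.

## The method

**Route 1 (features).** Unit-mass EICs are smoothed and
baseline-corrected, then peaks are picked with a matched filter (a
zero-area Gaussian-second-derivative kernel of configurable fwhm, apex
accepted above an S/N threshold against a robust MAD noise estimate).
Retention times are aligned across samples on well-behaved anchor
groups, features are grouped across samples by m/z and RT, and matrix
gaps are filled from the raw signal. Intensities are "maxo" — the
maximum raw intensity in the peak's integration window. Co-eluting
features of each sample are then grouped into pseudo-compounds through
a similarity network (edges require |ΔRT| ≤ 0.05 min and EIC-shape
cosine ≥ 0.8) and reconciled across samples by majority vote.

**Route 2 (compounds).** Each run is split at the temperature-ramp
boundaries (10.00 and 38.67 min for the default three-ramp program) and
each segment is deconvolved independently: co-eluting apex clusters of
≥ 4 ions become candidate compounds, and each ion's contribution is
unmixed by non-negative least squares against the Gaussian elution
models of all overlapping candidates. Spectra are scaled to a base peak
of 1000; compounds are aligned across samples and missing compounds are
recovered by integrating their top ions in the consensus RT window.

**Merge.** Each clique compound receives a relative-intensity spectrum
(average each feature across samples; the most intense feature defines
the base peak at 1000). Spectra from both routes are embedded on a
fixed 412-position grid over m/z 38–450, unit-normalized, and compared
by dot product. A deconvolved compound is kept (*filtered compound*) iff
it is the best match of some clique compound with dot > 0.7; features
matched to filtered compounds (same m/z, RT ± 0.05 min) are the
*filtered features*. Possible duplicates are reported (dot > 0.8,
RT ± 0.05 min, and area Pearson > 0.75 on the deconvolution side) and
the filtered matrix is normalized as
`log10(value) / log10(Σ values across the subset's samples) × 1000`.

**Identification.** Filtered compounds are matched against an MSP
library by a NIST-style weighted-cosine match factor (weights m·I^0.5,
percent scale). Candidates must exceed MF 80%, lie within 5 points of
the best, and are capped at 450 entries. Retention indices are computed
by van den Dool/Kratz interpolation on alkane anchors (RI(Cn) = 100·n)
— either supplied as a CSV or derived from the samples themselves by
the alkane-anchoring cascade (MF > 95% against alkane entries, 5-point
per-alkane window, molecular-ion presence, cross-route RT confirmation,
lowest-RT pick, robust-regression outlier removal). Entries with RI
error > 20% are discarded; the lowest RI error wins, falling back to
the highest match factor when no RI qualifies.

## Worked example

The package ships a synthetic-cohort generator that emulates the study
design end to end — 2 groups × (3 mothers + 3 children + 2 room-air
samples), 20 planted compounds, the two ubiquitous Tedlar-bag artifacts
(N,N-dimethylacetamide, phenol), a C7–C12 alkane ladder, between-group
column drift and per-sample RT jitter — so the whole pipeline runs with
no external data:

```bash
breathflow demo --seed 1 --outdir demo_out
```

This writes, per (group, subset) unit, the feature matrix, clique
table, compound table, match results, duplicate report, filtered and
normalized matrix, and identification table, plus `summary.json`:

```
"totals": {
  "n_features": 3572,
  "n_feature_groups": 1269,
  "n_clique_compounds": 155,
  "n_deconv_compounds": 127,
  "n_filtered_features": 1033,
  "n_filtered_compounds": 98,
  "n_identified": 98
}
```

Reading: 3 572 single-ion peaks across the 16 breath runs collapse to
1 269 cross-sample feature groups; the two routes propose 155 and 127
compounds respectively, and cross-validation keeps the 98 deconvolved
compounds confirmed by a clique compound (every one of the 28 distinct
planted compounds is among them), all 98 identified with the correct
library entry. The per-group anchor tables recover the planted ladder,
e.g. C7 at 5.905 min (RI 700) and C10 at 11.925 min (RI 1000) in
group 1, and a typical identification row reads

```
aligned_id,entry,match_factor,ri,ri_error,rank_basis
cmp_0004,n-alkane C07,100.0,705.1,0.73,ri_and_mf
```

Real data run through the same front door:

```bash
breathflow run config.yaml     # paths, groups/subsets, library, thresholds
breathflow simulate design.yaml  # write a synthetic cohort as mzML
```

All thresholds (0.7 filter, 0.8/0.05/0.75 duplicate rules, 80%/5%/450
candidate rules, 20% RI error, 95%/5-point alkane rules) are config
keys with these defaults.

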