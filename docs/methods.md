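# Methods

## Model and procedure

`betamodes` treats the across-sample beta values at one CpG probe as a
draw from an unknown density on [0, 1] and asks whether that density
has one mode or several. No mixture model is fit and no parametric
form is assumed; the decision is made on a kernel-smoothed estimate of
the empirical distribution, which keeps the method robust to the
skewed, boundary-compressed cluster shapes typical of methylation
arrays.

The density estimate deliberately mirrors the base-R `density()`
contract, because the detection rules are defined on that curve's
discrete grid: Gaussian kernel, 512 equally spaced evaluation points
spanning the data range extended by `grid_cut` = 3 bandwidths on each
side, and the rule-of-thumb bandwidth

    h = 0.9 · min(σ̂, IQR/1.34) · n^(−1/5)

with the sample SD (ddof = 1), linear-interpolation quartiles, and the
SD substituted when the IQR is zero. The kernel sum is evaluated
exactly in numpy rather than by binned FFT; the test suite cross-checks
it against both `scipy.stats.gaussian_kde` (exact, 1e-10) and R's
`density()` (to R's FFT-binning error, ~1e-3 of the maximum).

Stationary points come from the sign pattern of first differences:
slope > 0 is TRUE, anything else FALSE; a TRUE→FALSE switch marks a
maximum, FALSE→TRUE a minimum. The two sets interleave by
construction. Zero slopes fall on the FALSE branch, so an exactly flat
top reports its first plateau index (and a flat valley its last). On
the exact-arithmetic curves the package produces, plateaus cannot
occur away from floating-point underflow, and the `grid_cut` extension
guarantees the curve rises from both ends, so the first and last
stationary points are always maxima.

Each maximum becomes a candidate peak bounded by its adjacent minima;
the outermost boundaries are −∞/+∞ sentinels. Peak membership uses
half-open intervals [left, right): a sample sitting exactly on a
boundary belongs to the right-hand peak, and every sample belongs to
exactly one candidate peak, so candidate proportions sum to one — an
invariant the tests assert exactly.

Filtering then proceeds in the published order:

1. *Noise filter*: discard a candidate holding strictly less than
   `proportion_sample` of the cohort **and** bounded by at least one
   zero-density minimum (sentinel boundaries count as zero-density).
2. *Merge*: one left-to-right pass chains consecutive peaks whose apex
   separation is strictly below `peak_distance`; the chain closure is
   transitive, the merged apex is the member with the highest density,
   the boundaries are the group's outermost ones, and proportion and
   variance are recomputed from the samples inside them.
3. *Re-filter*: drop merged peaks strictly below `proportion_sample`
   (no zero-density condition at this stage).

One surviving peak → unimodal; several → multimodal. All threshold
comparisons are strict, so a peak sitting exactly at a threshold
survives. The filter order matters and is preserved deliberately: a
sparse cluster that splits into two sub-threshold wiggles is removed by
step 1 before step 2 could merge it into a viable mode — see
"Limitations".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `peak_distance` | 0.10 | minimum apex separation (beta scale) between distinct modes; closer apexes merge |
| `proportion_sample` | 0.01 | minimum cohort fraction a peak must hold |
| `grid_size` | 512 | density evaluation points |
| `grid_cut` | 3 | grid extension beyond the data range, in bandwidths |
| `zero_density_tol` | 1e-4 × max density (per curve) | density at or below this counts as "zero" for the noise filter |
| `secondary_peak_min` | 0.04 | post-hoc confidence cutoff on the secondary-peak proportion |
| `hypo_mean_max` / `hyper_mean_min` | 0.10 / 0.90 | probe-mean thresholds for the extreme-methylation flags |
| `extreme_var_max` | unset | optional variance ceiling additionally required for those flags |

`peak_distance` and `proportion_sample` are the two detection
parameters proper; 0.10 and 0.01 are the recommended defaults for
array-scale cohorts, and the 4% secondary-peak cutoff separates
confident multimodality from borderline noise. A Gaussian KDE is never
exactly zero in exact arithmetic, so "zero density" must be a
tolerance; it is defined relative to each curve's maximum so that the
same setting works for tight low-variance probes and broad ones alike
(an absolute override is available). The hypo/hyper thresholds are the
common EWAS conventions for extreme methylation; they only set flags
and never alter the modality call. A plain reading of "bounding
minimum equal to zero" could also mean an empty interval between
minima (zero *samples*); the density-value reading was adopted because
the rule is stated on the fitted curve, and the sample-count reading is
subsumed by the `proportion_sample` clause anyway.

Degenerate inputs: probes with fewer than 10 non-missing values get a
`too_few_obs` status, constant probes `degenerate` (detected on the
value range, since the floating-point SD of identical values is a
nonzero rounding residue); if filtering ever eliminates every peak,
the largest-proportion candidate is restored and the probe is called
unimodal with a `fallback_unimodal` status rather than inventing a
zero-mode outcome. Missing values are dropped per probe and `n_obs`
reports the count used. Within-peak variance with fewer than two
members is reported as 0 so every CSV cell is populated.

## Synthetic data

The generator emulates the three per-probe shapes that matter for this
detector, each as a mixture of Beta distributions parameterized by
(mean m, concentration k), giving cluster SD √(m(1−m)/(k+1)) — about
0.05 at m = 0.5 and 0.02 near the boundaries with the default k = 100,
matching the tight genotype clusters on real arrays:

- *unimodal*: one component, mean drawn from [0.15, 0.85] in the
  fixture;
- *SNP-trimodal*: components at 0.05/0.50/0.95 with Hardy–Weinberg
  weights (1−q)², 2q(1−q), q² for a MAF q (uniform on [0.1, 0.5] in
  the fixture);
- *subtle bimodal* (mQTL-like): components at 0.30/0.55 with weights
  0.90/0.10, chosen to exercise the merge and noise-filter paths.

The default fixture is 50 + 25 + 25 probes × 500 samples. Per-probe
seeds derive from (master seed, probe index) via `SeedSequence`, are
recorded in the truth table, and replay any single probe exactly.

What the generator does **not** emulate: array chemistry (intensities,
detection p-values), batch and plate effects, cross-hybridization
signal mixtures, probe-type (Infinium I/II) distribution differences,
and missingness mechanisms. Passing tests therefore demonstrate that
the detector recovers modality from well-formed beta mixtures of
realistic tightness — not that it is robust to every artifact real
cohorts contain; on real data the recommended upstream QC (detection
p-values, cross-reactive probe removal) still applies.

## Problem sizes and numerical choices

The simulation studies run 500 probes per condition at n = 1000
samples, and the end-to-end fixture 100 probes at n = 500 — large
enough that binomial noise on cluster proportions is small relative to
the thresholds being exercised, while the full suite and the
acceptance script each complete in seconds. The stationary-point
detector is verified against a brute-force neighbour-comparison oracle
on 1000 random mixtures of 1–5 Gaussian bumps; bump widths stay ≥ 0.05
so tails never underflow to exact zero on the grid (at an
underflow-induced boundary plateau the two scans' edge conventions
legitimately differ, and real KDE curves cannot produce one).

Determinism: the core contains no randomness; `classify_probe` is a
pure function of its inputs. The CLI processes probes as an
order-preserving map (serial or joblib), so output files are
byte-identical across worker counts and repeated runs. Results CSVs
round numeric fields to 6 decimals for cross-platform diffability;
matrix CSVs keep full float precision and round-trip exactly.

## Limitations

- Sensitivity to minor clusters fails gracefully but inevitably at the
  `proportion_sample` floor: a SNP-trimodal probe whose
  minor-homozygote cluster is expected to hold ~1% of samples
  (MAF ≈ 0.1 at n = 1000) loses that peak whenever the realized count
  falls below the floor, or when the sparse cluster's own KDE wiggles
  split it into sub-floor fragments that the noise filter removes
  before merging could reunite them. Measured on 500 simulated
  trimodal probes with MAF uniform on [0.1, 0.5], 100% are called
  multimodal but ~97% yield exactly three peaks; the remainder report
  two. Raising n, or lowering `proportion_sample`, shifts this
  boundary.
- The unimodal/multimodal decision is threshold-based, not
  inferential: no p-value or posterior accompanies a call. The
  secondary-peak proportion is the intended confidence ranking.
- The rule-of-thumb bandwidth undersmooths heavy-tailed probes at
  large n; occasional outlier bumps then surface as spurious small
  peaks. These carry secondary proportions near `proportion_sample`
  and are the class the 4% secondary-peak filter removes (on the
  default fixture: 5/50 unimodal probes gain such a peak; all are
  caught by the filter).
- Probes are treated independently; no information is shared across
  neighbouring CpG sites or with genotype data.
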