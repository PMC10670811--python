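# Methods

## Symbolization and dispersion entropy

A series is symbolized in three steps. First the normal-CDF map
`y_i = Φ((x_i − μ)/σ)` with `μ` the sample mean and `σ` the sample standard
deviation with the `N − 1` denominator. The `N − 1` convention is load-bearing:
on the canonical ten-sample walkthrough series the `N` denominator shifts one
borderline sample (2.2, standardized near the 1/3 quantile boundary) into the
wrong class and changes a pattern, while `N − 1` reproduces the published
class sequence exactly. Second, classes `label = round(c·y + 0.5)`, half
rounded away from zero, clamped to `[1, c]` — the standard dispersion-entropy
assignment; ties in `x` get equal classes because the map is a pure function
of the value. Third, delay embedding into `N − (m−1)d` windows. A series is
analyzable when at least two windows fit.

DE is the Shannon entropy of the pattern frequencies, in nats, bounded by
`ln c^m`. All `0·ln 0` terms are defined as 0 throughout.

## CRDE and the pattern ordering

CRDE feeds the pattern distribution through the cumulative residual entropy
functional `−Σ_j (1 − F_j) ln(1 − F_j)`. The functional needs a total order
on patterns; we use lexicographic order of the symbol tuples over all
`K = c^m` slots, unobserved patterns included. Lexicographic order is the
only canonical total order on the pattern alphabet and makes the value
deterministic; zero-mass slots still matter because they repeat the running
survival value, adding duplicated `(1 − F)` terms. Each term is at most
`1/e`, and the last slot contributes 0, so `CRDE ≤ (K − 1)/e`.

The empirical cumulative residual entropy of a raw sample is also provided:
`−Σ ((N−i)/N) ln((N−i)/N) (x_(i+1) − x_(i))` over the order statistics. The
nonnegative form is used (survival-function weights times nonnegative gaps),
consistent with CRE's defining nonnegativity; it is shift-invariant and
positively homogeneous.

## Multiscale procedure

Costa coarse-graining: non-overlapping window means at scale `s`, trailing
`N mod s` samples discarded, `s = 1` the identity. Default scale range
1–25 and dispersion parameters `m = 3, c = 3, d = 1`, the configuration used
for all benchmark experiments; defaults are configurable everywhere.

The NCDF normalization (`μ`, `σ`) is **frozen at the original series** and
reused for every coarse-grained series, the convention of standard multiscale
dispersion entropy. This is a deliberate design choice: coarse-graining
shrinks the variance of uncorrelated noise as `1/s`, and renormalizing at
every scale discards exactly that amplitude information. Empirically, with
per-scale renormalization the 50-seed mean MCRDE profile of white noise
declines only ~0.14 nats over scales 1–25 with a small-scale hump (Spearman
ρ of mean profile vs scale between −0.64 and −0.87 depending on the
ensemble seed), and 1/f noise also drifts downward; with frozen
normalization white noise decays strongly and monotonically (ρ ≈ −1) while
the 1/f profile stays nearly constant — the expected signature of a
complexity measure distinguishing long-range-correlated noise from white
noise. Scale 1 is identical under both conventions.

Per-scale failures are explicit: a scale where the coarse series is shorter
than `(m−1)d + 2`, or constant, or (for MSE) where a match count is zero,
carries an undefined marker that propagates to N/A cells in comparison
tables; nothing is silently dropped.

## Sample entropy baseline

SampEn uses Chebyshev distance, self-matches excluded, and counts both
template lengths over the same `N − m_se` windows (every length-`m_se`
template that extends by one sample, and all length-`m_se + 1` templates),
so a constant series gives `A = B` and SampEn 0. Defaults `m_se = 2,
r = 0.15` of the per-scale coarse-grained standard deviation — the HRV
community standard. Tolerance relative to the analyzed series makes the
measure affine-invariant. With white noise at `N = 1000` the profile is
reliably defined at small scales but match counts can vanish from roughly
scale 7 up (coarse lengths ≤ 150); at `N = 100` most cells above scale 10
are undefined. This failure mode is the baseline's documented limitation,
not an implementation artifact.

## Synthetic signals

White noise: i.i.d. standard normal draws from a seeded generator. Pink
noise: spectral synthesis — a white spectrum scaled by `1/√f`, zero DC,
inverse-transformed and standardized to zero mean, unit variance.
Spectral synthesis gives the exact expected `−1` log-log PSD slope and is
fully seedable; ensembles use seed `base + k` for realization `k`. Benchmark
ensembles use 50 realizations of `N = 1000`, matching the published
experimental design; acceptance checks on these signals are
spectral-property-based (fitted slopes within ±0.2, slope contrast ≈ 1)
rather than sample-exact since no reference generator is specified.

## RR surrogates

The bundled surrogate generators produce synthetic RR series for pipeline
testing without clinical data: healthy-like (pink-noise-driven around
0.9 s, sd 0.05 s — long-range correlated variability), AF-like (white
variability around 0.8 s, sd 0.15 s — large uncorrelated beat-to-beat
irregularity), CHF-like (heavily smoothed noise around 0.65 s, sd 0.012 s —
low, slowly wandering variability concentrating the dispersion patterns).
They emulate only these qualitative variability contrasts; passing tests on
them demonstrates the pipeline's mechanics (availability, ordering,
discrimination machinery), not clinical discrimination performance on real
ECG-derived RR data, which additionally contains ectopy, artifacts and
nonstationarity the surrogates lack.

## Group comparison

Two-sided Mann–Whitney U per scale and group pair on the defined entropy
values, α = 0.05. Exact enumeration of the null distribution when the pooled
sample has ≤ 12 observations without ties; otherwise the normal
approximation with midranks, tie-corrected variance and continuity
correction (scipy's implementation). A cell is N/A exactly when either group
has fewer than two defined values at that scale. Raw p-values are reported
with no multiple-testing correction across scales or pairs — the table
metadata records this; users comparing many scales should correct
accordingly. One profile per subject per segment length is the default
experimental unit; RR segments are contiguous windows at a seeded uniform
offset.

## Numerical conventions and limitations

- Natural logarithms everywhere; probability normalization asserted at
  1e−12; cross-implementation (oracle) comparisons at 1e−12 for counting
  kernels.
- Pattern-space guard `c ≤ 9`, `m ≤ 6`, `c^m ≤ 10^6`.
- Profile CSVs serialize floats at 17 significant digits and parse in
  round-trip mode, so export/import is bit-exact; undefined cells are empty
  fields.
- Entropy estimates are biased when the window count is not large relative
  to `c^m` (at `m = 3, c = 3`, coarse lengths below a few hundred
  undersample the 729 patterns); profiles at high scales of short series
  should be read comparatively, not as absolute complexity.
- The published walkthrough's printed DE value (1.0297) is inconsistent
  with its own printed pattern frequencies, whose Shannon sum is 1.6770
  nats; this package reproduces the frequencies exactly and reports 1.6770.
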