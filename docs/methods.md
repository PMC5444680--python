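# Methods

## Scope

`hybridsnv` detects single-nucleotide variants present as a minority in a
wild-type background from a single competitive-hybridization experiment
against a mismatch probeset, and converts the measured branch distance into a
concentration limit of detection. The package contains five analysis layers
(probeset design, duplex thermodynamics, branch fitting, hypothesis testing,
LOD estimation) plus a synthetic-data generator that emulates the measurement
process end to end. The KRAS exon-2 codon-12/13 panel is shipped as the
reference assay; all operations are generic over the target sequence.

## Probeset geometry

The target is a short single-stranded region (23 nt for the KRAS assay),
stored 5'→3' on the strand that hybridizes to the array. Probes are the
reverse complement of the (optionally mutated) target; mismatch annotations
live in target coordinates, so no double bookkeeping of strands is needed.
The full probeset is the PM probe, every 1MM probe at interior positions
(3 variants per position) and every 2MM probe over admissible position pairs
(3 × 3 variants). Two exclusion rules keep the free-energy model additive:
no mismatch within `edge_margin` (default 4 nt) of either duplex end, and no
2MM pair closer than `min_separation` (default 5 nt). The published design
only sketches these distances; the defaults reproduce its first listed
probes (first 1MM at the 5th base, first 2MM pair at distance 5) and are
configurable. For the KRAS target this yields 1 + 45 + 495 = 541 probes.

A useful structural consequence: the four panel positions lie within 4 nt of
each other, so with `min_separation = 5` no probe carries mismatches at two
panel positions — the twelve hypotheses' mutation branches never share a
doubly-elevated probe.

The panel's customary position counters run opposite to the stored strand
(counter = 23 − target index); label formatting accepts a caller-supplied
counter map, and the `kras` module ships the panel's mapping together with
amino-acid aliases (G12A, G13D, …).

## Free-energy model

Duplex free energy is additive to first order: `ΔG = ΔG_PM + Σ penalties`,
one penalty per non-Watson-Crick pairing, where a penalty depends only on the
mismatch context (target base opposite probe base; 12 contexts) and not on
position. Position-specific overrides are supported behind the same table
interface but are off by default. Under this model `ΔΔG = ΔG_mut − ΔG_wt` is
identical for every probe of a mutation branch (it equals minus the penalty
of the wild-type mismatch that the branch's variant removes), which is what
makes the branch distance a single number per mutation.

All inference treats `ΔΔG` as unknown and estimates `e^(−ΔΔG/RT)` from data;
the shipped penalty table is used only by the simulator and examples. Its
three panel-relevant contexts (wild-type C opposite a non-G probe base) are
anchored to concentration-profile slopes measured on this assay —
C/C = 4.35, C/A = 3.70, C/T = 2.95 kcal/mol, i.e. slopes between ~81 and
~649 at 65 °C — and the remaining nine contexts follow the qualitative
nearest-neighbor stability ordering (G·T wobble cheapest at 1.4 kcal/mol,
C-opposite-pyrimidine contexts most destabilizing). `RT` defaults to
1.987×10⁻³ kcal/(mol·K) × 338.15 K ≈ 0.672 kcal/mol (65 °C hybridization).

## Synthetic-data generator

The simulator realizes the measurement process the analysis assumes, plus
the leading nuisances of a real scanner:

- **Expected intensity**: linear competitive Langmuir,
  `I = A · Σ_s c_s · e^(−ΔG(probe,s)/RT)`. A saturating isotherm
  `I = A·z/(1+z)` is available but off by default, matching the linear-regime
  analysis. `A = 10,000` a.u./nM and `ΔG_PM = 0` put the PM spot near
  5×10⁴ a.u. at 5 nM — the scale only matters relative to background.
- **Replicates and noise**: each probe has `n_replicates = 8` spots; each
  replicate draws multiplicative lognormal noise with median 1
  (`noise_cv = 0.15`) plus additive Gaussian background (mean 2 a.u.,
  sd 0.6, clipped at zero). The per-probe signal is the replicate median.
- **Background handling**: the vendor pipeline's mean-background subtraction
  is applied to the reported signal (`subtract_background = True`), and rows
  below `background_threshold` (default 2× background mean) are *flagged*;
  removal happens downstream when the scatter is built, in either channel.
  The background is deliberately small relative to the PM signal (0.004%):
  it represents the residual after vendor background subtraction, and a
  larger floor would silence the double-mismatch probes that give every
  mutation branch more than one member. With these defaults a realistic
  minority of the dimmest 2MM probes still drops below the floor, so the
  filtering path is exercised.
- **Reproducibility**: all draws come from `numpy.random.default_rng`
  (PCG64); a table is byte-reproducible from its seed, and series/fixture
  generators derive per-array child seeds from a single master seed.

What the generator does **not** emulate: spatial artifacts, washing
kinetics, probe surface-density effects, mismatch–mismatch interaction
energies, and incomplete equilibration. Passing tests therefore demonstrate
the statistical machinery under the stated physical model, not robustness to
every failure mode of a physical array.

The fixture generator produces three experiment-set analogues: (1) a
geometric dilution series of 10C→G (start 10%, factor 2.5, six steps:
10 / 4.0 / 1.6 / 0.64 / 0.26 / 0.10 %) at 5 nM total; (2) the twelve panel
mutants at 5% plus a pure wild-type negative control at 10 nM; (3) seven
"clinical-like" blind samples with elevated noise (`noise_cv = 0.30`,
emulating degraded FFPE-derived material) and unknown fractions drawn
uniformly from 5–40%.

## Branch fitting

Analysis works in natural-log space of both intensity axes, so the vertical
distance to the reference line *is* the log-ratio statistic ρ and any common
optical gain cancels exactly (verified to ~10⁻¹⁴ in the tests). Probes below
the background threshold in either channel are removed before fitting.

The reference line is LOWESS with span 0.5 and 3 robustifying (bisquare)
iterations, fit over *all* retained points: the elevated branches are a small
minority (~10% of probes share any one position) and the robust weights
suppress them, which the tests verify directly (10% of probes elevated by
+1.5 log units move the line by < 0.05 everywhere). If an exactly collinear
majority collapses the robustness scale to zero (a degenerate case arising
only in noise-free simulation), the fit falls back to the unweighted pass.
An isotonic post-pass enforces the physically required monotone
non-decreasing shape, and evaluation interpolates linearly between knots
with constant extrapolation outside the fitted range.

ρ of a hypothesis is the median distance over its mutation branch; the
median is what makes the statistic insensitive to the theoretical
equal-ΔΔG assumption holding only approximately per probe.

Two second-order effects are knowingly neglected, as in the underlying
theory. First, reference-branch probes also bind the mutant (through a
cross-mismatch), which raises the reference line by
`≈ (c_mut/c_wt)·e^(−pen_cross/RT)`; the geometric ρ is exact up to this
term, which is below 10⁻³ whenever penalties exceed ~3.5 kcal/mol or the
mutant fraction is in the LOD regime. Second, the wild-type dilution factor
(1 − f) needs **no** correction: the reference line passes through the
mixture's own reference branch, which carries the same dilution, so the
factor cancels from the distance exactly like the optical gain — the
reference array's absolute concentration is irrelevant.

## Hypothesis testing and calling

Each candidate mutation is tested by a one-sided Wilcoxon rank-sum of its
mutation-branch distances against the reference branch (every retained probe
with no mismatch at the hypothesis position), alternative "greater".  The
exact null distribution is used whenever `n₁·n₂ ≤ 10⁴` and there are no
ties; this matters because a fully separated small subset saturates the
normal approximation around z ≈ 5 while its true significance is orders of
magnitude stronger. Beyond that, the tie-corrected normal approximation with
continuity correction is evaluated through the log survival function, so
`p′ = −ln(p)` never underflows. Hypotheses with fewer than 2 retained
mutation probes or 10 reference probes are flagged invalid rather than
tested.

The sample-level call: significance identifies the mutated *position* —
when a mutant is present, the side branches at the same position are
genuinely shifted and their tests also (correctly) reject — so the *base* is
identified by the branch geometry: the call is the significant hypothesis
with the largest ρ, at per-hypothesis α = 0.01 (a Bonferroni option exists,
off by default). A reported `gap` gives `p′` at the called position minus
the best `p′` at any other position, the margin separating true from false
positions. With no significant hypothesis the sample is called wild type.
Inputs containing more than one mutant are outside the single-mutant model;
the most deviating call is still returned, with an explanatory note.

## Detection limits

`e^ρ − 1` against `c_mut/c_wt` is fit by least squares through the origin
(optionally inverse-variance weighted); the slope estimates `e^(−ΔΔG/RT)`
and a single measurement already determines it. The detection limit for a
threshold `ρ_t` is `c_limit = (e^(ρ_t) − 1)/slope`, reported both as
c_mut/c_wt and c_mut/c_total. `ρ_t` defaults to 0.5 — the branch distance
still confidently measurable at the bottom of the dilution series on this
platform — and is an explicit calibration input, not a universal constant.
Under the default study conditions the weakest panel mutation (C/T context,
slope ≈ 81) lands at c_mut/c_wt ≈ 0.008, i.e. the whole panel is detectable
below 1% relative abundance, and the dilution series recovers the
generating ΔΔG to well within 0.05 kcal/mol at default noise.

## Numerical and interface choices

- Intensities travel in a single TSV dialect (probe_id, intensity,
  n_replicates, below_background; `#`-prefixed key=value metadata); mapping
  vendor exports into it is the caller's one-line job, keeping the analysis
  platform-free. Malformed tables are rejected with 1-based line numbers.
- Probesets serialize to FASTA (target first, mismatch annotations as
  `pos:wt>alt` header tokens) plus a TSV sidecar.
- Distances are never jittered; ties in the rank-sum fall back to the
  corrected normal approximation.
- Problem sizes in the test suite and acceptance script (541-probe arrays,
  six-point series, 500 null pairs) match the shipped assay's natural scale;
  the type-I check at 500 wild-type pairs bounds the empirical rejection
  rate at α = 0.01 by 0.015, reflecting the rank-sum test's conservatism.

## Known limitations

- The additive, position-independent penalty model ignores
  mismatch–mismatch interactions and end effects beyond the exclusion
  margins; real arrays show per-probe scatter around the equal-ΔΔG branch
  ideal, which the median-based ρ absorbs but does not model.
- The linear-regime assumption fails near probe saturation; the simulator
  can generate saturating data but the analysis does not correct for it.
- `ρ_t` transfers across platforms/noise regimes only as a calibration
  input; no universal threshold is claimed.
- LOD confidence intervals are limited to an optional bootstrap over probes
  (weights interface); they are not validated against external data.
- With a single reference hybridization the framework cannot distinguish a
  global shift of all probes from a change in `A`; this is by construction
  (and is why ρ is ratio-based).
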