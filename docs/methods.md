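# Methods

## Kinetic model

The regulator→target relationship is a sigmoidal-synthesis / first-order-decay
ODE:

    dz/dt = k1 · σ(Σᵢ wᵢ·yᵢ(t) + b) − k2·z,    σ(x) = 1/(1+e⁻ˣ)

| parameter | meaning | units | default bounds |
|---|---|---|---|
| `k1` | maximal synthesis rate | expression units / h | (0, 10·k2_max·max(x)] |
| `k2` | transcript degradation rate | 1/h | [0.02, 3] |
| `b`  | regulation bias (basal sigmoid operating point) | – | [−10, 10] |
| `wᵢ` | signed regulatory weight per regulator | – | [−10, 10] |
| `z0` | initial expression | expression units | fixed to the first observation |

The bounds are the model's biological-plausibility constraints: degradation
between half-lives of ~14 min and ~35 h, synthesis capped so steady states
stay within an order of magnitude of the observed maximum, and weights/bias
in symmetric boxes wide enough that the sigmoid can saturate either way.
Fixing `z0` to the first observed value removes one free parameter; the first
residual is then identically zero, which costs nothing in practice because
the trajectory is anchored where the data begin.

Integration is forward Euler with `dt` equal to the resampled observation
step (24 min), so every Euler state is compared directly with an observation.
`integrate_model` accepts any `dt` not exceeding the smallest observation
gap; an adaptive Runge–Kutta reference (`validation.euler_reference_solution`)
exists purely as a cross-check and the test suite verifies first-order
convergence against it.

### Fitting

The objective is the sum of squared differences (SSE) between the simulated
and observed linear-scale profiles. The optimizer is simulated annealing:

* geometric cooling, `T ← 0.975·T` per iteration, `T₀` set per chain to the
  objective value at its random starting point (so early uphill moves are
  nearly free and the scale adapts to each gene);
* Gaussian proposals with per-coordinate sd starting at 0.2× the bound width
  and shrinking by 0.985 per iteration, clipped to the bounds — the late,
  small-step phase refines the incumbent locally, which matters for reaching
  normalized SSEs below 1%;
* 400 iterations per chain, 256 restarts by default; the minimum-SSE restart
  wins, ties break to the lowest restart index.

Each restart's random stream (start point, proposal steps, acceptance
uniforms) is pre-drawn from a seed derived only from `(master_seed,
restart_index)`. Consequences: fits are bit-reproducible; the best SSE is
monotone non-increasing in the number of restarts (a prefix property the
tests exercise); and restarts can be executed as a vectorized batch with
arithmetic identical to running them one by one.

**Fit criterion.** A fit "reaches" the data when SSE / Σ(x−x̄)² falls below a
threshold (default 0.2); otherwise the tested regulation is *disproved*. The
threshold is a package choice — the criterion needs a number and 0.2 accepts
fits explaining ≥80% of the variance about the mean, which separates cleanly
the two regimes we observe on synthetic data (driven genes fit to ~0.01–0.05;
profiles uncorrelated with the regulator sit near 1).

Problem sizes used by the shipped experiments: 50 genes per noise level and
64 restarts per gene for the recovery batteries (the full 256 restarts remain
the library default and are used in the single worked-example fit test).

## Preprocessing

Published log2 intensities are exponentiated back to linear reads, smoothed
with a Savitzky–Golay filter, and linearly resampled onto a uniform
24-minute grid (the 20–60 h study grid gives 101 points). The filter's
window/order are not dictated by the data source; the defaults (9 points,
order 3) preserve the pulse-like features of these profiles while removing
most single-replicate noise, and both are exposed in the configuration.
All downstream analysis — correlation grouping and kinetic fitting — runs on
the linear scale, the scale on which the ODE is formulated.

## Group assignment

A profile is **flat** (group C) when its coefficient of variation is below
`flat_threshold` (default 0.1); otherwise it joins group A if its Pearson
correlation with the ECF factor passes `r_threshold` (default 0.7) and is at
least the HrdB correlation, group B if the HrdB correlation passes, else
*other*. The numeric thresholds are interpretive choices (no published
values exist): 0.7 reproduces the qualitative tri-partition on synthetic
cohorts; 0.1 CV separates unregulated from driven genes at low-to-moderate
noise. At a noise sd of 0.3 log2 units the residual post-smoothing CV of a
flat gene is ~0.10–0.15, so analyses at that noise level should raise the
flatness cut (0.2 separates flat CV ≤ 0.15 from driven CV ≥ 0.55 cleanly);
the corresponding property test does exactly that. Correlation is computed
on preprocessed (smoothed, resampled, linear-scale) profiles. Repressed
targets anti-correlate with their regulator and therefore land in *other*;
the pipeline fits those against the ECF factor with an unconstrained signed
weight, which is how repression is detected.

## Motif model and scanning

Coordinates are 0-based half-open throughout; the narrowPeak summit column
(an offset from peak start) is converted on input, with a midpoint fallback
for plain BED.

**ZOOPS-EM.** Each sequence contains zero or one motif occurrence; with
occurrence probability γ the placement is uniform over both strands.
EM alternates placement posteriors with weighted-count PWM and γ updates
(pseudocount 0.25× background per column); likelihood ascent is monotone and
tested. The best of `n_starts` seeded initializations wins. This finder is a
stand-in validated on planted motifs; it does not replicate any external
tool's exact objective. Two inherent ambiguities of de novo discovery are
handled explicitly: the recovered motif may be phase-shifted by a column or
two, and its orientation is arbitrary. When deriving the bipartite family,
both orientations of the −10 are tried and the one whose upstream segments
yield the larger per-segment likelihood gain for the −35 element is kept —
only the correct orientation has a conserved element 23 bp upstream.

**Composite motifs.** The −35 and −10 halves are joined across spacers of
16–19 bp; spacer columns sit at background frequencies and contribute exactly
zero to every log-odds score. The spacer is measured as the gap between the
last −35 column and the first −10 column. The 10 bp "upstream segment" for
−35 discovery starts 23 bp upstream of the −10 site start; with a ~4 bp −35
core this window covers the spacer range (a 7 bp −35 element is only
partially visible for the longer spacers, which is why the derived −35 is
narrower than a planted one).

**Exact p-values.** Scores are log-odds in bits against a 0-order background
(estimated from the scanned sequences by default — the genome is GC-rich, so
no uniform assumption), discretized on a 0.01-bit lattice. Scanning sums the
discretized column scores, so the dynamic program that convolves per-column
score distributions yields p-values that are *exact* for the scored motif
(the only approximation, ≤ width·granularity/2 bits, is in the discretization
of the scores themselves; a brute-force enumeration oracle confirms equality
for widths ≤ 6). One consequence worth knowing: a near-consensus motif takes
few distinct scores, so the largest achievable level below a threshold can
sit visibly under it — ordinary discrete-statistic conservatism. Calibration
is therefore demonstrated with a smooth-spectrum (Dirichlet-random) motif,
where the empirical null hit rate matches the threshold within binomial
error at both 0.05 and 0.001.

Overlapping hits on a sequence (including across spacer variants of the same
site) collapse to the lowest-p hit; ties break leftmost, then + strand, then
shortest spacer. Hit filtering implements the published two-part rule: keep
the lowest-p hit per sequence plus every hit whose core matches a wildcard
pattern (default `--TA---T--`).

## Enrichment

Overrepresentation is the upper-tail hypergeometric probability P(X ≥ k)
(scipy's distribution; an exhaustive-draw oracle verifies it for N ≤ 20).
Only the upper tail is tested. Percentages round half-up to the nearest
integer. No multiple-testing correction is applied by default (single focal
classes are tested at raw p < 0.05); a Benjamini–Hochberg flag exists for
users scanning many classes.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *regimes* of the study data: the non-uniform
32-point hour grid without replicates; additive Gaussian noise on the log2
scale (= multiplicative log-normal on reads — single-replicate microarray
variance is high, and its true magnitude is unpublished, so `noise_sd_log2`
is a tunable defaulting to 0.2); 72% GC i.i.d. background sequences of 100 bp
(summit-window sized); ZOOPS-style site planting with the observed spacer
distribution (0.59/0.21/0.11/0.09 for 18/19/17/16 bp); and a 16.8% focal
functional-class incidence. Planted sites are sampled from the PWM columns
(not consensus-only) so the scanner sees realistic score spread; tests that
need exact coordinate recovery switch to consensus sites explicitly.

The cohort's two regulator profiles are fixed canonical shapes: a mid-culture
pulse for the ECF factor and a sigmoidal decline for the housekeeping factor,
chosen nearly orthogonal over the grid (|r| < 0.15). This is a deliberate
identifiability condition: with strongly anti-correlated regulators the
decomposition of a single noisy time course into activator and repressor
contributions is ill-posed and no optimizer could recover the weight signs
reliably. Gene parameters are drawn with weight magnitudes 1.5–4, half-lives
of 0.5–2 h, a bias centering the sigmoid in its dynamic range at the
regulators' mean level (a responsive promoter), and `z0` at the steady state
of the first time point.

Per-entity seeds derive from `(seed, entity_index)`, so enlarging a cohort
never perturbs already-generated entities.

What passing these tests does **not** show about real data: no probe-level
artifacts, batch or normalization effects; no dinucleotide or positional
structure in promoter backgrounds; no peak-calling noise (summits are exact);
regulator profiles are noise-free inputs rather than measured ones; and real
regulators are not orthogonal by design, so dual-fit identifiability on real
profiles must be judged case by case (the anti-correlation of the two sigma
factors in the first 30 h of real cultures is precisely why sign constraints
on the dual fit are provided).

## Numerical and degenerate-input choices

* Correlation with a constant profile is defined as 0 with a warning;
  normalizing a constant profile yields all zeros.
* Euler states are clipped at 0 before the log2 transform in the simulator
  (floor 1e-12); with the default bounds (k2·dt ≤ 3·0.4/60 per fine step in
  the simulator, 3·0.4 = 1.2 > 1 only for extreme k2 on the coarse grid) the
  fit objective tolerates transient negativity, and the returned trajectory
  is clipped at 0.
* Non-ACGT bases score as background (zero log-odds) with a warning.
* Windows overrunning a contig are skipped with a warning by default
  (clipping and erroring are selectable).
* Annealer temperatures are floored at 1e-6; zero-width bound boxes (used to
  pin a weight) are handled by clipping.

## Known limitations

* Simulated annealing offers no optimality certificate; the restart budget is
  the only control. The shipped schedules reach normalized SSEs of ~0.003–0.02
  on noise-free targets, not machine precision.
* The ZOOPS finder reports one motif; it does not subtract discovered motifs
  and iterate, and phase/orientation are resolved only in the bipartite
  derivation step.
* The exact-p scanner is per-position; no E-values, q-values or genome-wide
  background correction (the analysis operates inside peak sequences at raw
  p ≤ 0.05 by design).
* Operon structure is ignored: genes are treated independently.
* No confidence intervals on kinetic parameters; the verdict is the weight
  sign plus the fit criterion.
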