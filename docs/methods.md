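# Methods

## Model overview

`cryptdrift` simulates a patch of colonic crypt epithelium of roughly 500
cells as agents on an `N x M` lattice with wrapping columns (the crypt
cylinder slit open and rolled flat).  Row 0 is the stem-cell niche; cells are
shed when pushed past row `M-1`.  The model couples three layers:

1. **Lattice mechanics** (`grid_core`, `engine`): a four-state cell cycle
   (`QUIESCENT -> G1 -> S+G2 -> MITOSIS`) advanced in discrete steps of
   `dt`; daughter insertion by a fixed priority over the four neighbours;
   migration by mitotic pressure (crowded sites push their oldest non-stem
   resident up one row, shifting the contiguous occupied run above); shedding
   past the top row.  More than one cell may occupy a site transiently, and
   niche sites may hold arbitrarily many stem cells — the reported stem
   counts under biased feedback (up to ~100+) require this.
2. **Division-type stochastics** (`division_niche`): a stem division is
   symmetric with probability `Ps`; a symmetric division differentiates with
   the biased, feedback-corrected probability `Pd` or self-renews otherwise,
   giving outcome probabilities `P0 = Ps*Pd`, `P1 = 1-Ps`, `P2 = Ps*(1-Pd)`.
3. **APC genotypes** (`mutation`): two monotone allele flags per cell;
   normal / all-heterozygous (FAP) / single-heterozygote (sporadic) initial
   conditions; an optional heterozygous stem-cell phenotype; a per-division
   Bernoulli(`mu`) second hit on the remaining wild-type allele.

## Homeostatic feedback

The niche is held near its target size `N0` by a linear response of the
differentiation probability to the current stem count `Ns`:

    Pd_corrected = clip(Ns/N0 - 1/2, 0, 1)

so the two symmetric fates balance exactly at `Ns = N0`, differentiation
shuts off below `Ns/N0 = 1/2` and saturates above `3/2`.  A multiplicative
bias `B` is applied *after* clipping (`Pd = clip(B * Pd_corrected, 0, 1)`),
which makes the attainable range `[0, B]`; this order is what reproduces the
observed equilibria `Ns* = N0 (1/2B + 1/2)` — 11.25, 12.1, 13.3 stems for
`B` = 0.8, 0.7, 0.6 at `N0 = 10`.  At `B = 0.5` the equilibrium (15) sits
exactly at the clip boundary, so the feedback loses its restoring force above
`Ns = 15` and the count wanders neutrally upward — long transients and very
large excursions are expected there, not a numerical fault.  For `B < 0.5`,
`min P2 = Ps(1-B) > max P0 = Ps*B` and the niche grows without bound; runs
are stopped by a stem-overflow guard (default 200) and flagged.

`Ns` in the feedback is the stem count at the start of the iteration
(snapshot semantics); all divisions committed within one iteration share it.

## Timing conventions

Cycle times are in hours and must be multiples of `dt` (default 30 min).
Defaults: stem cycle `TCs = 24 h` with `TG1s = 12 h`; transit cycle
`TCt = 12 h` with `TG1t = 4 h`; at most `Num_div_max = 6` transit divisions.
The literal rule list costs one extra step at each of the quiescence exit,
the G1 exit and mitosis, so the realized inter-division interval is
`TC + 3*dt` (25.5 h for stems); a unit test pins this down.  Absolute
iteration counts therefore run ~6% above the nominal `TC/dt` cadence, which
is well inside the replicate-to-replicate spread of every reported quantity.
Founders start desynchronised: each initial stem cell has already spent a
uniformly drawn whole number of steps (below `TG1s`) in G1.

## Update schedule and randomness

Each iteration: (1) snapshot the stem count; (2) advance every cell's cycle
synchronously (each cell consults only its own start-of-step state); (3)
commit all divisions in stable cell-index order against the live occupancy —
two mothers may legally target the same empty site because multi-occupancy
is resolved immediately afterwards; (4) migrate; (5) shed.  All randomness in
a run comes from one stream seeded per run, so a `(parameters, seed)` pair is
bit-reproducible.  Replicate seeds derive from a master seed via
`numpy.random.SeedSequence([master_seed, stream])`, with a distinct stream
per experiment; the scheme is stable across versions.

Age ties in migration are broken uniformly at random; off-lattice neighbours
(north of the top row, south of the niche) are simply not insertion
candidates; cells resident in the top row persist until a push from below
moves them off the lattice.

## The mutation layer

The second hit is one Bernoulli(`mu`) draw per *division* of a heterozygous
cell, taken on the mother as she divides so both daughters inherit the
homozygous genotype (`hit_unit="daughter"` switches to independent
per-daughter draws).  First hits in wild-type cells are disabled: all
experiments start from a pre-existing heterozygote.  The endpoint scope is
`STEM_ONLY` by default — only stem-cell lineages persist in the crypt, so a
hit in a transit cell is washed out within days; `ANY_CELL` is available and
is always the earlier endpoint (hundreds of times earlier, since transit
divisions dominate the division count).

The heterozygous phenotype (`HetEffect`) may override `Ps` and `B` and scale
the stem cycle time; the cycle multiplier is treated as a stem-cell
phenotype (transit timings untouched) because every observable it feeds —
fixation, succession, second hits — is a property of the stem compartment.
Homozygous cells carry no further phenotype; reaching homozygosity is the
measured endpoint.

## The stem-only oracle

Division-type draws depend on the lattice only through `Ns`, so the niche is
statistically autonomous.  The oracle (`experiments.stem_only_oracle`)
exploits this: an event-driven simulation of stem cells alone, with the same
first-division law (`TC - t0 + 2` steps) and inter-division interval
(`TC + 3` steps) as the lattice engine.  It reproduces the lattice's
succession-period distribution (Welch-checked in the tests at alpha 0.01)
at a tiny fraction of the cost, and with `synchronized_start=True` it
degenerates to a generation process that can be enumerated exactly — the
two-founder, all-symmetric case (succession 1/2; extinction 1/4 at
generation one and 1/4 at generation two) is frozen into the tests as an
independent absorption-law check.

## What the experiments measure

* `succession_period_vs_ps` / `run_fig3` — mean days until all stem cells
  share one founding ancestor.  Periods scale roughly as `1/Ps` (drift rate
  is proportional to the symmetric-division rate) and diverge as `Ps -> 0`,
  where every lineage is immortal.
* `stem_count_dynamics` / `run_table2` — pooled mean and 5th-95th percentile
  band of `Ns` over a horizon (default 5000 iterations, 480 discarded as
  burn-in for band estimates), with growth classified homeostatic
  (pooled mean within 15% of `N0`), elevated, or unbounded (guard tripped).
* `estimate_fixation_probability` / `run_table3` — fraction of sporadic-mode
  replicates whose marked lineage wins succession; runs ending in overflow,
  censoring or extinction count as non-fixation and are flagged.  The
  neutral case fixes at `1/N0` by symmetry (chi-square-checked).
* `mean_time_to_second_hit` / `run_table4` — mean first second-hit iteration
  over uncensored FAP replicates; censored runs are counted and excluded.

Default replicate counts are 100 for fixation estimates and 20-30 for period
and second-hit means — enough that a 2-standard-error band is a few
percentage points / ~20% of the mean respectively, while a full acceptance
sweep stays around two minutes.

## What the synthetic conditions do and do not capture

The lattice is a ~500-cell patch with `N0 = 10`, not a whole crypt: absolute
stem counts, periods and hit times are patch-scale numbers, and only their
*variation* with `Ps`, `B` and `mu` should be read onto real crypts.  The
second-hit probability `mu = 0.001` per division is deliberately high to
keep waiting times computable; it has no empirical basis, so only ratios
between phenotype variants are meaningful.  The model has no cell mechanics
or adhesion, no 3-D geometry, no Wnt-pathway molecular detail, no crypt
fission (the unbounded `B < 0.5` regime is where fission would take over in
reality, and runs are flagged rather than continued), and no post-second-hit
progression.

## Numerical and degenerate-case conventions

* Probabilities are compared as `draw < p` (a draw below the threshold fires
  the event), so `p = 0` never fires and `p = 1` always does.
* A single-founder niche (`N0 = 1`) is an immediate succession at iteration
  0; it is also the only standard configuration whose niche can go fully
  extinct through the feedback (at `Ns = 1`, `Pd = 1/2`), which is reported
  as a flagged `extinction` outcome, never a succession.  Multi-founder
  niches can in principle die through a one-iteration burst of symmetric
  differentiations at small `Ns`; the same flag applies.
* Stemness is stored as an exact fraction (object model) or integer quantum
  index (engine), so quantisation is never subject to float error.
* The engine's cell capacity is `N*M + 2*guard + 64`, sufficient because
  transit cells resolve to single occupancy every iteration and the stem
  count can at most double between overflow checks.

## Known limitations

* The object model and the array engine consume randomness differently, so
  they agree statistically (and on every exact invariant), not draw-for-draw.
* Succession-period means carry heavy right tails; small-replicate means
  (including published point values for this class of model) scatter by tens
  of percent, and comparisons should use the provided standard errors.
* With `B` at or just below 0.5 the niche performs a reflected random walk
  with no upper restoring force; summary statistics there depend strongly on
  horizon and guard settings and should be treated as regime descriptors,
  not point estimates.
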