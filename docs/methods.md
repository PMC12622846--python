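# Methods

## Model

The simulator couples one gene's transcription to the supercoiling of the
topological domain that contains it. The domain is a line
`[0, D_up + L + D_down]` bounded by rotation barriers; bound RNAPs are
additional barriers, so `k` RNAPs partition the DNA into `k + 1` segments.
Each segment carries a real-valued linking number `Lk`; its supercoiling
density is `σ = (Lk − Lk₀)/Lk₀` with `Lk₀ = length/h`. Supercoiling
diffusion is instantaneous *within* a segment (σ is uniform there) and
blocked *across* barriers; this is the operative assumption that makes the
segment list a complete state.

Deterministic processes, per timestep `Δt = 1/v`:

- **Elongation.** Every RNAP advances 1 bp with both flanking `Lk` values
  held fixed — the polymerase is assumed fully drag-limited, so the DNA
  rotates, not the transcription machinery. Stretching the upstream
  segment at fixed `Lk` underwinds it and shrinking the downstream segment
  overwinds it (the twin-domain effect). An RNAP stalls this step iff
  `σ_up < −σ_s` or `σ_down > +σ_s`; the comparison is strict, stall flags
  are recomputed from current σ every timestep, and stalling is fully
  reversible (no backtracked state). A trailing RNAP whose advance would
  bring its centre closer than `w` to the RNAP ahead waits (steric
  exclusion holds during elongation, not only at binding).
- **Termination.** An RNAP reaching `x = D_up + L` is removed instantly;
  its two segments merge (lengths and `Lk` add, so σ becomes the
  length-weighted mix); one transcript is created with an exponential
  lifetime of mean `t_RNA`.

Stochastic processes, resolved in chronological order inside each
timestep window: promoter initiation, TopoI binding on each flank, gyrase
binding on each flank, and scheduled RNA decays. Every channel's waiting
time is exponential at its current rate; the earliest in-window event
fires, the state (hence every rate) is updated, and waiting times are
redrawn. Because exponentials are memoryless this is realised exactly —
without thinning or approximation — by drawing a single exponential at the
total rate and selecting the firing channel with probability proportional
to its rate. RNA decay times are fixed at transcript creation and kept in
a heap.

Rate laws:

- Initiation: `k_i′ = k_i / (1 + exp((σ − σ_i)/β_i))`, evaluated at the σ
  of the segment containing the promoter position `D_up`; zero while an
  RNAP centre sits at `x < D_up + w/2` (occlusion). A newly bound RNAP is
  placed at `D_up − w/2` (downstream edge at the TSS), splitting its
  segment proportionally so both halves inherit σ; it elongates, and can
  stall, from its first step.
- TopoI: per-bp rate `k_T / (1 + exp((σ − σ_T)/β_T))` times the flank
  length (`D_up` or `D_down`), acting on the segment containing that
  flank; each event adds +1 `Lk` and unbinds instantly.
- Gyrase: per-bp rate `k_G / (1 + exp(−(σ − σ_G)/β_G))` times the flank
  length, gated to zero when the flank σ ≤ σ_ρ. A binding performs
  `n ~ Geometric{1, 2, …}` cycles with mean `ρ_G` (a binding that did
  nothing would not be a binding event, hence support starting at 1);
  each cycle removes 2 `Lk`, and remaining cycles are abandoned as soon
  as the segment σ has reached σ_ρ, so gyrase never works on DNA below
  its binding threshold.

Topoisomerases act only through the two gene-flanking regions, never
between co-transcribing RNAPs inside the gene. This keeps the steady-state
calibration dimensionally consistent (below); a side experiment letting
them act on every segment changed none of the qualitative behaviour and
moved the bursting statistics by less than the seed-to-seed spread.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| L | gene length | 1000 | bp |
| D_up, D_down | barrier distances | 10 000 | bp |
| v | RNAP velocity (sets Δt = 1/v) | 25 | bp/s |
| h | helical repeat of relaxed DNA | 10.5 | bp/turn |
| w | RNAP footprint | 30 | bp |
| σ_start | initial supercoiling density | −0.055 | – |
| k_i | maximal initiation rate | 0.05 (weak 0.008, strong 0.2) | s⁻¹ |
| σ_i, β_i | initiation sigmoid midpoint, width | −0.04, 0.005 | – |
| k_T | TopoI per-bp binding rate | k_T*(D_up) | bp⁻¹ s⁻¹ |
| σ_T, β_T | TopoI sigmoid midpoint, width | −0.04, 0.005 | – |
| k_G | gyrase per-bp binding rate | k_G*(D_down) | bp⁻¹ s⁻¹ |
| σ_G, β_G | gyrase sigmoid midpoint, width | 0, 0.015 | – |
| ρ_G | mean gyrase cycles per binding | 4 | – |
| σ_ρ | gyrase binding threshold | −0.11 | – |
| σ_s | stalling threshold | 0.062 | – |
| t_RNA | mean RNA lifetime | 120 | s |

σ_T and β_T mirror the initiation sigmoid because both promoter opening
and TopoI activity require DNA melting; the topoisomerase response to σ is
deliberately gradual (logistic) rather than a step, which stabilises the
dynamics against small σ changes without adding parameters.

The steady-state rates are `k_T* = (v/h)/D` and `k_G* = (v/h)/(2ρ_G D)`:
acting at saturation over a flank of length `D`, each enzyme then removes
supercoils at exactly the flux `v/h ≈ 2.38 Lk/s` that one continuously
elongating RNAP injects. For reporting, activities are expressed in
comparable units as `k_T` and `2 k_G ρ_G` per kb (0.24 Lk/kb/s at
D = 10 kb). With asymmetric barriers, TopoI's steady-state rate is
computed against the upstream distance and gyrase's against the downstream
distance, since those are the flanks whose supercoils they respectively
remove. Sweeps express `k_T` and `k_G` as fractions of these values.

Without transcription the two sigmoids balance where
`f_T(σ) = f_G(σ)`, at σ = −0.03 for the defaults; the simulated
time-averaged domain σ and an independent master-equation solution of the
single-segment jump process (tests/oracles.py) agree with this value to
well under 1%.

## Run protocol and observables

Runs are 2×10⁶ timesteps (22.2 h simulated) at full scale. The first
45 000 steps (30 min) are discarded before statistics; 90 000 steps
(60 min) when a barrier distance reaches 100 kb, because larger domains
equilibrate more slowly. All statistics are computed on per-timestep
samples taken at the end of each step: transcription rate
`k_obs` (terminations per retained second), normalized rate `k_obs/k_i`,
free promoter fraction (`k_obs` over the time-mean of `k_i′(σ_promoter)`,
averaged over all retained steps including occluded ones — it isolates
steric availability), mean elongation speed (gene length over
initiation-to-termination time, completed transits only), Fano factor
(variance/mean of the RNA copy number) and normalized variance
(variance/mean²). Fano estimates from a single trajectory carry heavy
autocorrelation, so regression-style comparisons use means over seeds and
cross-seed spread, never naive standard errors.

A single integer seed deterministically derives every stream: grid cells
and replicates get `SeedSequence([seed, cell indices…])` children, so a
sweep is reproducible cell-by-cell and no global RNG state is shared.

## Plasmid (in-vitro) mode

A freely rotating circular plasmid annihilates elongation-generated
supercoils, holding σ constant. Rather than implementing periodic
linking-number bookkeeping, the mode approximates the circle by a linear
domain with barriers 10⁹ bp away: injected supercoils dilute into the
enormous flanks. The residual deviation of any segment σ from σ_start is
tracked at every step and reported; at the default settings (L = 500 bp,
k_i = 0.4 s⁻¹, 10⁶ steps) it stays below 3×10⁻⁴, negligible against the
stalling threshold. Transcription rates are terminations over total time
(no burn-in — the template starts at equilibrium). Topoisomer mixtures,
as extracted from cells, are modelled as a Gaussian over σ with sd 0.004
on a grid of single-topoisomer rates (−0.1 … 0 in steps of 0.005); the
ensemble rate is the normalized-weight average. Single topoisomers
transcribe nothing below −σ_s (the first RNAP stalls at the promoter
forever) and progressively less as σ rises above σ_i; only the ensemble
average produces the non-monotonic curve with an interior optimum at
moderately negative σ. The ensemble y-scale is not anchored to any
external normalisation, so only the curve's shape and threshold behaviour
are asserted.

## Sweep experiments

`run_grid` crosses TopoI fractions × gyrase fractions × promoter
strengths × barrier distances (full scale: 0 … 2k* in steps of 0.1k*,
promoters 0.008/0.05/0.2 s⁻¹, distances 1/10/100 kb — cluster-scale work;
the test suite and CLI run reduced grids as first-class citizens).
`log2_fold_change` compares seed-averaged rates between paired grids
(e.g. shrinking the domain, or scaling both activities 10-fold — in this
model the two manipulations are equivalent in distribution because
binding is non-specific). `inhibition_ratio` divides one enzyme's rate by
a factor (default 5) and reports `log2FC(strong) − log2FC(weak)`; negative
values mean the inhibition preferentially represses the strong gene.
`far_close_ratio` reproduces the asymmetric-barrier design (close:
250 bp upstream / 320 bp downstream; far: 3200 / 3408 bp) holding per-bp
rates fixed at the close-geometry steady-state fractions, so moving a
barrier changes the number of binding sites, not the rates.

`quartile_response` is a generic analysis of per-gene
(expression, fold-change) tables: stable expression ranking into four
equal-count bins, per-bin mean linear fold-change, the statistic
`log2(mean FC Q4 / mean FC Q1)`, and a two-sample unequal-variance
(Welch) t-test between the top and bottom quartiles' log2 fold-changes —
Welch because nothing guarantees equal variances across expression
classes. `synth_expression_table` emulates the *structure* of such tables
for testing: log-normal expression strengths and a linear trend of log2
fold-change in expression percentile scaled so the Q4−Q1 difference in
mean log2 fold-change equals the configured effect, plus Gaussian noise.
It does not emulate count noise, normalisation artefacts,
composition effects of total-output normalisation, or any biological
covariate structure — recovery tests therefore show estimator
correctness, not robustness to real transcriptomic messiness.

## Numerical choices

- `Lk` is real-valued: enzyme steps are integral but proportional splits
  at RNAP binding create fractions; only σ enters any rate law, so no
  rounding is ever applied. The global ledger — total `Lk` equals the
  initial value plus TopoI events minus twice the gyrase cycles — is
  asserted after every run (and after every step in the invariant tests)
  at 10⁻⁶ relative tolerance.
- Segment boundaries sit at RNAP centres; the 30-bp footprint affects
  only steric occlusion and collision, not the `Lk` partition.
- Elongation processes RNAPs downstream-first, so a trailing RNAP sees
  the leader's updated position within the same step.
- The promoter-containing segment is the upstream flank segment once the
  last-bound RNAP has cleared `D_up`; before that (occlusion window) the
  promoter lies just downstream of that RNAP.
- The logistic rate guards `exp` overflow by returning 0 beyond
  z = 700; non-finite σ raises immediately (it signals corrupted state).
- Geometric variates use inverse-CDF from a buffered uniform stream;
  exponential and uniform variates are consumed from pre-drawn blocks of
  a `numpy` Generator, keeping scalar draws cheap and the whole
  trajectory bit-reproducible from the seed.
- Ties: an RNAP exactly at a stall threshold is not stalled (strict
  inequalities); a decay and a channel event at the same instant resolve
  decay first; quartile boundary ties break by stable rank order.

## Desk-scale problem sizes

The package's own smoke/regression scales, used by the test suite and
documented here as defaults for interactive work: qualitative surface
checks run 3×3 fraction grids with 2 seeds at 1.5–4×10⁵ steps;
the plasmid response uses 1.5–2.5×10⁵ steps per topoisomer; the
homeostasis check 8×10⁵ steps; the Fano regression keeps the full
2×10⁶ steps × 3 seeds because burst statistics converge slowly. The full
11×11 grids at 2×10⁶ steps reproduce the complete regulatory surfaces and
are exposed through `GridSpec`/the CLI presets.

## Known limitations

- No twist/writhe partition, no 3-D conformation, no explicit supercoil
  diffusion kinetics (diffusion is instantaneous within segments).
- No RNAP rotation, net-torque stalling, premature termination, promoter
  escape, abortive initiation or R-loops; RNAP cooperation is limited to
  steric blocking, so the cooperative speed-up of co-transcribing
  polymerases is not reproduced.
- Topoisomerase binding is sequence-independent by design.
- The bursting regression is the one place where this implementation and
  its reference point disagree beyond seed noise: at the moderate-gene /
  10 kb / steady-state-activity condition the measured Fano factor is
  ≈ 2.1–2.2 (mean over seeds; single-trajectory estimates span roughly
  1.6–2.5 over 5×10⁵-step windows), on the high side of the 1–3 band
  expected for such genes. Alternative readings of the topoisomerase
  action (all-segment binding) and of the initiation input (domain-wide
  σ) were implemented and rejected: the former changes nothing outside
  seed noise, the latter abolishes bursting altogether. All surrounding
  observables (homeostatic σ, free promoter fraction, sub- vs
  super-Poisson ordering across topoisomerase conditions) behave as
  expected, so the residual gap most likely sits in an unobservable
  scheduling or bookkeeping detail of the reference rather than in the
  model structure exposed here.
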