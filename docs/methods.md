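# Methods

## Model and units

The model is a 28-species, 83-reaction mass-action ODE system for the
IKK–IκB–NF-κB–A20 module, generated from the packaged rate-constant table
(`nfkbse/data/rate_constants.tsv`). Every reaction row becomes exactly one
flux term (rows grouping several species under a shared constant — the
IKK degradation row and the IκB protein-degradation rows — expand to one
reaction per species). The table carries two value columns, `nominal`
(literature-assembled constants of the Hoffmann/Lipniacki model lineage)
and `fitted`; see "Parameter columns" below for why `nominal` is the
package's working reference set.

Units are μM for concentrations and s⁻¹ (or μM⁻¹s⁻¹ for bimolecular
associations, μM·s⁻¹ for zeroth-order syntheses) for rate constants. The
table's magnitudes (total NF-κB 0.06, IKK activation ~3·10⁻³ s⁻¹) only
produce the characteristic hour-scale dynamics under this calibration;
user-facing time is converted to hours.

### Compartments and the Kv convention

Nuclear species (`NFkBn`, `IkB*n`, `IkB*n_NFkBn`) live in a compartment
`Kv = 5` times smaller than the cytoplasm. Transport fluxes
(`I1`, `K01`, `L*`, `Q*`, `V*`) conserve molecule amounts, with the
tabulated constant read as the cytoplasm-referenced rate: for a transport
reaction the nuclear-side stoichiometric coefficient is multiplied by Kv
in **both** directions (import: cytoplasm −k·[X], nucleus +Kv·k·[X];
export: nucleus −Kv·k·[Xn], cytoplasm +k·[Xn]). Under this convention the
volume-weighted total NF-κB (cytoplasmic NF-κB species + nuclear NF-κB
species / Kv) has exactly zero derivative, which the tests assert to
machine precision and along whole trajectories to 1e-9 relative.

The alternative amount-conserving convention (tabulated export constants
read as nuclear-referenced) was implemented and rejected: it accumulates
a ~2.6 μM resting nuclear free-IκBα pool that buffers incoming NF-κB and
delays the first nuclear peak to ~1.7 h, incompatible with the ~0.5 h
first translocation time this model family is known for. mRNA synthesis
(transcription induced by nuclear NF-κB, product appearing in the
cytoplasmic mRNA pool) carries no volume factor; the synthesis constants
are calibrated directly in cytoplasmic concentration units (the ×Kv
variant was tested and degrades the oscillation timescales).

### Parameter columns

The packaged table preserves both numeric columns. Under this
implementation the `nominal` column reproduces the model family's
canonical behavior — first nuclear peak ~0.5 h after stimulation onset,
oscillation period ~2.2 h for the IκBβ/ϵ double knockout (second peak at
2.8 h), single-peaked responses for the A20 and IκBα-containing double
knockouts, a sigmoidal dose–response without hysteresis — while the
`fitted` column yields a substantially stronger A20 arm and ~4.5 h
periods. The package therefore uses `nominal` as the default working
reference set for its bundled study conditions and the acceptance
observables; `fitted` remains fully supported through
`load_parameter_table(column="fitted")`.

Known transcription quirks preserved from the source table: IκBβ has no
NF-κB-induced transcription (`Ub = 0` in both columns), A20 has no
constitutive transcription (`C2 = 0`), and the shared constants
(`Da/Db/De`, `Ga..e`, `Ha..e`, `Kdeg`, `Wa..e`) feed several fluxes each.

## Integration protocol

Classical fixed-step RK4 with dt = 1 s (default), sampled every 60 s,
with concentrations clamped at 0 (tolerance 1e-12 μM) before each flux
evaluation. dt = 1 s sits far below the fastest first-order timescale in
the table (~0.6 s⁻¹ translation rates); halving dt moves the nuclear
NF-κB trajectory by < 1e-6 in relative sup-norm (asserted in tests). The
RHS and the RK4 loop are code-generated from the reaction table and
numba-compiled once per process (~5 s); a plain numpy
stoichiometry-matrix × flux-vector reference implementation is
cross-checked against the compiled kernel to 1e-12.

Every simulation starts from the standard initial condition (all NF-κB
free in the cytoplasm, everything else zero) and equilibrates 33 h with
TR = 0 before stimulation. The 33 h pre-run is a fixed protocol, not a
convergence criterion: the NF-κB-containing species settle well within
it, but the constitutive IκBβ/ϵ complex pools still drift at ~0.3%/h
(extending to 66 h moves them by up to ~8%). `equilibrate` warns when the
end-of-run drift exceeds 1%/h (configurable) and never raises.

The dose–response protocol holds each dosage of an ascending grid
(default: 20 points/decade over [1e-5, 1e-1] plus 0) for 30 h, carrying
state between steps, records mean nuclear NF-κB over hours 20–30 of each
hold, and retraces the grid descending from the forward sweep's end
state. Hysteresis is declared when the forward/backward gap exceeds 5%
(configurable); the observed maximum gap (~4% near the activation
threshold) comes from slow transients inside the averaging window, not
from bistability — it shrinks with longer holds.

## Ensemble generation

Extrinsic noise is modeled as time-independent cell-to-cell variation of
the kinetic constants: replicate r draws each sampled constant uniformly
from (x₀(1−χ), x₀(1+χ)). Defaults follow the study conditions: N = 1000,
χ = 0.3, all nonzero rate constants sampled, `Kv` and `NFkB_total` fixed
(structural constants; both can be added to `sampled_symbols`).
Constants with x₀ = 0 — including knocked-out synthesis rates, since
sampling operates on the post-knockout reference — have zero-width
intervals and stay exactly 0.

Latin hypercube sampling is implemented directly (rather than through a
generic QMC API) because the sampler guarantees two properties the tests
rely on: (i) exact stratification — the N sorted values of every sampled
constant occupy the N equal-width strata exactly once; and (ii)
per-constant independent streams — each constant's draws and permutation
derive from `SeedSequence([master_seed, crc32(symbol)])`, so enlarging
the sampled-symbol set never reshuffles other constants, and identical
configs reproduce bitwise. Uniformity is property-tested against a plain
Monte Carlo oracle (mean within 0.5%, KS distance under the 1% critical
value at N = 10⁴).

Knockouts zero both synthesis channels of a gene: `U*` and `Y*` for an
IκB isoform, `C1` and `C2` for A20.

## Dynamic features and the pattern taxonomy

Peak calling uses scipy's prominence machinery: a local extremum counts
if its prominence is ≥ 5% of the trajectory's global maximum
(`prominence_frac`, default 0.05) and, for maxima, its height is ≥ the
amplitude floor (default 6e-6 μM = 10⁻⁴ of total NF-κB). Consecutive
same-type extrema are reduced to the more extreme one so peaks and
troughs interleave. The detector is tested against an exhaustive
every-grid-point oracle on both simulated and noisy synthetic signals.

The six features of a nuclear NF-κB profile: first maximum (amplitude of
the first peak), first translocation time (its time), first period (gap
between the first two peaks), and — normalized by the first maximum — the
first inter-peak minimum, the second maximum, and the steady state (mean
over the trailing 10% of the stimulated window, `steady_window = 0.1`).
Undefined entries (e.g. no second peak) are NaN with explicit flags,
never silent zeros. A separate responder flag records whether the
trajectory moved at all: global max − initial value ≥ amplitude floor
(defined this way rather than through the peak-based first maximum so
that strong monotonic responses count as responders).

Pattern classification: 0 prominent peaks → monotonic-increasing (the
"hyperbolic" class, which also absorbs flat non-responders — the
taxonomy has no separate no-response bin); 1 → single-peaked; ≥ 2 peaks
with second/first amplitude ratio ≥ `sustain_threshold` (0.6) and at
least `min_peaks_sustained` (3) peaks → sustained oscillation; any other
multi-peak profile → damped oscillation. The sustained/damped boundary
is a declared convention, and the reported pattern fractions are
sensitive to it. Under this reconstruction replicate trajectories are
uniformly moderately damped (second/first ratios 0.25–0.40 across
genotypes and dosages), so essentially no trajectory is labeled
sustained at the 0.6 threshold; a survey over thresholds and peak-count
requirements showed the wild type is never markedly less
sustained-looking than the IκBβ/ϵ knockout here, so the published strong
contrast between those genotypes is not reproducible by re-tuning the
classifier and the defaults were left at their declared values.

Feature distributions use 50 uniform bins over the observed range; the
reported mode is the center of the fullest bin (noisy for broad
distributions at moderate N). Histograms, means, dispersions and
defined-fractions are serialized per feature.

## Heuristic ensemble-average fitting

Targets are values (with relative tolerance, default 0.15, and optional
weights) for any subset of the six features of the SE-average nuclear
NF-κB curve. The search loop: evaluate the SE average (N_fit = 200
replicates at the current χ) → compute relative deviations → pick the
worst feature (deviation scaled by its tolerance) → nudge the two
kinetic constants most rank-correlated (Spearman, on a pilot ensemble of
100 replicates) with that feature by a multiplicative factor 1 ± η
(η = 0.2), direction from the correlation sign and the sign of the
deviation → accept if the worst deviation did not increase, otherwise
roll back, try the opposite direction once, then halve η; when η
exhausts (< 0.02), decrement χ by 0.05 (χ is non-increasing over a run,
floor 0.05). Every evaluation reuses the same seed-derived random
numbers, so comparisons are noise-free and the whole fit is bitwise
reproducible. Features missing from the average receive a finite penalty
(5.0) rather than an exception.

The feature→parameter pairing is computed on the fly rather than fixed a
priori, and can be overridden (`pairs`) or restricted
(`adjustable_symbols`). Caveats observed in validation: with the full
symbol set, correlated-parameter degeneracy can let the search satisfy
all feature tolerances at a compensated parameter combination; the
parameter-recovery experiment (two constants perturbed ×1.5, recovered
within 4% at N_fit = 200) restricts the search to the perturbed
constants. Feature–parameter correlations also revealed that the first
translocation time is dominated by the nuclear import rate `I1`
(|ρ| ≈ 0.77), with the IKK activation rate `K1` contributing a weaker,
advance-the-peak (negative) effect confirmed by direct perturbation.

## What the synthetic generators do and do not emulate

The synthetic-signal module (constant, saturating-exponential,
damped-cosine, sustained-sine families plus seeded Gaussian noise)
exercises the feature/pattern analytics independently of the ODE model;
it makes no claim to NF-κB realism beyond waveform shape. The ensembles
themselves emulate extrinsic noise only: uniform, uncorrelated,
time-independent parameter variation. They do not model intrinsic
(copy-number shot) noise, parameter correlations, cell-cycle drift of
the noise distribution, or receptor-level signaling upstream of the
`TR·K1` activation term — so passing tests validate the ensemble
machinery and the mass-action reconstruction, not the biological
completeness of the noise model.

## Problem sizes and numerical choices

Test-suite ensembles use 200 replicates (the acceptance script uses the
full 1000) with a 10 h stimulated window; the dose–response test sweeps
6 replicates over a 13-point grid. A 43 h trajectory at dt = 1 s costs
~30 ms after kernel compilation. Trajectory CSVs are written with
`%.17g` and read back with round-trip float parsing so serialized runs
are bit-identical.

## Known limitations

* The two printed parameter columns disagree dynamically under this
  reconstruction (see "Parameter columns"); the original integrator's
  conventions are not fully recoverable from the source material.
* Replicate trajectories are more strongly damped than the published
  single-cell exemplars; sustained-oscillation fractions are therefore
  near zero under any defensible classifier setting (documented above).
* The wild-type modal oscillation period is ~2.8–3 h here, above the
  published ~2 h; the IκBβ/ϵ knockout's ~2.2 h matches.
* No stochastic (Gillespie) kinetics, no SBML I/O, no TNFα autocrine
  positive feedback, no time-varying stimuli beyond the step protocols.
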