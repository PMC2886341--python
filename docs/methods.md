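# Methods

## Model structure

The regulated protein is represented by one chemical species per
combination of (PTM flag set, compartment). A *collective* PTM groups all
individual sites with a common functional effect into one binary flag;
the default model's eight flags are listed in the README. Compartments
are cytoplasm, nucleus and a DNA-bound (transcriptionally active) state;
the DNA-bound state is reachable only from the nucleus, and "total
nuclear" observables count nucleus + DNA-bound together. With all eight
flags enabled this yields 768 protein species; the generator refuses more
than 24 flag classes (3·2^24 ≈ 5·10^7 species) with an explicit error,
reporting the closed-form count.

Reactions change exactly one flag or one compartment at a time, so each
species interconverts with at most (number of classes + 1) others. All
rate laws are elementary mass-action in molecule counts (units #·min^−1
throughout; compartment volumes are absorbed into the rate constants):

* PTM addition/removal: `v = k · E · A`, with `E` the catalysing enzyme's
  copy number. Only the pseudo-first-order product `k′ = k·E` is
  experimentally meaningful; the split into `k` and a default copy number
  follows the convention that fully activated kinases number 10^4–10^5
  molecules.
* Transport: first-order, basal rates 0.182 (cytoplasm→nucleus), 0.055
  (nucleus→cytoplasm), 0.25 (nucleus→DNA), 0.125 (DNA→nucleus) min^−1.
  The import/export pair is chosen to give a redistribution half-life of
  ~10 min and a nuclear-favouring basal equilibrium; the binding pair
  puts exactly 2/3 of nuclear protein on DNA at stationarity.
* Gene expression, per target gene: stimulated transcription is catalytic
  in each DNA-bound species (`0.3` per bound molecule·min, modulated by
  transcription MFs), plus zero-order basal production (3 min^−1) of
  nuclear mRNA; export 0.22, translation 1.23, mRNA degradation 5.622
  (cytoplasmic mRNA only — nuclear mRNA leaves only by export), protein
  degradation 1.9·10^−3 min^−1. These generic gene-expression constants
  imply an mRNA lifetime of minutes and a protein half-life of
  `ln 2 / 1.9e-3 ≈ 6.1 h`.

### Multiplicative-factor composition

The effect of pre-existing modifications on a process is modelled as a
product of per-flag multiplicative factors applied to the basal rate:
`k_eff = k · Π_f MF(f, process)`. The product is commutative and empty
for unmodified species; unspecified MFs default to 1. This is a gross but
necessary approximation — interactions between modifications have rarely
been measured — and it makes the whole network linear in the state, which
several numerical choices below exploit.

### Polyubiquitination and degradation

Polyubiquitination is a one-step flag (no chain assembly) permitted only
in the cytoplasm, and degradation (by the proteasome pool) consumes only
cytoplasmic polyubiquitinated species. By default pUb-flagged species are
*terminal*: they neither translocate nor gain/lose other flags, keeping
the one-step semantics; the `pub_terminal` config switch restores full
mobility for exploration. Acetylation and monoubiquitination are
independent flags (no lysine-site competition). Synthesis injects
unmodified cytoplasmic protein at `0.0055 × E2F1` (default E2F1 = 100,
i.e. 0.55 molecules·min^−1 — calibrated so that, with degradation
blocked, the pool of 1000 grows by 20% in 6 h).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| kinase/phosphatase k | 5·10^−5 (E = 10^4) | #^−1 min^−1 | k′ = 0.5 min^−1: modification fast against transport/turnover |
| acetylation k | 10^−4 (E = 10^3) | #^−1 min^−1 | k′ = 0.1 min^−1: full acetylation in tens of minutes |
| monoubiquitination k | 2·10^−4 (E = 10^3) | #^−1 min^−1 | same timescale class |
| polyubiquitination k | 10^−6 (E = 10^3) | #^−1 min^−1 | k′ = 10^−3 min^−1, fitted jointly with degradation to the observed ~6 h half-life under high Akt |
| degradation k | 10^−4 (E = 10^3) | #^−1 min^−1 | k′ = 0.1 min^−1 |
| initial protein | 1000 | molecules | order of consensus binding sites genome-wide; large enough that ODE ≈ SSA for totals, small enough that per-species counts are few |

Enzyme copy numbers are the model's *inputs*: protocols are expressed as
overrides (e.g. Akt = 10^5 for insulin-stimulated levels, 100 when nearly
inactive) and timed dosing events (step resets of a copy number).

## Simulation

**SSA.** Exact Gillespie direct method; propensity `k · E · x_reactant`.
One integer seed (numpy `default_rng`) governs a whole trajectory;
identical seeds are bit-reproducible. At every recording or dosing
boundary the pending waiting time is discarded and redrawn, which is
exact because exponential waiting times are memoryless. A step guard
(default 5·10^7) aborts runaway simulations with the reached time. The
propensity vector is refreshed with two vectorized operations per step
(first-order reactions are laid out contiguously), ~30 µs/step for the
full 3595-reaction network.

**ODE.** The rate equations are affine, `dx/dt = A x + b`, with constant
sparse `A` between dosing events; integration uses BDF with the exact
Jacobian and restarts at each event. For this reaction class the ODE
solution equals the SSA ensemble mean exactly, which the test suite
exploits (mean agreement within 3 standard errors).

**Pre-equilibration** integrates the ODE for the stated duration under
pre-event enzyme levels and uses the final state as the t = 0 condition
(rounded to whole molecules for SSA starts). Since the ODE is the exact
mean, this is deterministic and removes any dependence on the arbitrary
all-cytoplasmic initial placement.

**Steady states** are found by long-time integration over doubling
horizons; the state is accepted when a doubling changes no component by
more than 10^−7 relative and the residual derivative is decaying. A
direct sparse solve of `A x = −b` (`linear_steady_state`) is provided
separately and serves as the independent cross-check in the tests.
Regimes without a non-trivial steady state (e.g. synthesis with
degradation disabled) raise an explicit error.

**Sensitivities** are local elasticities `(k/X)·dX/dk` from central
finite differences with ±1% parameter perturbations — adequate because
the network is linear in the state, so truncation error is negligible.
Targets below a floor (10^−9) at the evaluation time are reported as
undefined rather than divided by.

## SBML and shorthand

Networks serialize to SBML Level 3 Version 2 with substance units "item"
(counts): species are fully flattened (no multistate package), enzymes
are non-constant global parameters, every kinetic law is the product of a
local rate parameter, the optional enzyme parameter and the reactant (or
modifier, for catalytic reactions such as stimulated transcription), and
dosing events are SBML events with `t ≥ T` triggers. Counters are
parameters governed by assignment rules summing species — never reacting
species. The reader supports exactly this mass-action subset and rejects
anything else; round trips are identity up to canonical ordering, and
output is byte-deterministic for golden-file comparison. The compact
shorthand dialect mirrors the published SBML-shorthand section layout
(`@model/@compartments/@species/@parameters/@reactions/@events`); the
`@rules` section used for counter sums is a dialect extension, documented
here as a deviation.

## Scenario conventions

* Scenario baselines zero all modifying enzymes except those a protocol
  varies, keeping phosphatase, ubiquitination/degradation machinery and
  synthesis at defaults; each protocol is then "default config + listed
  overrides + dosing schedule".
* The two long-pulse acetylation protocols use a 2520-min
  pre-equilibration. At basal enzyme levels the total protein itself
  still creeps toward its synthesis/degradation balance on a ~10^4-min
  timescale, so downstream gene product is near- but not exactly
  stationary at that horizon (a few percent drift per further 100 min) —
  reported observables are therefore ratios to the t = 0 level.
* Steady-state read-outs (dose-response curves, transcription ratios) are
  computed deterministically; time courses run as ODE (ensemble mean) or
  as replicate SSA paths (default 10) with mean reported.
* Transcription comparisons between acetylation states are made at
  matched total protein by rescaling the synthesis input (total is linear
  in it), and reported as ratios — absolute mRNA counts are otherwise
  unconstrained.
* Mapping model fractions to cell-population readouts follows the
  convention that the fraction of protein in a compartment stands in for
  the experimentally scored fraction of cells with that localization;
  cells scored as mixed are counted with the cytoplasmic class. This
  convention is documentation-only: no digitized experimental overlays
  ship with the package.

## Numerical choices and degenerate inputs

Default ODE tolerances rtol = atol = 10^−8 (counts of order 1–1000).
Half-life is operationalized as first time to 50% of the initial value
with linear interpolation between grid points — not a fitted exponential
constant — because decay toward a nonzero synthesis-fed floor makes the
apparent half-life longer than `ln 2 / k`. Localization fractions and PTM
fractions raise on zero total protein. Configurations are validated
(non-negative rates, strictly positive MFs, existing enzyme references,
sorted non-duplicate events) with one finding per violation; loading an
empty document reproduces the built-in defaults exactly, and
serialize/reload round-trips are identities.

## What the defaults do and do not show

The built-in parameterization reproduces the calibration targets it was
built from: species combinatorics, the 20%-in-6h synthesis rate, the ~6 h
half-life under high Akt, the ~91% kinase-mark pseudo-equilibrium at
k′a/k′b = 10, the 99%/90% acetylation levels of the two acetylase/
deacetylase settings, the ≈3/4 transcription ratio of acetylated vs
deacetylated protein at matched level, and compartment-count fluctuations
of ~1% of a 1000-molecule pool. Passing these says nothing about detailed
kinetics real FOXO exhibits beyond the mass-action, single-step,
multiplicative-composition assumptions: cooperative multi-site
phosphorylation (concave-up onset), 14-3-3 binding intermediates,
lysine-site competition between acetylation and ubiquitination, stepwise
polyubiquitin chains, gene-specific transcriptional effects of
acetylation, and feedback onto synthesis are all outside the model
boundary.

Known approximations worth remembering:

* The balanced-rescaling invariance (multiplying a kinase/phosphatase
  pair's rates by the same factor leaves steady states unchanged) is
  exact only in the limit where modification is fast against transport
  and turnover; at default rates the residual is a few percent and
  shrinks as the pair is scaled up.
* "About 80%" kinase-mark occupancy quoted for kinase 10^5 / phosphatase
  10^4 conflicts with the naive two-state equilibrium (~91%) that the
  default compartment-unrestricted kinases produce; the defaults keep
  kinases active in all compartments and the discrepancy is recorded, not
  resolved.
* One table prints the synthesis pseudo-first-order constant as 5.5
  min^−1, inconsistent with its own factors (0.0055 × 100 = 0.55) and
  with the 20%-in-6h calibration; 0.55 is used.
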