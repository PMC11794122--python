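# Methods

This note records the modeling assumptions behind qdacsim, the defaults
and why they were chosen, and what the synthetic generator does and does
not emulate.

## Conjugate assembly statistics

The number of biotinylated antibodies landing on one streptavidin
tetramer is modeled as Poisson(λ) with λ the antibody:streptavidin molar
ratio. `prob_multivalent_antibody` evaluates P(n > 1) = 1 − (1 + λ)e^(−λ)
(implemented with `expm1`; the naive form cancels catastrophically below
λ ≈ 10⁻⁵). For small λ, P(n > 1) = λ²/2 − λ³/3 + O(λ⁴); the second-order
form agrees with the exact value within 1% for λ ≤ 0.05, while the
leading term λ²/2 alone is ~3% high at λ = 0.05 — tests use the
second-order form.

The exact model is a per-site multinomial: each of the 4 sites
independently holds an antibody biotin (p_ab), a DNA biotin (p_dna) or
stays free/blocked. Independence amounts to assuming no ligand depletion
and equal biotin affinity across species; the biocytin blocker occupies
sites but is otherwise inert. `enumerate_site_occupancy` computes the
distribution by full enumeration of the 3⁴ assignments, which doubles as
the oracle against the Binomial(4, p) marginals. The Poisson model is
the λ ≪ 1 limit: with per-site probability λ/4 the mean count is exactly
λ and the n = 0, 1 classes agree to O(λ); the n > 1 tail constants
differ (0.375λ² vs 0.5λ²), which is why the two models are exposed
separately rather than interchangeably.

The working conjugation mix (0.06 µM × 10 µL antibody against
1.6 µM × 3 µL streptavidin) computes to λ = 0.125, although the ratio is
quoted as ~1:80 wherever the multivalence probability is evaluated.
`lambda_from_mix` returns the computed 0.125 and logs the discrepancy;
`WORKING_LAMBDA = 1/80` carries the quoted ratio, and the design check in
`validate_fixtures` reports both.

## Oligo panel

The packaged panel (`data/table1.fasta`, 13 records) carries the assay's
printed designs with terminal modifications as `mod5=`/`mod3=` metadata
tags. Verified geometry: the C1 + C2 ligation product equals the printed
111-nt C1C2; the proximity primer pair spans [2, 89) on C1C2 (87-nt
amplicon); the ROX probe's reverse complement sits in the 69-nt
reporter; the forward reporter primer is its exact 5' prefix. Two print
discrepancies are preserved deliberately and surfaced as warnings, not
errors: the reverse reporter primer's complement mismatches the printed
69-mer 3' end (GTATCCGAGCCAACACGGC vs ...GTATCCGATAGAACACGGC), and the
connector's complementarity to the C1/C2 junction is only partial, so
its bridging role is treated as metadata. Matching is exact-string by
design — no melting temperature, mismatch tolerance or secondary
structure — because the assay's design questions here are combinatorial,
not thermodynamic.

## Synthetic assay generator

The generator emulates the measurement chain, not vesicle biology:

- **Population.** Each vesicle is tumor-derived with probability
  `tumor_fraction`; tumor vesicles draw antigen copies from a negative
  binomial (mean, size), the standard over-dispersed choice for
  surface-marker counts; normal vesicles carry none. `antigen_fixed`
  substitutes a constant copy number for deterministic scenarios.
- **Labeling.** Each antigen copy binds a conjugate with probability
  `p_bind`; bound conjugates split evenly between the two types in
  dual-label (PLA) mode; each vesicle additionally picks up
  Poisson(`nonspecific_rate`) spurious conjugates (vesicle-level, so the
  PLA background mechanism stays expressible). Every conjugate carries
  3 reporters by default, per the occupancy analysis above.
- **Capture.** Bead capture and washing are independent Bernoulli
  thinning at `capture_eff × wash_retention`; survivors elute into
  `eluate_volume` µL and the ground-truth DNA concentration follows by
  Avogadro scaling (N_A = 6.02214076 × 10²³), exact to float precision.

Defaults (chosen once as representative of a cell-culture EV prep, since
no measured values exist for them): n_ev = 10⁴ (a computational
down-sample; real preps run ~10⁹ particles/mL — concentrations, not
counts, are the quantities carried forward), tumor_fraction = 0.3,
antigen_mean = 50 copies, dispersion = 5, p_bind = 0.3,
nonspecific_rate = 0.05, capture_eff = 0.7, wash_retention = 0.9,
eluate_volume = 100 µL. The `cellline_low`/`cellline_high` scenario
presets scale the population so expected eluate DNA lands near 0.21 and
79 nM, the span observed across cell lines; they are documentation
presets, not assertions. The generator does not model vesicle size
distributions, binding kinetics/diffusion, plasma matrix effects or the
particle-to-protein-mass mapping (left as a user-set scale factor), so
passing tests demonstrate correctness of the inference machinery under
the stated stochastic model, not fidelity to any particular biological
sample.

All randomness flows through `numpy.random.Generator`; the pipeline
expands one global seed into per-stage streams via
`SeedSequence.spawn` in a fixed order (population, labeling, capture,
ligation, standards, sample wells), so stages are independently
replayable and equal seeds give byte-identical artifacts.

## qPCR model

Ct = slope·X + intercept with X = −log10(dilution); larger X is more
dilute, hence the positive slope of the reference curve (4.059, 8.144).
Because the absolute concentration at X = 0 is not defined by the curve
itself, concentration conversions anchor on a user-supplied
`ref_conc_nM` at X = 0. Gaussian cycle noise (default sd 0.2 cycles,
typical replicate scatter) and censoring at `max_cycles` (default 40)
produce *undetermined* wells, which are excluded — never imputed — from
fitting (OLS via `scipy.stats.linregress`) and quantification. The
reference curve's slope implies amplification efficiency
10^(1/4.059) − 1 ≈ 0.76, i.e. sub-ideal doubling; this is reported by
`amplification_efficiency` but not corrected for. The detection limit
rule is "most dilute level at which all replicates amplified", matching
the qualitative in/out-of-range reading of dilution series; a probit
LOD was considered and rejected as over-specified for three replicates.
Note the published observation pair (Ct 26.96 at 100 pM, 29.65 at
10 pM, ΔCt 2.69 per decade) is internally inconsistent with the
published slope 4.059; both are honored as data, neither is asserted.

## Proximity ligation

Proximity is binary colocalization on one vesicle: a vesicle with
conjugate counts (b₁, b₂) offers min(b₁, b₂) ligatable pairs (each
conjugate used at most once — the simplest conservative pairing; no
geometry is modeled), each succeeding independently with `p_ligate`.
Free-conjugate collision ligation is a reaction-level
Poisson(`background_rate`) background, with the vesicle-borne /
background split always conserved in the outcome. `background_rate` has
no anchored default: the assay's no-biotin controls showed no Ct at all,
which cannot distinguish zero background from background below the
detection limit. Under Poisson labeling the per-vesicle detection
probability has the closed form p_ligate(1 − e^(−λ₁))(1 − e^(−λ₂)). In
this model PLA is a *specificity* filter: it reads out fewer molecules
than direct qPCR (each template consumes ≥2 conjugates), so at zero
background its LOD in concentration terms is never better than the
direct arm's; its advantage appears when nonspecific signal dominates
the direct readout. The published scenario in which ligation extends
detection from 100 pM to 10 pM is reproducible as a scenario outcome
under tuned noise/background settings, and is documented rather than
asserted.

## Quantification

The Ct → DNA → antibody → mass chain is linear, so replicate SDs
propagate multiplicatively and analytic propagation equals Monte-Carlo
propagation for this chain. Internal math keeps full precision;
rounding (2 decimals for nM, 3 significant figures for ng/mL) happens
only at reporting. With the published inputs the chain gives
0.48/3 = 0.16 nM and 0.16 × 29.1 = 4.656 → 4.66 ng/mL at 3 s.f. (the
source prints 4.6, a truncation inconsistency we do not reproduce).
MW defaults to 29.1 kDa — the value the published chain computes with —
although EpCAM is elsewhere described as ~40 kDa; MW is always
user-overridable. The digital estimator λ = −ln(1 − p̂) is the standard
single-partition Poisson correction; the published "standard curve +
Poisson" particle-concentration procedure is under-specified, so this
estimator is this package's interpretation. Its linearization λ ≈ p̂ is
accurate within 2% only for positive fractions below ~0.035
(−ln(1−p)/p = 1 + p/2 + …), and an all-positive plate has no finite
estimate. Published per-mL exosome concentrations of order 10⁻⁵–10⁻⁷
are dimensionally puzzling and are not reproduced by any operation.

## Test design and problem sizes

Property tests run derandomized (hypothesis profile `ci`, 50 examples).
Simulation studies were sized to stabilize their statistics: the
end-to-end recovery study uses 200 seeds × 2000 vesicles × 3 replicate
wells at 0.2-cycle noise (median |relative error| of recovered mass
< 10%; the dominant error source is Ct noise, ~7% sd on concentration
after 3-replicate averaging); OLS slope recovery averages 200 plates;
LOD noise-monotonicity averages 500 paired plates; digital-estimator
calibration averages 200 plates of 10⁴ partitions per λ (a single
plate's sampling error at λ = 0.1 is ~3.2%, so the 2% check is a bias
statement about the estimator, not a single-draw guarantee). The whole
suite runs in a few seconds on one CPU.
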