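# Methods

## Model form

Each circuit is a closed list of mass-action reactions over molecule
counts.  Only zeroth-, first- and second-order steps are allowed;
cooperative rate laws (Hill, Michaelis–Menten) are out of scope — where
a saturating response is needed it emerges from explicit
promoter-occupancy species.  Genes are single-copy species with one
state per bound configuration:

* two states for a single repressor or activator site (miR-1, MyoD,
  Mafbx, myogenin genes in the individual circuits);
* three states where an activator and a repressor compete for the same
  site (the miR-378 gene: free / MyoD-bound / Msc-bound);
* products of independent sites where regulators act on separate
  elements (the integrated MyoD gene: Pax3-site × Hox-A11-site, four
  states; the integrated miR-143 gene: {free, MyoD, Msc} × {IL-6 free,
  IL-6 bound}, six states).

Transcription-factor binding consumes one molecule of the factor and
releases it on unbinding.  The one exception is pAkt at the myogenin
promoter, which acts catalytically (`pAkt + gene_off → pAkt + gene_on`)
so that both the Akt/pAkt pool and the gene-state pair stay exactly
conserved — with a sequestering encoding one pAkt molecule would leave
the phosphorylation pool whenever the promoter is active.

### miRNA mechanisms

The two silencing modes the circuits distinguish are encoded literally:

* **enhanced degradation** (miR-1 on Pax3 mRNA, miR-378 on Msc mRNA,
  miR-143 on Igfbp5 mRNA): the miRNA:mRNA complex decays with a rate
  constant well above the basal mRNA rate, releasing the miRNA intact
  (miRNAs are recycled everywhere; nothing in the underlying biology
  requires consumption).
* **translation inhibition without enhanced decay** (miR-181 on
  Hox-A11 and Sirt-1 mRNA): the complex cannot translate and decays at
  the *same* rate constant as the free transcript, again releasing the
  miRNA.  A direct consequence, used as a validation signature, is that
  total transcript abundance (free + bound) is exactly independent of
  the miRNA level while protein output falls with the free fraction.

The miR-1:Pax3 complex *does* translate, at the free-transcript rate.
This is required by the observation that miR-1 lowers Pax3 transcript
and protein by the same ~30–50% at 48 h; a translation block would
depress protein more than transcript.

## Engines

**ODE.**  d**x**/dt = S·**w**(**x**) with S the stoichiometry matrix
and **w** the propensity vector, integrated by LSODA (automatic
stiff/non-stiff switching) at relative tolerance 1e-6, absolute
tolerance 1e-13 and maximum internal step 10⁴ s.  The requested
relative tolerance is treated as a target for *global* accuracy: the
stepper's local error control receives a 0.1 safety factor, because
local tolerances alone bound only the per-step error (without the
factor, a 10⁵ s pure-decay run accumulates ~2e-6 relative error).
Sub-tolerance negative excursions are clipped to zero on output; larger
negativity is treated as a solver failure.  The continuous homodimer
convention is k·x²/2 (unused by the shipped circuits).

**SSA.**  Exact direct method: total propensity a₀ = Σwⱼ, waiting time
~ Exp(a₀), reaction j chosen with probability wⱼ/a₀.  State is recorded
onto a fixed grid by zero-order hold (the state immediately before the
first event past each grid time), which makes replicate trajectories
comparable pointwise.  A vanishing a₀ freezes the remaining grid
(absorbing state), not an error.  Each run owns one explicitly seeded
generator; identical (network, grid, seed) gives a bit-identical
trajectory, and an ensemble with base seed s uses seeds s … s+n−1.  The
inner loop is numba-compiled with a pure-Python fallback implementing
the same algorithm.

**Ensembles** report the pointwise mean and population (ddof = 0)
standard deviation.

## Parameters

Time is seconds; all abundances are molecule counts.  Printed
experimental-condition values are used verbatim:

| quantity | value | role |
|---|---|---|
| k_synPax3mRNA | 0.08 molecules s⁻¹ | Pax3 transcription, high-Pax3 state |
| k_synPax3 | 6.0e-5 s⁻¹ | Pax3 translation, high-Pax3 state |
| Pax3 / Pax3_mRNA | 1000 / 400 | high-Pax3 initial amounts |
| k_synmiR1 | 0.001 s⁻¹ | raised basal miR-1 synthesis (switch scenario) |
| miR-181 / k_synmiR181 | 1000 / 6e-4 s⁻¹ | high-miR-181 state |
| k_degIL6 | 1e-6 s⁻¹ | sustained-IL-6 regime |

Remaining constants follow turnover ranges typical of this model
family: mRNA half-life ≈ 3.9 h (k = 5e-5 s⁻¹), protein ≈ 9.6 h
(2e-5 s⁻¹; Pax3 slightly faster at 2.5e-5 s⁻¹), miRNAs ≈ 4 days
(2e-6 s⁻¹; miR-143 ≈ 19 h so the injury response resolves within the
21-day window).  Binding/unbinding constants are free parameters and
were calibrated — once, against the published qualitative outcomes (low
vs high Pax3 regimes, the 30–50% knock-down window, the switch firing
only with raised basal miR-1, the protein-not-mRNA signature, the
anti-correlation, the IL-6 recovery behaviour, the six integrated-model
effects) — with these anchors:

* miR-1 accumulates slowly at first (weak MyoD:miR-1-gene affinity,
  K ≈ 4e-5 per molecule) so that at 48 h the knock-down sits mid-window,
  while the MyoD-driven steady state is strong enough to hold Pax3
  below 10% of its initial level after the switch;
* repressor:promoter affinities (Pax3 0.2, Hox-A11 0.1 per molecule)
  give near-complete silencing at repressor levels of a few hundred
  molecules and release at a few tens;
* Msc transcript copy number is kept high (≈1000 free at steady state)
  because at a handful of copies the nonlinear miRNA-binding covariance
  visibly biases the stochastic ensemble mean away from the mean-field
  curve, contradicting the observed agreement between average
  stochastic and deterministic behaviour;
* in the integrated model the Msc:miR-1-promoter affinity is weak
  (5e-4 per molecule) so that changing miR-378 transcription moves
  miR-1 visibly (−11% over the scan) while MyoD stays within the <10%
  "no effect" band, matching the reported dissociation.

The full parameter set is embedded in the builders and exported with
`myomirnet models export-table <key>`.

## Scenarios, metrics and bands

Every published simulation experiment is a registry entry (model,
overrides, engine, horizon, metrics); `CLAIM_MANIFEST` maps each
textual claim to the metrics that assert it.  Qualitative language is
quantified once and recorded there: "unaffected/no effect" = relative
change <10%; "slight/modest" = 10–30%; scans report final-time values
on the scenario horizon because several experiments never reach steady
state inside the plotted window.  Scan flatness for miR-143 synthesis
under sustained IL-6 is measured as endpoint spread relative to the
no-IL-6 baseline (spread relative to the tiny leak level would be
meaningless).  Individual-circuit horizons: 48 h for the knock-down
validation, 10 days for the switch and miR-181/miR-378 panels, 21 days
for the IL-6 panels.  The integrated model runs 21 days throughout: its
shared-MyoD feedback plus 4-day miRNA half-lives leave the 10-day state
mid-transient, and the integrated narrative extends past the IL-6
decline.

One readout of the validation horizon: the source text mentions a
five-hour simulation in the same sentence that reports a 48 h readout;
the model documentation treats the five-hour phrase as a typo and runs
48 h, since the readout time is what the data constrain.

## What the tests do and do not show

The suite checks the implementation against independent oracles
(closed-form exponentials, the Poisson stationary and transient laws of
the linear birth–death chain, a symbolic propensity evaluation, the
two-state promoter occupancy), structural invariants (conservation,
validation idempotence, SBML round-trip identity, integrated-model
reduction onto each sub-model at solver tolerance 1e-5 relative), and
the published outcome bands above.  Passing them shows the circuits
reproduce the targeted qualitative biology under *these* calibrated
constants; it does not show parameter identifiability, and none of the
rate constants are fitted to quantitative time-series data — only the
handful of printed condition values are data-anchored.

## Known limitations

* All promoter and binding responses are hyperbolic (single sites, no
  cooperativity), which bounds the feedback loop gain below true
  bistability: the miR-1 "switch" is a sharp monostable transition
  driven by the basal-synthesis parameter, not hysteresis.  One visible
  consequence: in the high-Pax3 state rescued by miR-181 + miR-378 the
  network recovers MyoD only partially within 21 days, so a persistent
  extra miR-1 source ends *higher* than the un-boosted rescue rather
  than merely earlier; the boost scenario therefore asserts the faster
  Pax3 decline and earlier MyoD recovery only.
* IL-6 signalling is abstracted to a single decay constant; the
  receptor/STAT pathway and its feedback are not modelled.
* The miR-143 gene in the integrated model is MyoD-dependent with a
  small basal leak (1e-5 molecules s⁻¹, tunable); strict MyoD
  dependence versus basal activity is not settled by the available
  description.
* Msc repression of the miR-1 and miR-143 genes is modelled as
  promoter competition (mirroring the miR-378 gene) rather than MyoD
  sequestration; either mechanism is compatible with the reported
  effects.
* Deposited SBML reference files are cross-checks only; the package
  builds and runs all models without them, and the importer accepts
  L3V1 plus read-only L2V4 with strict mass-action kinetic laws.
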