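# myomirnet

Kinetic models of microRNA:target-gene networks in adult myogenesis —
a mass-action reaction-network simulator with deterministic (LSODA) and
exact stochastic (Gillespie direct method) engines, shipping five
calibrated regulatory circuits:

| key          | circuit                                               |
|--------------|-------------------------------------------------------|
| `mir1`       | MyoD → miR-1 ⊣ Pax3 ⊣ MyoD (quiescence/differentiation switch) |
| `mir181`     | miR-181 ⊣ Hox-A11 ⊣ MyoD and miR-181 ⊣ Sirt-1 ⊣ FoxO3 → Mafbx (atrophy arm) |
| `mir378`     | MyoD → miR-378 ⊣ Msc, with Msc/MyoD competing at the miR-378 promoter |
| `mir143`     | IL-6 ⊣ miR-143 ⊣ Igfbp5 → IGF2/IGF1-R → pAkt → myogenin |
| `integrated` | all four with one shared MyoD, a two-repressor MyoD gene and Msc repression of the miR-1/miR-143 genes |

## Who this is for

Muscle biologists and modellers asking how individual miRNA:target
interactions (degradation-enhancing vs translation-blocking) combine
into network behaviour during muscle regeneration, and how their
dysregulation with age (low miR-1/-181/-378, chronically high IL-6)
shifts the balance between quiescence, differentiation and atrophy.

## The model

Every circuit is a list of zeroth-, first- and second-order mass-action
reactions over integer molecule counts.  A reaction with rate constant
*k* has propensity *k*, *k·x*, or *k·x·y* (and *k·x(x−1)/2* for a
homodimer).  The same network is either

* integrated as ODEs, d**x**/dt = S **w**(**x**), with LSODA
  (rel. tol 1e-6, abs. tol 1e-13, max step 10⁴ s), or
* sampled exactly with the stochastic simulation algorithm: waiting
  times ~ Exp(Σwⱼ), next reaction chosen ∝ wⱼ.

Genes are explicit single-copy species (free/bound promoter states);
the sum over each gene's states is conserved and equals 1.  miRNA
mechanisms are encoded literally: "enhances degradation" = faster decay
of the miRNA:mRNA complex with the miRNA released intact; "inhibits
translation" = no translation from the complex; "does not enhance
degradation" = the complex decays at the free-mRNA rate constant.

## Worked example

The miR-1 circuit's validation experiment compares a run in which MyoD
induces miR-1 against one with miR-1 absent, reading out Pax3 at 48 h:

```sh
$ myomirnet scenario run mir1_validation --seed 1
{
  "pax3_mrna_reduction_48h_pct": 45.77811242582165,
  "pax3_protein_reduction_48h_pct": 35.88170206475036
}
```

miR-1 removes ~46% of the Pax3 transcript and ~36% of the protein at
48 h — inside the 30–50% window measured when miR-1 is transfected into
Pax3-high cells.  Protein lags transcript because only the transcript
is targeted (the bound mRNA still translates).

The miR-143 circuit under an injury-like IL-6 pulse:

```sh
$ myomirnet scenario run mir143_transient --seed 1
{
  "mir143_baseline": 499.99999999999994,
  "mir143_day21_over_baseline": 0.954345083399488,
  "myogenin_end": 164.06077927005413,
  "recovery_time_days": 16.275
}
```

miR-143 collapses while IL-6 occupies its promoter and regains 90% of
its baseline of 500 molecules after ~16 days — within the 21-day
recovery seen after muscle injury.  With sustained IL-6
(`k_degIL6 = 1e-6 s⁻¹`) it stays below 50% of baseline at day 21.

Other entry points:

```sh
myomirnet scenario list                      # all registered experiments
myomirnet simulate --model mir378 --engine ssa --days 10 --seed 3 --out out/
myomirnet scan --model mir378 --parameter k_binMscmiR378gene \
    --values 5e-7,1e-6,2e-6,4e-6,8e-6 --readouts miR378,Msc_mRNA_total
myomirnet models export-sbml integrated --out integrated.xml
myomirnet models export-table mir1           # reaction table as TSV
```

From Python:

```python
from myomirnet import get_model, simulate_ode, run_ensemble

net = get_model("mir378")
traj = simulate_ode(net, t_end=10 * 86400, n_points=201)
ens = run_ensemble(net, 10 * 86400, n_runs=100, base_seed=1)
```

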