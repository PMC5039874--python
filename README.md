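# anginacea

A decision-analytic cost-utility model for chronic stable angina,
comparing trimetazidine (TMZ, 35 mg b.i.d.) added to standard of care
(SoC) against SoC alone from a third-party-payer perspective (Greek
setting, €2016 prices). The package is aimed at health-economics
practitioners who want the published base case as a tested, scriptable
artifact — and at anyone who needs a small, fully validated Markov
cohort engine with one-way and probabilistic sensitivity analysis.

## The model

Five health states: four angina-severity states defined by episode
frequency (*minimal*, *mild*, *moderate*, *severe*) plus absorbing
*death*. The cohort enters distributed over the symptomatic states and
moves in 3-month cycles over a 1-year horizon (4 cycles, no
discounting):

* **Cycle 1** — survivors transition between severity states according
  to a per-strategy 4×4 matrix (trial-derived, conditional on
  survival). From cycle 2 onwards survivors stay in their state (no
  long-term efficacy data; the 3-month effect is carried forward).
* **Mortality** — state-dependent, treatment-independent. Annual
  probabilities `p` convert to cycle probabilities via the constant
  hazard assumption `p_cycle = 1 − (1 − p)^¼`.
* **Rewards** — occupancy is counted at cycle start; each cycle accrues
  `0.25 ×` utility (QALYs), `annual_cost / 4` per medical category, and
  `3 ×` monthly drug cost on the proportion alive. No half-cycle
  correction.

Strategies are compared by the incremental cost-effectiveness ratio
`ICER = ΔC/ΔE` (€ per QALY gained) against a willingness-to-pay
threshold of €34,000/QALY, with dominance handled explicitly and
decisions under uncertainty framed as net monetary benefit
`NMB = λ·E − C`. Uncertainty analyses:

* **OWSA / tornado** — each parameter varied ±10 % (clinical) or ±20 %
  (cost), ranked by the width of the resulting cost-per-QALY range;
* **rebate scenarios** — both arms' drug prices cut by a volume-rebate
  fraction;
* **PSA** — second-order Monte Carlo (gamma costs, beta
  utilities/mortality, Dirichlet transition rows) with CEAC output.

## Worked example

```bash
$ cea run --out out/
TMZ+SoC: cost EUR 1755.51, QALYs 0.6650, LYs 0.9747
SoC: cost EUR 1751.74, QALYs 0.6562, LYs 0.9743
incremental: cost EUR 3.77, QALYs 0.0088
ICER: EUR 426.62 per QALY -> cost-effective at EUR 34,000/QALY
```

The add-on arm costs €3.77 more per patient-year but yields 0.0088
extra QALYs — about €427 per QALY gained, two orders of magnitude below
the threshold. The small extra drug spend is mostly offset by fewer
hospitalizations and revascularizations in the milder severity mix.

```bash
$ cea owsa --out out/
top-ranked parameter: transition:TMZ+SoC:moderate:mild (spread 3643.14)

$ cea psa --out out/ --n 5000 --seed 1
P(cost-effective at EUR 34,000/QALY) = 0.860
```

The tornado is led by the add-on arm's moderate→mild transition
probability; no one-way endpoint pushes the ICER anywhere near the
threshold. The same library surface is available from Python:

```python
from anginacea import paper_fixture, evaluate_strategy, incremental_analysis

params = paper_fixture()
tmz = evaluate_strategy(params, params.intervention)
soc = evaluate_strategy(params, params.comparator)
print(incremental_analysis(tmz, soc).icer)   # 426.6
```

Custom analyses use the same JSON configuration schema as the packaged
base case (`src/anginacea/data/paper_params.json`); `cea generate`
writes a random, structurally valid example.

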