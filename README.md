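# crc-cea

A Markov cohort cost-effectiveness model of colorectal cancer (CRC)
screening, for health economists and screening-programme analysts.  The
package compares six strategies — no screening, annual/biennial guaiac
fecal occult blood testing (G-FOBT), annual/biennial immunologic FOBT
(I-FOBT), and colonoscopy every 10 years — for a cohort entering at age
50 and followed to 75 in one-year cycles.

## The model in brief

Fourteen health states follow the adenoma–carcinoma sequence: normal
epithelium → low-/high-risk polyp → undiagnosed CRC stages I–IV →
diagnosed CRC I–IV, plus three absorbing death states (CRC, screening
complication, other causes).  Screening overlays natural history each
cycle: participation (60 % routine, 80 % follow-up/surveillance),
test sensitivity/specificity, immediate follow-up colonoscopy after a
positive stool test, polypectomy with 5-yearly (low-risk) or annual
(high-risk) surveillance colonoscopy, perfect colonoscopy accuracy, and
bleeding/perforation risks.

Per strategy the engine accumulates discounted (3.5 %/yr,
half-cycle-corrected) cost *C*, life-years *E*<sub>LY</sub> and
quality-adjusted life-years *E*<sub>QALY</sub> per person.  Strategies
are compared by the incremental cost-effectiveness ratio

> ICER = ΔC / ΔE

with strictly dominated and extended-dominated strategies removed; the
surviving strictly-increasing-ICER chain is the efficiency frontier, and
for a ceiling ratio λ (willingness-to-pay per LY or QALY) the optimal
strategy is the frontier member with the largest ICER ≤ λ.  Uncertainty
is handled by one-way sensitivity analysis, utility-set scenarios, and
probabilistic sensitivity analysis (beta/log-normal draws, 10,000
iterations) summarised as cost-effectiveness acceptability curves.

A note on inputs: the packaged default parameter set (`fixture-hk2009`)
carries every published main-text value (compliance, discounting,
utility scenario sets, strategy definitions, exchange rate) and clearly
flagged *placeholder* values for the natural-history, test-performance
and cost tables, whose published source is a non-public supplement —
fixture runs exercise the machinery and are not a reproduction of the
published base-case tables.  A synthetic-parameter generator
(`synthesize_parameters`) produces random valid parameter sets for
property testing.

## Worked example

```python
from crc_cea import default_parameters, evaluate_strategies, dominance_analysis, optimal_strategy
from crc_cea.reports import render_table1, render_optimal_ranges

params = default_parameters()
outcomes = evaluate_strategies(params)
print(render_table1(list(outcomes.values())).to_string(index=False))
result = dominance_analysis(list(outcomes.values()), measure="qaly")
print("frontier:", " -> ".join(result.frontier))
print(render_optimal_ranges(result)[["interval", "optimal_strategy"]].to_string(index=False))
```

prints (fixture parameters; placeholder-dependent numbers):

```
       strategy  cost_per_person incremental_cost  expected_lys incremental_lys  expected_qalys incremental_qalys
   no_screening            876.0                        16.2473                         15.9832
 biennial_gfobt           1227.0            351.0       16.2675          0.0202         16.0366            0.0534
   annual_gfobt           1500.0            624.0       16.2794          0.0321         16.0731            0.0899
 biennial_ifobt           1204.0            328.0       16.2788          0.0315         16.0761            0.0929
   annual_ifobt           1417.0            541.0       16.2921          0.0448         16.1257            0.1426
colonoscopy_10y           2026.0           1151.0       16.2892          0.0419         16.1652             0.182
frontier: no_screening -> biennial_ifobt -> annual_ifobt -> colonoscopy_10y
     interval optimal_strategy
    [0, 3533]     no_screening
 (3533, 4292]   biennial_ifobt
(4292, 15441]     annual_ifobt
(15441, +inf)  colonoscopy_10y
```

Each row gives the discounted per-person cost, life expectancy and
quality-adjusted life expectancy under that strategy, with increments
versus no screening; the interval table says which strategy maximises
net benefit for each willingness-to-pay range.  On these placeholder
inputs both G-FOBT strategies are dominated and colonoscopy joins the
frontier — on the published inputs the frontier is
no screening → biennial I-FOBT → annual I-FOBT, which the CEA layer
reproduces exactly from the published outcome table (ICERs $2976 and
$3155 per QALY; see the test suite).

The same analyses are available from the shell:

```sh
crc-cea run --out results/
crc-cea scenario --set-name ramsey --out results/
crc-cea ceac --iterations 10000 --seed 1 --out results/
crc-cea validate --out results/
crc-cea synth-params --seed 7 --out my_params.yaml
```

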