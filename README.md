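# rheumcea

Cost-effectiveness modelling of **treat-to-target DMARD sequences for
rheumatoid arthritis** in resource-limited settings, built around a
six-strategy Markov cohort model (Zanzibar base case) with dominance-frontier
construction, deterministic and probabilistic sensitivity analysis, and
drug-price threshold search.

It is written for health economists and rheumatology researchers who want a
tested, scriptable re-implementation of this class of analysis: every stage —
parameter sets, EQ-5D-5L utility derivation, cohort simulation, ICER table,
tornado/PSA/CEAC, price thresholds, price scenarios — is a plain Python
function with CSV/JSON outputs, and a synthetic patient-cohort generator
replaces the clinical dataset so the entire pipeline runs out of the box.

## The model

Patients start on methotrexate with moderate disease activity (CDAI band).
At the end of each 6-month cycle disease activity is reassessed: patients at
the treatment target (remission or low disease activity) stay on their
current drug and remain at target with probability 0.8 per cycle; patients
off target escalate to the strategy's next line — triple therapy
(MTX + sulfasalazine + hydroxychloroquine) and/or one or two
biologic/targeted-synthetic DMARDs — and, once options are exhausted, to
rescue therapy (MTX + low-dose prednisolone), where 43% reach the target and
the rest are categorized off-target for the remaining cycles. Death is an
absorbing state with disease-activity-adjusted background mortality
(multipliers 1.29 / 1.42 for low / moderate-and-high activity).

Over a 3-year horizon (6 cycles) each strategy accrues discounted (3%/year,
cycle-midpoint) costs — drugs, investigations, clinic visits, one-off
diagnosis/bridging and biologic start-up panels — and QALYs from CDAI-band
utilities (0.87 / 0.72 / 0.57 / 0.21) with half-cycle correction. Strategies
are compared by ICERs (Δcost/ΔQALY), absolute/extended dominance and net
monetary benefit NMB = QALYs·WTP − cost at a willingness-to-pay threshold
(282 USD/QALY base case). See `docs/methods.md` for the full specification
and the design choices behind it.

## Worked example

```python
from rheumcea import load_bundled_config, evaluate_all
from rheumcea.frontier import cea_table

config = load_bundled_config("zanzibar")
print(cea_table(evaluate_all(config)))
```

prints (cost-sorted, values rounded):

```
strategy   cost  incremental_cost  qalys  incremental_qalys      icer       classification
       1    672               NaN  1.741                NaN       NaN          on_frontier
       3    816               144  1.814              0.073      1972          on_frontier
       2   1059               243  1.799             -0.015       NaN absolutely_dominated
       4   1150               334  1.826              0.012     28988          on_frontier
       5   3207              2057  1.828              0.002    914691          on_frontier
       6   5289              2082  1.829              0.001   2016057          on_frontier
```

Reading the table: methotrexate monotherapy (strategy 1) costs 672 USD per
patient over three years and yields 1.741 QALYs. Adding a first
biologic/targeted-synthetic DMARD (strategy 3) buys 0.073 extra QALYs for
144 USD — an ICER of ~1,972 USD/QALY, above the 282 USD/QALY threshold, so
methotrexate monotherapy is the cost-effective choice. Strategy 2
(MTX → triple therapy) is *absolutely dominated*: costlier and less
effective than strategy 3. The two-biologic sequences add almost no QALYs at
several thousand dollars, hence the very large frontier ICERs.

The same run from the shell, plus the sensitivity analyses:

```bash
rheumcea run --out results/base               # CEA table + cohort traces
rheumcea run --scenario india --out results/india
rheumcea owsa --pair 1,3 --out results/owsa   # tornado table
rheumcea psa --iterations 10000 --seed 42 --out results/psa
rheumcea ceac --iterations 10000 --seed 42 --out results/ceac
rheumcea threshold --drug btsdmard1 --pair 1,3 --wtp 282
rheumcea synth --n 102 --visits 5 --seed 1 --out results/synth
rheumcea derive-utilities --cohort results/synth/cohort.csv --out results/utils
```

At WTP 282 USD/QALY the PSA (10,000 iterations) leaves strategy 1 optimal in
~98% of draws; raising the threshold toward 2,272 USD/QALY (twice GDP per
capita) shifts the acceptability curve to strategy 3. The price-threshold
search reports the 6-month drug price at which a comparison becomes
cost-effective versus methotrexate — e.g. the first b/tsDMARD would need to
fall from 94 to ≈ 30 USD — and finds no positive threshold price for the
second b/tsDMARD.

## Package layout

| module | contents |
|---|---|
| `rheumcea.parameters` | config schema, validation, YAML I/O, bundled Zanzibar/India/Scandinavia sets, uncertainty registry |
| `rheumcea.utilities` | EQ-5D-5L scoring, CDAI banding, band-utility derivation with bootstrap CIs |
| `rheumcea.synthetic` | synthetic cohort, toy value set and life table generators |
| `rheumcea.engine` | expanded-state Markov cohort engine, cost/QALY accrual, traces |
| `rheumcea.frontier` | ICERs, dominance classification, NMB, CEA table |
| `rheumcea.sensitivity` | distribution fitting, tornado, PSA, CEAC, scatter, price thresholds |
| `rheumcea.cli` | `rheumcea` command-line interface |
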