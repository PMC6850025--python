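# warmgrowth

Detecting gradual, size-dependent warming effects on fish body growth in a
paired heated/reference design.

## The problem

Whole-ecosystem warming experiments are the rare setting where long-term
growth responses of wild, unexploited fish can be separated from background
climate trends.  The canonical case is an enclosed coastal bay receiving
power-plant cooling water, held ~5–10 °C above an adjacent reference area
since 1980, with both perch (*Perca fluviatilis*) populations monitored by
standardized gillnet surveys and aged from winter rings (annuli) in the
operculum bone.  The scientific questions: did body growth change after
warming, was the change immediate (plastic) or gradual, and does it depend
on body size — as the temperature–size rule predicts faster juvenile growth
but smaller adults in the warm?

`warmgrowth` implements the full inference chain for this design, plus an
individual-based simulator so every stage is testable without any data
deposit:

1. **growthsim** — two-area populations with a size-dependent thermal
   performance curve, warming scenarios, gillnet selectivity, female-only
   ageing, and length-stratified subsampling; plus survey catch records for
   the fish community.
2. **backcalc** — operculum annuli and back-calculation of length-at-age
   under the body proportional hypothesis with a power relation
   `L = aR^b`, giving `L_i = L_c (R_i/R_c)^b`.
3. **growthstats** — size-at-age and length-specific growth
   `G_L = (L_{t+1} − L_t)/L_t` within discrete non-overlapping size classes
   (one per age), and annual heated-minus-reference difference series.
4. **bacips** — Progressive-Change BACIPS: least-squares fits of
   step, linear, asymptotic and sigmoid impact-response curves
   `δ_t = β₀ + α·f(t)`, compared by AICc weights ω, with R², an F-test of
   the best model against the constant-difference null, a pre-impact
   stationarity check, and the shared-warming-trend comparison.
5. **community** — CPUE (fish per net per night, first fishing night,
   area-specific survey month), Chord-distance PCoA of the species-by-year
   matrix, and ordination-axis difference series.
6. **pipeline / cli** — a configuration-driven end-to-end runner with
   provenance (seed, config hash, schema-versioned tables).

## Worked example

```python
from warmgrowth import biotest_scenario, run_pipeline

report = run_pipeline(biotest_scenario(seed=1))
print(report.to_text())
```

prints

```
warmgrowth model-selection report
seed=1 config=cee4ba51f1c4
growth coverage: 12 years before onset, 24 after (onset counted as before)
individuals: heated=1155 reference=1226; length-at-age estimates: heated=4645 reference=5072
warming-trend difference: slope=0.0008 degC/yr, F=0.01, p=0.941, r2=0.000

response	best_model	weight_pct	r_squared	p_value	stationarity_ok
size_at_age_1	linear	47.8	0.863	8.242e-16	True
size_at_age_3	linear	53.8	0.828	2.123e-13	True
growth_ageclass_0	asymptotic	51.4	0.871	6.126e-15	True
growth_ageclass_3	step	43.5	0.085	0.1574	True
perch_cpue	step	42.9	0.001	0.8476	True
pco1	sigmoid	99.6	0.876	4.964e-11	True
pco2	sigmoid	60.0	0.568	0.0001325	True
```

Reading the table: the difference in size-at-age 1 and 3 between areas is
best described by a *gradual linear* increase after warming onset
(significant, high R²), the growth of 140–160 mm three-year-olds shows no
significant response (large fish sit near or past their thermal optimum in
the heated area), perch CPUE shows no shift, and the community composition
(first ordination axis) shifts sigmoidally rather than tracking the growth
response — the qualitative fingerprint of a gradual, size-dependent
warming effect on body growth.  The warming-trend row confirms the paired
design's assumption that background warming is shared between areas.

The same run from a shell:

```bash
warmgrowth run-all --seed 1 -o out/
warmgrowth report --report out/report.json
```

All stage outputs are flat delimited-text tables with a schema-version
header, so real survey tables can replace any simulated stage.

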