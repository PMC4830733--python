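# stressdoe

Design-of-experiments tooling for *forced degradation* (stress testing) of
drug substances, built for analytical chemists developing
stability-indicating HPLC assays. Instead of trial-and-error stressing, a
2^k full factorial design varies the stress factors (e.g. acid strength,
temperature, heating time) systematically; `stressdoe` then screens which
factors drive degradation, fits the response polynomial, and inverts it to
find conditions producing a *target* extent of degradation (typically
5–20%, enough to challenge the assay without destroying the sample). The
package also computes the ICH Q2 statistics used to validate the resulting
assay. The built-in worked case is chlorthalidone, a thiazide-like diuretic.

## The model

Each factor is coded so its low/high level maps to −1/+1:
`x = (actual − midpoint) / half-range`. The response (% degradation,
`100·(A_unstressed − A_stressed)/A_unstressed`) over a 2^k design follows the
saturated multilinear polynomial

```
Y = β0 + Σ βj Xj + Σ βij Xi Xj + … + β1..k X1⋯Xk
```

whose least-squares coefficients have closed forms by orthogonality:
`β0 = ΣY/2^k`, `β_term = (column·Y)/2^k`. The **Yates algorithm** (k passes
of pairwise sums/differences over the standard-order response vector) yields
every factorial contrast `c`; from it, effect `E = c/2^(k−1)` (= 2β) and
mean square `MS = c²/2^k`. With no replication, the smallest `p` mean
squares are pooled as the error estimate and each effect is tested by
`F = MS / error_MS` against `F(1, p)`. A **Pareto ranking** normalizes the
squared effects to `100·E²/ΣE²`. Because the polynomial is linear in any
single factor, inverting it for a target response is exact:
`x = (target − a)/b` with the other factors fixed.

Validation statistics: calibration least squares with a linearity ANOVA and
coefficient t-tests; `DL = 3.3σ/S`, `QL = 10σ/S`; recovery regression of
amount found on amount added; and intermediate precision by one-way ANOVA
with day as the grouping factor, `F = BMS/WMS`.

## Worked example

The chlorthalidone acid-degradation study ships with the package
(`stressdoe.datasets`): a 2³ design in HCl strength (0.01/0.1 M),
temperature (55/80 °C) and heating time (30/60 min).

```python
>>> import stressdoe as sd
>>> from stressdoe import datasets
>>> design = datasets.acid_design()
>>> y = datasets.acid_responses()
>>> cfg = sd.ScreeningConfig(yates_rounding="nearest-integer")
>>> table = sd.effects_table(y, cfg)
>>> table.contrasts
array([146.,  -6.,  82.,  -2.,  36.,   4.,  20.,   0.])
>>> sd.f_screen(table, cfg, candidates=["X1", "X2", "X3"])
['X2', 'X3']
>>> model = sd.fit_full_model(design, y)
>>> model.equation_text()
'Y = 18.32 - 0.67X1 + 10.26X2 + 4.56X3 - 0.16X1X2 + 0.44X1X3 + 2.59X2X3 - 0.10X1X2X3'
>>> sd.reduced_r_squared(table, ["X2", "X3"])
0.9462010382255781
>>> cond = sd.choose_condition(model.rounded(2), 10.0, ("X2", "X3"), design=design)
>>> cond.coded_point
(0.0, -1.0, 0.9847715736040608)
>>> cond.actual_point
(0.055, 55.0, 59.77157360406091)
```

Reading: the Yates contrasts say temperature (82) and heating time (36)
dominate; only those two pass the pooled-error F screen at the 1% level,
and a reduced model keeping them carries R² ≈ 0.946 of the effect variance.
Solving the fitted surface for 10% degradation puts the optimum at mid
acid strength (0.055 M HCl), the low temperature (55 °C) and ≈ 60 min of
heating — mild conditions that degrade exactly enough for a specificity
challenge. (The original report of this study prints the acid optimum as
"0.55 M"; the coded midpoint of 0.01–0.1 M decodes to 0.055 M.)

The same workflow is scriptable from the shell:

```
stressdoe screen   --runs runs.csv --factors factors.csv --paper-rounding --out outdir
stressdoe fit      --runs runs.csv --factors factors.csv --significant X2,X3 --out model.json
stressdoe optimize --model model.json --factors factors.csv --target 10 \
                   --active X2,X3 --paper-rounding --out optimum.json
stressdoe simulate --kind factorial --seed 7 --out simdir
```

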