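# plantforward

Sustainability scoring of hospital in-patient menus.

Food services are a substantial share of healthcare's carbon footprint, and
shifting standard in-patient menus towards plant-forward provision — more
vegan and vegetarian dishes, less ruminant and processed meat, and choice
architecture ("nudging") that makes the plant-based option the easy one —
is one of the few levers a hospital controls directly. `plantforward` is a
reusable implementation of a composite-indicator audit for exactly that
question, aimed at dietitians, sustainability officers and food-environment
researchers who want to score, rank and monitor menus consistently.

## The scoring model

A menu is scored on 14 indicators, each on a 0–100 scale, grouped into
three dimensions:

| dimension | indicator | values | weight |
|---|---|---|---|
| main meals | vegan main every day, lunch / dinner ("base offer") | 0 / 100 | 0.5 + 0.5 |
| | % vegan mains, lunch / dinner | 0–100 | 1 + 1 |
| | % vegetarian mains, lunch / dinner | 0–100 | 0.5 + 0.5 |
| | ruminant-avoidance score, lunch / dinner | 0–100 | 0.5 + 0.5 |
| smaller meals | % vegan / % vegetarian smaller meals | 0–100 | 2 + 1 |
| menu presentation | environmental-impact descriptors | 0 / 50 / 100 | 1 |
| | vegan options positioned first | 0 / 100 | 1 |
| | positive labels ("plant-rich", …) on plant dishes | 0 / 50 / 100 | 0.5 |
| | no negative labels ("vegan", "vegetarian", "meat-free") | 0 / 50 / 100 | 0.5 |

Each dimension's **subscore** is the weighted mean of its *present*
indicators,

```
S_g = Σ_i w_i x_i / Σ_i w_i          (i over present indicators of group g)
```

computed only when the present indicators carry at least half of the
group's total weight; otherwise the subscore is missing.  Missing is a
first-class value throughout — an unassessable smaller-meals section yields
missing indicators, never zeros.  The **final score** is the weighted mean
of the subscores with weights 3 (main meals), 1 (smaller meals) and
2 (menu presentation), renormalized over present subscores.

The ruminant-avoidance score maps the percentage `r` of mains free of
beef/lamb/goat through `max(0, 3r − 200)`: 100 for a ruminant-free slot,
exactly 0 once a third or more of mains contain ruminant meat.  Label
indicators use a 20 % regular-use threshold over all vegan/vegetarian
dishes.  Cyclical menus are truncated to their first week before scoring;
à-la-carte menus are assessed in full, with the standing menu treated as
available daily.

Dietary annotations can be supplied in the menu file (manual coding) or
derived from dish names by a configurable whole-word lexicon; file-supplied
codes always win.

## Worked example

```python
import plantforward as pf

example = pf.worked_example_menu()     # 7-day menu, 28 mains + 4 smaller meals
report = pf.score_menu(example.menu)
print({k: round(v, 2) for k, v in report.subscores.items()})
print(round(report.final, 1))
```

prints

```
{'main_meals': 80.0, 'smaller_meals': 66.67, 'menu_presentation': 0.0}
51.1
```

The menu offers a vegan main every day at lunch and dinner (base offers
100), half of its mains are vegan and all are vegetarian with no ruminant
meat, so the main-meals subscore is
(0.5·100·2 + 1·50·2 + 0.5·100·2 + 0.5·100·2)/5 = **80**.  Its smaller meals
are half vegan and all vegetarian: (2·50 + 1·100)/3 = **66.67**.  Every
plant dish is tagged "vegan"/"vegetarian", nothing is positioned first or
positively labelled, and there is no environmental messaging, so menu
presentation is **0**.  The final score is
(3·80 + 1·66.67 + 2·0)/6 = **51.1** — a menu with strong provision but no
nudging loses a third of the attainable score.

## Command line

```bash
plantforward simulate --out cohort/ --n 36 --seed 1     # synthetic cohort + ground truth
plantforward validate cohort/                           # schema + invariant checks
plantforward score cohort/ --out scores/                # per-menu reports + CSV
plantforward cohort cohort/ --out summary/ --figures    # ranked table, histograms,
                                                        # provider comparison, prevalence
```

Menus are plain JSON (schema via `plantforward validate --emit-schema`) or
a flat CSV dialect with a JSON sidecar.  All tunables (ruminant mapping,
label threshold, weights, lexicon, final-score renormalization) take a YAML
config file with CLI overrides, and the effective configuration is embedded
in every output directory.

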