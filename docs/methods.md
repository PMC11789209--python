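# Methods

This note records the model implemented by `plantforward`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's numerical conventions.

## Scope and assumptions

The unit of assessment is one hospital's *standard* in-patient menu — the
default offering served without a special request.  Only lunch mains,
dinner mains and smaller meals (sandwiches, soups, jacket potatoes, salads,
lighter-appetite options) are assessed; starters and desserts are out of
scope, as are specialised diet menus, portion sizes, recipe-level meat
reduction, nutritional adequacy and any carbon-emission quantification.
Cyclical menus (repeating on a 1–4 week cycle) are truncated to days 1–7
before scoring, on the assumption that the first week is representative;
à-la-carte menus are standing menus and are assessed whole, with every item
treated as available daily.

Vegan dishes are counted as a subset of vegetarian dishes everywhere — the
standard convention; the vegetarian percentages therefore include vegan
dishes.

## Indicators

Fourteen indicators on a 0–100 scale, in three groups (weights in
parentheses):

- **main meals (total weight 5)** — daily vegan base offer per slot
  (0/100; 0.5 each), % vegan mains per slot (1 each), % vegetarian mains
  per slot (0.5 each), ruminant-avoidance per slot (0.5 each);
- **smaller meals (3)** — % vegan (2), % vegetarian (1);
- **menu presentation (3)** — environmental descriptors (0/50/100; 1),
  vegan positioned first (0/100; 1), positive labels (0/50/100; 0.5), no
  negative labels (0/50/100; 0.5).  The two label indicators deliberately
  carry 0.5 each so labelling as a dimension weighs 1.

Open points resolved as package decisions:

- **Ruminant mapping.**  The default maps the ruminant-free percentage `r`
  through `max(0, 3r − 200)`, i.e. 100 at no ruminant mains falling
  linearly to 0 at one third ruminant mains.  A plain identity mapping
  (`score = r`) could never produce a zero score on a bounded menu, which
  contradicts the observed behaviour of the scale on real cohorts; the
  linear clamp is the simplest bounded map with the documented zero point.
  `identity` remains available via `ExtractionOptions(ruminant_mapping=...)`.
- **Base offer, à la carte.**  "Every day" is read as *at least one
  qualifying item on the standing menu*, since the whole menu is available
  daily.  A repeated vegan dish satisfies the daily base offer; distinct
  dishes are not required.
- **Positioning.**  Scored 100 only when position 1 of *every* main
  (day, slot) section is vegan.  The strict reading keeps the indicator
  meaningful as a deliberate layout policy rather than an accident of one
  section.
- **Label threshold.**  Label use is measured over all vegan + vegetarian
  dishes (mains and smaller meals).  Exactly 20 % falls in the
  "sometimes" (50-point) band; "regular" requires strictly more than the
  threshold.  The 20 % default is configurable.
- **Environmental descriptors.**  100 requires menu-wide messaging (a
  menu-level flag); messaging on some items/sections only scores 50;
  explicit absence scores 0; if every flag is unknown the indicator is
  missing.

## Missing data

Missing is a first-class value (`None`/NaN), distinct from 0, produced
when: a slot has no mains, the smaller-meals section is absent or
ward-based (unassessable), the menu has no plant dishes (label indicators),
or all messaging flags are unknown.  A subscore excludes missing
indicators and is computed only when the present indicators carry at least
half of the group's weight — the threshold is inclusive, so exactly half
suffices.  The final score renormalizes the 3/1/2 weights over present
subscores (the same principle applied between groups as within them); a
strict mode (`renormalize_final=False`) propagates any missing subscore
instead.  Both behaviours are exposed because the treatment of hospitals
with unassessable smaller meals is genuinely underdetermined.

## Numerical conventions

Internal arithmetic is full double precision; reported scores are rounded
half-away-from-zero to integers (configurable digits).  Boundary cases are
decided on integer numerators, not floats: the ruminant clamp uses
`(300·without − 200·n)/n` so a slot with exactly one third ruminant mains
scores exactly 0, and label bands compare `100·labelled` against
`threshold·dishes`.  Ranking ties break by main-meals subscore, then
hospital identifier (deterministic); histogram bins are half-open with the
top bin closed at 100.  Scoring contains no randomness.

## Dish-name classification

The lexicon classifier emulates manual coding for short British menu
prose: lowercase, hyphens/slashes split to spaces, whole-word matching,
multi-word terms matched as phrases ("corned beef" consumes its tokens
before bare-token categories; the `beef` token still marks the dish
ruminant).  A dish is omnivorous if any meat/fish term matches, otherwise
vegetarian if any dairy/egg/honey marker matches, otherwise vegan.  The
token `vegetarian` is itself an animal-product marker: a dish a menu
prints as "Vegetarian …" rather than "Vegan …" conventionally contains
dairy or egg.  Keyword matching cannot fully replicate human coding, so
file-supplied annotations always override derived ones; the lexicon is a
reproducibility aid, shipped as editable YAML.

## Synthetic cohorts

The generator emulates the structure of audited menu cohorts: 7-day
cyclical menus (one quarter on 2-week cycles, exercising truncation), 3–5
mains per slot, a standing smaller-meals list, a provider mix of
17 in-house / 14 contracted / 3 mixed / 2 unknown per 36 hospitals
(largest-remainder scaled, exactly preserved), and smaller-meals
availability 31 listed / 2 ward-based / 3 not listed.  Default per-hospital
parameter draws encode sparse vegan provision (about half of hospitals
offering no vegan mains), vegetarian shares of 15–45 %, ruminant marginals
of 8–40 %, a ~9 % per-main processed-meat marginal with a sausage-heavy
category mix (giving roughly 4–5 processed mains per menu), frequent
negative labelling, rare positive labelling, and rare environmental
messaging or vegan-first positioning.  Dish names come from template pools
that round-trip through the default lexicon; annotations are left
underived so the classifier sits on the generator's hot path and
regressions surface immediately.

Exact-count mode fixes per-day class counts and computes the ground-truth
indicator vector analytically (processed dishes are drawn from non-ruminant
categories there, so ruminant counts stay analytic); probabilistic mode
provides closed-form expectations for the percentage indicators (ruminant
under the identity mapping — the clamp's mean has no closed form).  A
`category_prevalence` override converts per-dish sampling into independent
menu-level Bernoulli inclusion of each processed-meat category, making
cohort prevalences exact binomial proportions.  Randomness fans out from
one root seed via `numpy.random.SeedSequence` (one stream per hospital), so
cohorts are byte-identical across runs and platforms.

What the generator does *not* emulate: realistic menu prose beyond what
classification needs, seasonal rotation, correlated day-to-day structure
(each dish is drawn independently), allergen/nutrition content, and
ward-level service variation.  Passing tests therefore demonstrate that
the pipeline is correct on schema-valid, lexicon-consistent menus — not
that the lexicon would code an arbitrary real menu the way a human auditor
would.

## Monotonicity caveat

Replacing an omnivorous main with a vegan main weakly improves every
provision indicator, but the label indicators are ratios over plant dishes:
adding an *unlabelled* plant dish can push the positive-label share from
just above to just below the regular-use threshold and drop that indicator
a band.  The monotonicity guarantee (and its test) therefore applies to
best-practice substitutions — the incoming dish carries a positive label
and no negative label — under which every indicator, subscore and the
final score is provably non-decreasing.

## Problem sizes

The verification suite uses 1,000 random indicator vectors against a
brute-force aggregation oracle (tolerance 1e-9), exhaustive enumeration of
ruminant compositions up to 12 mains and all 2^8 main-group missingness
patterns, 200 menus for substitution monotonicity, cohorts of 36 for
study-conditions descriptives and 500 for expectation/prevalence recovery
(3-standard-error and binomial-95 % checks respectively).  These sizes make
the statistical checks sharp while keeping the whole suite and the
acceptance script comfortably fast on one CPU.
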