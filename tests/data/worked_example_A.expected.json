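{
  "note": "hand-computed expected values for the worked example menu",
  "indicators": {
    "base_offer_lunch": 100.0,
    "base_offer_dinner": 100.0,
    "pct_vegan_lunch": 50.0,
    "pct_vegan_dinner": 50.0,
    "pct_vegetarian_lunch": 100.0,
    "pct_vegetarian_dinner": 100.0,
    "ruminant_free_lunch": 100.0,
    "ruminant_free_dinner": 100.0,
    "pct_vegan_smaller": 50.0,
    "pct_vegetarian_smaller": 100.0,
    "env_descriptors": 0.0,
    "vegan_first": 0.0,
    "positive_labels": 0.0,
    "no_negative_labels": 0.0
  },
  "subscores": {
    "main_meals": 80.0,
    "smaller_meals": 66.66666666666667,
    "menu_presentation": 0.0
  },
  "final": 51.111111111111114
}
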