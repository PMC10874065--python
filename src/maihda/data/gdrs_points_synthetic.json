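{
  "name": "gdrs-points-synthetic-v1",
  "provenance": "SYNTHETIC stand-in point table. The German Diabetes Risk Score (updated, simplified categorical version) assigns integer points to ten non-invasively assessed risk factors; the published point assignments are not redistributed here. This table reproduces the published structure exactly -- the same ten components, categorical form, a minimum achievable total of 0 and a maximum of 122 -- with point values chosen to be epidemiologically plausible. Replace via configuration with a transcription of the official table for substantive use.",
  "max_total": 122,
  "components": {
    "age": {
      "type": "numeric",
      "unit": "years",
      "domain": [18, 120],
      "categories": [
        {"label": "18-<35", "min": 18, "max": 35, "points": 0},
        {"label": "35-<45", "min": 35, "max": 45, "points": 5},
        {"label": "45-<55", "min": 45, "max": 55, "points": 10},
        {"label": "55-<65", "min": 55, "max": 65, "points": 15},
        {"label": ">=65", "min": 65, "max": 120, "points": 19}
      ]
    },
    "waist_cm": {
      "type": "numeric",
      "unit": "cm",
      "domain": [40, 250],
      "categories": [
        {"label": "<75", "min": 40, "max": 75, "points": 0},
        {"label": "75-<80", "min": 75, "max": 80, "points": 4},
        {"label": "80-<85", "min": 80, "max": 85, "points": 8},
        {"label": "85-<90", "min": 85, "max": 90, "points": 11},
        {"label": "90-<95", "min": 90, "max": 95, "points": 15},
        {"label": "95-<100", "min": 95, "max": 100, "points": 19},
        {"label": "100-<105", "min": 100, "max": 105, "points": 23},
        {"label": "105-<110", "min": 105, "max": 110, "points": 26},
        {"label": ">=110", "min": 110, "max": 250, "points": 30}
      ]
    },
    "height_cm": {
      "type": "numeric",
      "unit": "cm",
      "domain": [120, 230],
      "categories": [
        {"label": "<165", "min": 120, "max": 165, "points": 10},
        {"label": "165-<175", "min": 165, "max": 175, "points": 7},
        {"label": "175-<185", "min": 175, "max": 185, "points": 3},
        {"label": ">=185", "min": 185, "max": 230, "points": 0}
      ]
    },
    "hypertension": {
      "type": "categorical",
      "categories": [
        {"label": "no", "points": 0},
        {"label": "yes", "points": 7}
      ]
    },
    "smoking": {
      "type": "categorical",
      "categories": [
        {"label": "never_or_former_lt20", "points": 0},
        {"label": "current_lt20", "points": 4},
        {"label": "former_ge20", "points": 8},
        {"label": "current_ge20", "points": 11}
      ]
    },
    "physical_activity_5h": {
      "type": "categorical",
      "categories": [
        {"label": "yes", "points": 0},
        {"label": "no", "points": 5}
      ]
    },
    "coffee_cups_per_day": {
      "type": "numeric",
      "unit": "cups/day",
      "domain": [0, 50],
      "categories": [
        {"label": "0", "min": 0, "max": 1, "points": 6},
        {"label": "1-<5", "min": 1, "max": 5, "points": 3},
        {"label": ">=5", "min": 5, "max": 50, "points": 0}
      ]
    },
    "wholegrain_portions_per_day": {
      "type": "numeric",
      "unit": "portions/day",
      "domain": [0, 30],
      "categories": [
        {"label": "<0.5", "min": 0, "max": 0.5, "points": 5},
        {"label": "0.5-<2", "min": 0.5, "max": 2, "points": 3},
        {"label": ">=2", "min": 2, "max": 30, "points": 0}
      ]
    },
    "red_meat": {
      "type": "categorical",
      "categories": [
        {"label": "lt1_per_week", "points": 0},
        {"label": "1_6_per_week", "points": 5},
        {"label": "daily", "points": 10},
        {"label": "gt1_per_day", "points": 15}
      ]
    },
    "family_history": {
      "type": "categorical",
      "categories": [
        {"label": "none", "points": 0},
        {"label": "one_parent", "points": 7},
        {"label": "sibling", "points": 8},
        {"label": "both_parents", "points": 11},
        {"label": "parent_and_sibling", "points": 14}
      ]
    }
  }
}
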