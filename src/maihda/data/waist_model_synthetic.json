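{
  "name": "waist-estimation-synthetic-v1",
  "provenance": "SYNTHETIC stand-in. Waist circumference is not asked in telephone surveys and is instead predicted from self-reported height, weight and age with separate linear equations per sex, estimated in an external examination survey. The published coefficients are not redistributed here; these values are chosen to give anthropometrically plausible, strictly positive predictions over the declared adult input domain. Replace via configuration for substantive use.",
  "unit": "cm",
  "bounds": {
    "height_cm": [130, 220],
    "weight_kg": [30, 250],
    "age": [18, 110]
  },
  "coefficients": {
    "male":   {"intercept": 56.0, "height_cm": -0.25, "weight_kg": 0.90, "age": 0.13},
    "female": {"intercept": 60.0, "height_cm": -0.27, "weight_kg": 0.85, "age": 0.14}
  }
}
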