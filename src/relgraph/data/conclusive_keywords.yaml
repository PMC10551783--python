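# Editable default rule set for the conclusive-language credibility filter.
# Matching is case-insensitive on word-boundary stems.
date_window: ["2022-06-01", "2023-06-01"]
attention_above_mean: true
conclusive_keywords:
  - conclude
  - demonstrate
  - show
  - confirm
  - improve
  - reduce
  - effective
  - efficacious
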