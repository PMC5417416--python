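# Example experiment configuration for `ictalsheet simulate --config ...`
kind: onset_demo
preset: HAS
duration: 7000.0
geometry:
  n_rows: 60
  n_cols: 60
  macro_size: 10
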