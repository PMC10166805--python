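name: detector_eval
seed: 3
steps:
- bindings:
    field_height:
      kind: manual
      value: 256
    field_width:
      kind: manual
      value: 256
    n_cells:
      kind: manual
      value: 80
  module: generate_ground_truth
- bindings:
    detection_prob:
      kind: manual
      value: 0.85
    ground_truth:
      kind: pipe
      source_output: ground_truth
      source_step: 0
    n_false_positives:
      kind: manual
      value: 15
  module: simulate_detector
- bindings:
    detected:
      kind: pipe
      source_output: detected
      source_step: 1
    reference:
      kind: pipe
      source_output: ground_truth
      source_step: 0
    threshold:
      kind: runtime
      prompt_key: threshold
  module: evaluate
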