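name: consensus_demo
seed: 7
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
      value: 40
  module: generate_ground_truth
- bindings:
    ground_truth:
      kind: pipe
      source_output: ground_truth
      source_step: 0
    n_false_positives:
      kind: manual
      value: 10
  module: simulate_detector
- bindings:
    ground_truth:
      kind: pipe
      source_output: ground_truth
      source_step: 0
    n_false_positives:
      kind: manual
      value: 10
  module: simulate_detector
- bindings:
    set_a:
      kind: pipe
      source_output: detected
      source_step: 1
    set_b:
      kind: pipe
      source_output: detected
      source_step: 2
    threshold:
      kind: runtime
      prompt_key: threshold
  module: match_rois
- bindings:
    detected:
      kind: pipe
      source_output: consensus
      source_step: 3
    reference:
      kind: pipe
      source_output: ground_truth
      source_step: 0
    threshold:
      kind: runtime
      prompt_key: threshold
  module: evaluate
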