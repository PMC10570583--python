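goal: "US driving risks 2019"
severity: us2019_severity.csv
evidence: us2019_evidence.csv
criteria_pcm:
  labels: [C1, C2, C3]
  entries:
    - ["1", "1/4", "1/5"]
    - ["4", "1", "1"]
    - ["5", "1", "1"]
criteria:
  - name: C1
    title: Environment
    evidence_group: environment
  - name: C2
    title: Driver State
    evidence_group: driver_state
  - name: C3
    title: Driver Behavior
    evidence_group: driver_behavior
quantizer:
  ceil_threshold: 0.25
method: eigen
strict_cr: false
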