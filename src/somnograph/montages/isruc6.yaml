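# Six-channel ISRUC-style EEG montage (reference suffixes stripped).
# Edges connect physically neighboring 10-20 sites.
name: isruc6
labels: [F3, F4, C3, C4, O1, O2]
edges:
  - [F3, F4]
  - [F3, C3]
  - [F4, C4]
  - [C3, C4]
  - [C3, O1]
  - [C4, O2]
  - [O1, O2]
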