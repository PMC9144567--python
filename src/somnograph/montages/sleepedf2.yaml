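# Two bipolar derivations of the sleep-EDF recordings.
name: sleepedf2
labels: [Fpz-Cz, Pz-Oz]
edges:
  - [Fpz-Cz, Pz-Oz]
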