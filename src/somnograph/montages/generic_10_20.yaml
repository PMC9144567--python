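# Neighbor edges among common 10-20 electrode sites: left-right pairs
# plus anterior-posterior chains.  Used to derive adjacency for custom
# montages whose labels are canonical 10-20 sites.
name: generic_10_20
labels: [Fp1, Fpz, Fp2, F7, F3, Fz, F4, F8, T3, C3, Cz, C4, T4,
         T5, P3, Pz, P4, T6, O1, Oz, O2]
edges:
  - [Fp1, Fpz]
  - [Fpz, Fp2]
  - [Fp1, Fp2]
  - [Fp1, F7]
  - [Fp1, F3]
  - [Fpz, Fz]
  - [Fp2, F4]
  - [Fp2, F8]
  - [F7, F3]
  - [F3, Fz]
  - [Fz, F4]
  - [F4, F8]
  - [F3, F4]
  - [F7, T3]
  - [F3, C3]
  - [Fz, Cz]
  - [F4, C4]
  - [F8, T4]
  - [T3, C3]
  - [C3, Cz]
  - [Cz, C4]
  - [C4, T4]
  - [C3, C4]
  - [T3, T5]
  - [C3, P3]
  - [Cz, Pz]
  - [C4, P4]
  - [T4, T6]
  - [T5, P3]
  - [P3, Pz]
  - [Pz, P4]
  - [P4, T6]
  - [P3, P4]
  - [T5, O1]
  - [P3, O1]
  - [Pz, Oz]
  - [P4, O2]
  - [T6, O2]
  - [O1, Oz]
  - [Oz, O2]
  - [O1, O2]
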