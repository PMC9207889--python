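# Plausible large-conductance K+ channel-like scheme: three open
# (O1-O3) and five closed (C4-C8) substates.  Mean dwells (ms):
# O1=2, O2=5, O3=10, C4=1, C5=3, C6=8, C7=20, C8=50.  Connectivity is a
# loosely chained manifold with open/closed gateways at O1/C4, O2/C5 and
# O3/C6; rates are illustrative, not fitted to any recording.
initial_state: O1
substates:
  O1: O
  O2: O
  O3: O
  C4: C
  C5: C
  C6: C
  C7: C
  C8: C
rates:
  O1: {O2: 0.2, C4: 0.3}
  O2: {O1: 0.1, O3: 0.05, C5: 0.05}
  O3: {O2: 0.05, C6: 0.05}
  C4: {O1: 0.7, C5: 0.3}
  C5: {C4: 0.2, C6: 0.1, O2: 0.033333333333333333}
  C6: {C5: 0.075, C7: 0.04, O3: 0.01}
  C7: {C6: 0.03, C8: 0.02}
  C8: {C7: 0.02}
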