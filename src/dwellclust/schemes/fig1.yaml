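# Five-substate toy gating scheme used throughout the documentation.
# Mean dwells (time units): C5=5, O3=1, O4=3, C6=3, C7=9.
# Routing makes the O3->O4 open route (observed dwell 4) and the C6->C7
# closed composite (observed dwell 12) dominant: p(O3->O4)=0.85,
# p(C6->C7)=0.90, p(C7->O3)=0.90.
initial_state: C5
substates:
  C5: C
  O3: O
  O4: O
  C6: C
  C7: C
rates:
  C5: {O3: 0.2}
  O3: {O4: 0.85, C6: 0.15}
  O4: {C7: 0.3333333333333333}
  C6: {C7: 0.3, O3: 0.033333333333333333}
  C7: {O3: 0.1, C6: 0.011111111111111112}
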