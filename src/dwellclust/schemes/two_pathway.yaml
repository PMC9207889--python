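# Two weakly coupled gating pathways for parameter-recovery experiments.
# Every dwell is a multi-stage hypoexponential (sequential substates of
# equal rate), which narrows the dwell coefficient of variation so the
# pathway mean triples stay recoverable from cluster templates.  The
# pathways differ in *shape*, not just scale, because cross-correlation
# is amplitude invariant: pathway A pairs short openings with long
# closures, pathway B the reverse.
#   Pathway A: open 3 x 1/3 = 1 ms, closed 3 x 20/3 = 20 ms
#              -> O-C-O mean triple (1, 20, 1)
#   Pathway B: open 3 x 8/3 = 8 ms, closed 6 x 1/3 = 2 ms
#              -> O-C-O mean triple (8, 2, 8)
# Cross-links carry probability 0.02 per closed cycle.
initial_state: Oa1
substates:
  Oa1: O
  Oa2: O
  Oa3: O
  Ca1: C
  Ca2: C
  Ca3: C
  Ob1: O
  Ob2: O
  Ob3: O
  Cb1: C
  Cb2: C
  Cb3: C
  Cb4: C
  Cb5: C
  Cb6: C
rates:
  Oa1: {Oa2: 3.0}
  Oa2: {Oa3: 3.0}
  Oa3: {Ca1: 3.0}
  Ca1: {Ca2: 0.15}
  Ca2: {Ca3: 0.15}
  Ca3: {Oa1: 0.147, Ob1: 0.003}
  Ob1: {Ob2: 0.375}
  Ob2: {Ob3: 0.375}
  Ob3: {Cb1: 0.375}
  Cb1: {Cb2: 3.0}
  Cb2: {Cb3: 3.0}
  Cb3: {Cb4: 3.0}
  Cb4: {Cb5: 3.0}
  Cb5: {Cb6: 3.0}
  Cb6: {Ob1: 2.94, Oa1: 0.06}
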