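# Reference canonical-Wnt step protocol: the pathway starts off, is switched
# on at 4000 min (Wnt -> 1 nM) and back off at 15000 min. Times in minutes,
# concentrations in nM.
t_start: 0.0
t_end: 26000.0
events:
  - {time: 4000.0,  species: Wnt, value: 1.0}
  - {time: 15000.0, species: Wnt, value: 0.0}
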