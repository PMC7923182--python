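# The eight-condition input matrix for the integrated Wnt/RhoA-ROCK model.
#
# Conditions 1-4: RhoA-ROCK driven on (RhoGEF = 100 nM, RhoGAP = 0).
# Conditions 5-8: RhoA-ROCK driven off (RhoGAP = 100 nM, RhoGEF = 0).
# Within each panel, canonical Wnt (1 nM when on) and Wnt5b (100 nM when
# present) are combined. Condition 7 includes Wnt5b: with both pathways
# nominally off it retains residual Rho activity through the Wnt5b-Daam1
# route. All inputs are constant boundary conditions; units nM.
conditions:
  - {label: 1, wnt: 1.0, wnt5b: 0.0,   rhogef: 100.0, rhogap: 0.0}
  - {label: 2, wnt: 1.0, wnt5b: 100.0, rhogef: 100.0, rhogap: 0.0}
  - {label: 3, wnt: 0.0, wnt5b: 100.0, rhogef: 100.0, rhogap: 0.0}
  - {label: 4, wnt: 0.0, wnt5b: 0.0,   rhogef: 100.0, rhogap: 0.0}
  - {label: 5, wnt: 1.0, wnt5b: 0.0,   rhogef: 0.0,   rhogap: 100.0}
  - {label: 6, wnt: 1.0, wnt5b: 100.0, rhogef: 0.0,   rhogap: 100.0}
  - {label: 7, wnt: 0.0, wnt5b: 100.0, rhogef: 0.0,   rhogap: 100.0}
  - {label: 8, wnt: 0.0, wnt5b: 0.0,   rhogef: 0.0,   rhogap: 100.0}
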