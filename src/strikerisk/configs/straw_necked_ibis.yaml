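# Default network structure for a volatile flocking species whose presence
# tracks food availability more than season (Straw-necked Ibis pattern).
nodes:
  - {name: Season, states: [low, medium, high], discretisation: quantile}
  - {name: Temperature, states: [low, medium, high], discretisation: quantile}
  - {name: Rain, states: [low, medium, high], discretisation: quantile}
  - {name: Observed Count, states: [low, medium, high], discretisation: quantile}
  - {name: Zone Population, states: [low, medium, high], discretisation: quantile}
  - {name: All Population, states: [low, medium, high], discretisation: quantile}
  - {name: Aircraft Movement, states: [low, medium, high], discretisation: quantile}
  - {name: Likelihood, states: [low, medium, high], discretisation: quantile}
edges:
  - {parent: Season, child: Temperature}
  - {parent: Season, child: Rain}
  - {parent: Rain, child: All Population}
  - {parent: All Population, child: Observed Count}
  - {parent: Observed Count, child: Zone Population}
  - {parent: Observed Count, child: Likelihood}
  - {parent: Zone Population, child: Likelihood}
  - {parent: Aircraft Movement, child: Likelihood}
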