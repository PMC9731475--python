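# Default network structure for a migratory hazard species (Cattle Egret
# pattern).  Season drives weather and the migratory/breeding behaviour that
# sets how many birds are present; the likelihood of a collision depends on
# how many birds are observed, how many sit in the runway-adjacent zones,
# and how much traffic is moving.
nodes:
  - {name: Season, states: [low, medium, high], discretisation: quantile}
  - {name: Temperature, states: [low, medium, high], discretisation: quantile}
  - {name: Rain, states: [low, medium, high], discretisation: quantile}
  - {name: Seasonal Behaviour, states: [low, medium, high], discretisation: quantile}
  - {name: Observed Count, states: [low, medium, high], discretisation: quantile}
  - {name: Zone Population, states: [low, medium, high], discretisation: quantile}
  - {name: All Population, states: [low, medium, high], discretisation: quantile}
  - {name: Aircraft Movement, states: [low, medium, high], discretisation: quantile}
  - {name: Likelihood, states: [low, medium, high], discretisation: quantile}
edges:
  - {parent: Season, child: Seasonal Behaviour}
  - {parent: Season, child: Temperature}
  - {parent: Season, child: Rain}
  - {parent: Seasonal Behaviour, child: Observed Count}
  - {parent: All Population, child: Observed Count}
  - {parent: Observed Count, child: Zone Population}
  - {parent: Observed Count, child: Likelihood}
  - {parent: Zone Population, child: Likelihood}
  - {parent: Aircraft Movement, child: Likelihood}
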