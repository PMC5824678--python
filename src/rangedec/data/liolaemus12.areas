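# Twelve biogeographic provinces of southern South America (codes A-L).
# Adjacency derived from the Matrix II dispersal-cost table: a pair of areas
# is adjacent iff its dispersal multiplier is 0.8 (the adjacent-pair value).
areas:
  - A  Desierto Peruano Costero
  - B  Puna
  - C  Yungas
  - D  Atacama
  - E  Coquimbo
  - F  Prepuna
  - G  Monte
  - H  Chaco
  - I  Pampa
  - J  Santiago
  - K  Maule
  - L  Patagonia Central
adjacency:
  - 1 1 0 1 0 0 0 0 0 0 0 0
  - 1 1 1 1 1 1 1 1 0 0 0 0
  - 0 1 1 0 0 0 0 1 0 0 0 0
  - 1 1 0 1 1 0 0 0 0 0 0 0
  - 0 1 0 1 1 1 0 0 0 0 0 0
  - 0 1 0 0 1 1 1 0 0 1 0 1
  - 0 1 0 0 0 1 1 1 1 0 0 1
  - 0 1 1 0 0 0 1 1 1 0 0 0
  - 0 0 0 0 0 0 1 1 1 0 0 1
  - 0 0 0 0 0 1 0 0 0 1 1 1
  - 0 0 0 0 0 0 0 0 0 1 1 1
  - 0 0 0 0 0 1 1 0 1 1 1 1
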