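# Wall-material harmonization into the shared binary poor_walls codebook:
# 1 = inadequate material, 0 = finished/good material.
variable: poor_walls
source: survey
default: error
mapping:
  "no walls": 1
  "natural walls": 1
  "cane/palm/trunks": 1
  "dirt": 1
  "cardboard": 1
  "reused wood": 1
  "uncovered adobe": 1
  "bamboo with mud": 1
  "plywood": 1
  "cement": 0
  "stone with lime/cement": 0
  "stone with mud": 0
  "bricks": 0
  "cement blocks": 0
  "covered adobe": 0
---
variable: poor_walls
source: census
default: error
mapping:
  "guadua": 1
  "rough wood": 1
  "board": 1
  "plank": 1
  "cane": 1
  "mat": 1
  "other vegetation": 1
  "no walls": 1
  "waste materials": 1
  "block, brick, stone": 0
  "polished wood": 0
  "poured concrete": 0
  "rammed earth": 0
  "bahareque": 0
  "covered adobe": 0
  "prefabricated material": 0
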