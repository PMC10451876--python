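# Default ecological-resistance classification for Asian-elephant dispersal.
# Four factors; class intervals are lower-closed, upper-open ([a, b)).
# Land-use groups map CNLUCC-style integer codes to resistance values.
elevation:
  kind: continuous
  units: m
  breaks: [1000, 1500, 2000]
  values: [10, 50, 100, 10000]
slope:
  kind: continuous
  units: degrees
  breaks: [10, 15, 30]
  values: [10, 50, 100, 10000]
roughness:
  kind: continuous
  units: dimensionless
  breaks: [1.1, 1.2, 1.3]
  values: [10, 50, 100, 10000]
landuse:
  kind: categorical
  groups:
    shrub_grass:          # shrubbery, grassland, sparse woodland
      value: 10
      codes: [22, 23, 31, 32, 33]
    forest_dry:           # forest, bare land, dry land
      value: 100
      codes: [21, 12, 65]
    swamp_beach_rural:    # swamp, river beach, rural settlement
      value: 200
      codes: [64, 46, 52]
    otherwood_paddy_rock: # other woodland, paddy field, bare rock land
      value: 400
      codes: [24, 11, 66]
    urban_water:          # urban/construction land, canal, lake, reservoir, glacier/snow
      value: 10000
      codes: [51, 53, 41, 42, 43, 44]
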