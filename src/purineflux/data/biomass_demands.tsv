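# Anabolic precursor demands for biomass synthesis, mmol per g cell dry
# weight, representative of published coryneform/gram-positive biomass
# composition tables.  Editable: replace values to match a specific strain.
# The sparing_3PG_* rows give the 3-phosphoglycerate demand (glycine plus
# two formyl units per purine ring) spared when the corresponding nucleobase
# is supplied in the medium and purine rings are salvaged instead of made
# de novo.
precursor	mmol_per_gCDW
G6P	0.205
F6P	0.071
P5P	0.879
GAP	0.129
3PG	1.295
PEP	0.652
Pyr	2.604
AcCoA	2.490
AKG	1.072
OAA	1.787
sparing_3PG_adenine	0.26
sparing_3PG_guanine	0.24
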