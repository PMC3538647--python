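# Measured GC-MS fragments and their precursor carbon origins.
# precursors: '+'-separated list of metabolite:positions entries; the
# fragment mass isotopomer distribution is the convolution of the precursor
# EMU distributions (standard bacterial biosynthesis assignments: Ala from
# pyruvate; Gly from 3PG C1-C2 via serine; Ser from 3PG; Val from two
# pyruvates losing one C1 as CO2; Thr from oxaloacetate; Phe from two PEP
# plus erythrose 4-phosphate; trehalose from two glucose 6-phosphate units).
# formula: atoms of the derivatized ion beyond the tracer-carbon skeleton
# (TBDMS amino-acid [M-57] ions; per-TMS trehalose ion), used for
# natural-abundance correction.
fragment	precursors	formula
ala_m57	Pyr:1,2,3	C8H26N1O2Si2
gly_m57	3PG:1,2	C8H24N1O2Si2
ser_m57	3PG:1,2,3	C14H40N1O3Si3
val_m57	Pyr:1,2,3+Pyr:2,3	C8H30N1O2Si2
thr_m57	OAA:1,2,3,4	C14H42N1O3Si3
phe_m57	PEP:1,2,3+PEP:2,3+E4P:1,2,3,4	C8H30N1O2Si2
tre_tms	G6P:1,2,3,4,5,6+G6P:1,2,3,4,5,6	C23H83O11Si8
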