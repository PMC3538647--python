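# Central carbon metabolism of glucose-grown C. glutamicum.
# One reaction per line: id: equation | rev/irr [| gene=tag] [| drain=PRECURSOR]
# Atom maps in letter notation; ';' separates equal-weight scrambling variants
# for symmetric intermediates (succinate/fumarate).
# Net fluxes are expressed in % of glucose uptake; the pentose pool is lumped
# into a single P5P species and anaplerosis into one net PEP+CO2<->OAA
# interconversion with an exchange parameter.

@external GLC_ext CO2_ex Gly_ex Tre_ex C1_ex BIOMASS

upt: GLC_ext (abcdef) -> G6P (abcdef) | irr

# glycolysis
pgi: G6P (abcdef) <-> F6P (abcdef) | rev | gene=pgi
pfk: F6P (abcdef) -> F16BP (abcdef) | irr
fba: F16BP (abcdef) -> DHAP (cba) + GAP (def) | irr
tpi: DHAP (abc) -> GAP (abc) | irr
gapdh: GAP (abc) -> 3PG (abc) | irr
eno: 3PG (abc) -> PEP (abc) | irr
pyk: PEP (abc) -> Pyr (abc) | irr

# pentose phosphate pathway (lumped P5P pool)
zwf: G6P (abcdef) -> P5P (bcdef) + CO2 (a) | irr
tkt1: P5P (abcde) + P5P (ABCDE) <-> S7P (abABCDE) + GAP (cde) | rev
tal: S7P (abcdefg) + GAP (ABC) <-> E4P (defg) + F6P (abcABC) | rev
tkt2: P5P (abcde) + E4P (ABCD) <-> F6P (abABCD) + GAP (cde) | rev

# pyruvate dehydrogenase and TCA cycle
pdh: Pyr (abc) -> AcCoA (bc) + CO2 (a) | irr
cs: OAA (abcd) + AcCoA (ef) -> Iso (dcbfea) | irr
idh: Iso (abcdef) -> AKG (abcde) + CO2 (f) | irr
akgdh: AKG (abcde) -> Suc (bcde) + CO2 (a) | irr
# succinate dehydrogenase + fumarase, with scrambling over the symmetric C4 axis
sdh: Suc (abcd) -> Mal (abcd) ; Suc (abcd) -> Mal (dcba) | irr
mdh: Mal (abcd) <-> OAA (abcd) | rev

# anaplerosis (net PEP carboxylation with exchange)
ppc: PEP (abc) + CO2 (d) <-> OAA (abcd) | rev

# secretion
gly_sec: 3PG (abc) -> Gly_ex (ab) + C1_ex (c) | irr
tre_sec: G6P (abcdef) + G6P (ABCDEF) -> Tre_ex (abcdefABCDEF) | irr
co2_out: CO2 (a) -> CO2_ex (a) | irr

# anabolic precursor drains (fluxes fixed from biomass demands, mu and q_S)
bm_g6p: G6P (abcdef) -> BIOMASS (abcdef) | irr | drain=G6P
bm_f6p: F6P (abcdef) -> BIOMASS (abcdef) | irr | drain=F6P
bm_p5p: P5P (abcde) -> BIOMASS (abcde) | irr | drain=P5P
bm_gap: GAP (abc) -> BIOMASS (abc) | irr | drain=GAP
bm_3pg: 3PG (abc) -> BIOMASS (abc) | irr | drain=3PG
bm_pep: PEP (abc) -> BIOMASS (abc) | irr | drain=PEP
bm_pyr: Pyr (abc) -> BIOMASS (abc) | irr | drain=Pyr
bm_accoa: AcCoA (ab) -> BIOMASS (ab) | irr | drain=AcCoA
bm_akg: AKG (abcde) -> BIOMASS (abcde) | irr | drain=AKG
bm_oaa: OAA (abcd) -> BIOMASS (abcd) | irr | drain=OAA
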