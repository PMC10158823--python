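@model toy_ecoli_w
@compartments c e
@objective BIOMASS
@metabolites
glc_e | D-glucose | e
glc_c | D-glucose | c
pyr_c | pyruvate | c
accoa_c | acetyl-CoA | c
alac_c | 2-acetolactate | c
dhmb_c | 2,3-dihydroxy-3-methylbutanoate | c
kiv_c | 2-ketoisovalerate | c
kiv_e | 2-ketoisovalerate | e
co2_e | CO2 (vented) | e
nad_c | NAD+ | c
nadh_c | NADH | c
nadp_c | NADP+ | c
nadph_c | NADPH | c
atp_c | ATP | c
adp_c | ADP | c
@reactions
EX_glc_e: glc_e --> [-10, 0] ex
GLCt: glc_e --> glc_c [0, 1000]
EMP: glc_c + 2 nad_c + 2 adp_c --> 2 pyr_c + 2 nadh_c + 2 atp_c [0, 1000]
PDH: pyr_c + nad_c --> accoa_c + nadh_c + co2_e [0, 1000] gpr{aceF}
TCA: accoa_c + 3 nad_c + adp_c --> 3 nadh_c + atp_c + 2 co2_e [0, 1000] gpr{gltA}
ACLS: 2 pyr_c --> alac_c + co2_e [0, 1000] gpr{alsS}
KARA: alac_c + nadph_c --> dhmb_c + nadp_c [0, 1000] gpr{ilvC}
DHAD: dhmb_c --> kiv_c [0, 1000] gpr{ilvD}
THD: nadh_c + nadp_c --> nad_c + nadph_c [0, 1000]
NOX: nadh_c + 2 adp_c --> nad_c + 2 atp_c [0, 1000]
ATPM: atp_c --> adp_c [0, 1000]
BIOMASS: 0.5 pyr_c + 0.5 accoa_c + atp_c --> adp_c [0, 1000]
KIVt: kiv_c --> kiv_e [0, 1000]
EX_kiv_e: kiv_e --> [0, 1000] ex
EX_co2_e: co2_e --> [0, 1000] ex
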