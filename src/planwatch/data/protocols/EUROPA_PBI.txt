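# EUROPA trial 1.2, partial breast irradiation arm: 30 Gy in 5 daily fractions.
# Limits per the EUROPA trial planning constraints (Meattini et al.).
name = EUROPA_PBI
selection = 5 fx @ 6.0-6.2 Gy/fx, 1-1 ptvs
PTV_BREAST | D95%[Gy] | >= | 28.5 | - | std | PTV       # 95% of 30 Gy coverage
PTV_BREAST | V31.5Gy[%] | <= | 5 | - | std | PTV        # volume above 105% of Rx
LUNG_IPSI | V10Gy[%] | <= | 20 | - | std | MAIN_OAR
HEART | Dmean[Gy] | <= | 1.5 | - | std | MAIN_OAR
LUNG_CONTRA | V3Gy[%] | <= | 10 | - | extra | MAIN_OAR  # extra: site-configurable
BREAST_CONTRA | Dmean[Gy] | <= | 1 | - | extra | MAIN_OAR
SKIN | Dmax[Gy] | <= | 32 | - | extra | OTHER_OAR       # extra: site-configurable
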