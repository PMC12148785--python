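# EUROPA trial 1.2, whole breast irradiation arm: 40.05 Gy in 15 fractions.
# Limits per the EUROPA trial planning constraints (Meattini et al.).
# Single-PTV selection keeps this arm disjoint from the RTOG1005 boost arm.
name = EUROPA_WBI
selection = 15 fx @ 2.6-2.7 Gy/fx, 1-1 ptvs
PTV_BREAST | D95%[Gy] | >= | 38 | - | std | PTV         # 95% of 40.05 Gy coverage
PTV_BREAST | V42Gy[%] | <= | 5 | - | std | PTV          # volume above 105% of Rx
LUNG_IPSI | V16Gy[%] | <= | 20 | - | std | MAIN_OAR
HEART | Dmean[Gy] | <= | 3 | 2 | std | MAIN_OAR
LUNG_CONTRA | V4Gy[%] | <= | 15 | - | extra | MAIN_OAR  # extra: site-configurable
BREAST_CONTRA | Dmean[Gy] | <= | 1.5 | - | extra | MAIN_OAR
SKIN | Dmax[Gy] | <= | 42 | - | extra | OTHER_OAR       # extra: site-configurable
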