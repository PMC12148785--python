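# NRG RTOG 1005: hypofractionated whole breast irradiation with concurrent
# boost (40 Gy/15 fx + boost) or conventional arm (50 Gy/25 fx + boost).
# Limits per the RTOG 1005 protocol dose constraints (acceptable-variation
# values as mandatory, per-protocol values as optimal where both exist).
name = RTOG1005
selection = 15/16 fx @ 2.5-2.9 Gy/fx, 2-3 ptvs
selection = 23/24/25 fx @ 1.8-2.1 Gy/fx, 2-3 ptvs
PTV_BREAST | D95%[Gy] | >= | 38 | - | std | PTV            # 95% of 40 Gy coverage
PTV_BOOST | D95%[Gy] | >= | 45.6 | - | std | PTV           # 95% of 48 Gy boost coverage
PTV_BREAST | V43.2Gy[%] | <= | 30 | - | std | PTV          # hot volume above 108% of Rx
LUNG_IPSI | V16Gy[%] | <= | 20 | 15 | std | MAIN_OAR       # per-protocol 15, acceptable 20
LUNG_IPSI | V8Gy[%] | <= | 40 | 35 | std | MAIN_OAR
LUNG_CONTRA | V4Gy[%] | <= | 15 | 10 | std | MAIN_OAR
HEART | Dmean[Gy] | <= | 4 | 3.2 | std | MAIN_OAR
BREAST_CONTRA | Dmax[Gy] | <= | 3.1 | 1.9 | std | MAIN_OAR
THYROID | Dmean[Gy] | <= | 5 | - | extra | OTHER_OAR       # extra: site-configurable
SKIN | Dmax[Gy] | <= | 44 | - | extra | OTHER_OAR          # extra: site-configurable
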