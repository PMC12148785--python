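# ICR Fast-Forward: 26 Gy in 5 daily fractions.
# Standard limits per the Fast-Forward trial protocol (Brunt et al.,
# Lancet 2020, ISRCTN19906132); extra limits are site-suggested additions.
name = FAST_FORWARD
selection = 5 fx @ 5.0-5.4 Gy/fx, 1-3 ptvs
PTV_BREAST | D95%[Gy] | >= | 24.7 | - | std | PTV       # 95% of 26 Gy coverage
PTV_BREAST | V27.3Gy[%] | <= | 5 | 2 | std | PTV        # volume above 105% of Rx
PTV_BREAST | V28.6Gy[%] | <= | 2 | - | std | PTV        # volume above 110% of Rx
LUNG_IPSI | V8Gy[%] | <= | 15 | - | std | MAIN_OAR      # trial ipsilateral lung limit
HEART | V1.5Gy[%] | <= | 30 | - | std | MAIN_OAR        # trial heart limit
HEART | V7Gy[%] | <= | 5 | - | std | MAIN_OAR           # trial heart limit
LUNG_IPSI | V16Gy[%] | <= | 20 | - | extra | MAIN_OAR   # extra: hypofractionation lung limit
LUNG_CONTRA | V3Gy[%] | <= | 10 | - | extra | MAIN_OAR  # extra: suggested contralateral lung limit
HEART | Dmean[Gy] | <= | 2 | - | extra | MAIN_OAR       # extra: suggested mean heart dose limit
BREAST_CONTRA | Dmean[Gy] | <= | 1 | - | extra | MAIN_OAR  # extra: contralateral breast sparing
ESOPHAGUS | Dmean[Gy] | <= | 5 | - | extra | OTHER_OAR  # extra: site-configurable
LIVER | Dmean[Gy] | <= | 2 | - | extra | OTHER_OAR      # extra: site-configurable
STOMACH | Dmean[Gy] | <= | 2 | - | extra | OTHER_OAR    # extra: site-configurable
THYROID | Dmean[Gy] | <= | 3 | - | extra | OTHER_OAR    # extra: site-configurable
SKIN | Dmax[Gy] | <= | 30 | - | extra | OTHER_OAR       # extra: site-configurable
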