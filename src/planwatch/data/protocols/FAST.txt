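# ICR FAST: 28.5 Gy in 5 once-weekly fractions.
# Standard limits per the FAST trial protocol (Brunt et al., 2011/2020,
# ISRCTN62488883); extra limits are site-suggested additions.
name = FAST
selection = 5 fx @ 5.5-5.9 Gy/fx, 1-2 ptvs
PTV_BREAST | D95%[Gy] | >= | 27.1 | - | std | PTV       # 95% of 28.5 Gy coverage
PTV_BREAST | V30Gy[%] | <= | 5 | - | std | PTV          # volume above 105% of Rx
LUNG_IPSI | V8.5Gy[%] | <= | 15 | - | std | MAIN_OAR    # trial ipsilateral lung limit
HEART | V1.5Gy[%] | <= | 30 | - | std | MAIN_OAR        # trial heart limit
HEART | V7.5Gy[%] | <= | 5 | - | std | MAIN_OAR         # trial heart limit
LUNG_CONTRA | V3Gy[%] | <= | 10 | - | extra | MAIN_OAR  # extra: suggested
HEART | Dmean[Gy] | <= | 2 | - | extra | MAIN_OAR       # extra: suggested
BREAST_CONTRA | Dmean[Gy] | <= | 1 | - | extra | MAIN_OAR  # extra: site-configurable
SKIN | Dmax[Gy] | <= | 33 | - | extra | OTHER_OAR       # extra: site-configurable
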