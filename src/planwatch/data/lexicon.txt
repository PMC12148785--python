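# Structure-name matching lexicon: ROLE: token1, token2, ...
# Tokens are case-insensitive; tokens of 1-2 characters match whole words
# only, longer tokens match as substrings of the normalized name
# (punctuation collapsed to spaces). Edit freely to match local naming.
PTV_BREAST: ptv breast, breast ptv, ptv mamma, ptv, ctv breast, mamma, chestwall, chest wall, parete
PTV_BOOST: boost, ptv boost, letto tumorale, surgical bed, tumor bed
PTV_NODES: nodes, node, lymph, linfonodi, nodal, sclav, axilla
LUNG: lung, polmone
HEART: heart, cuore
LAD: lad, left coronary, coronaria, iva, ada
BREAST_CONTRA: breast contra, contra breast, contralateral breast, breast cntr, mammella contro, controlaterale
ESOPHAGUS: esophagus, oesophagus, esofago
STOMACH: stomach, stomaco
LIVER: liver, fegato
THYROID: thyroid, tiroide
SKIN: skin, cute
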