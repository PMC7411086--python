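# Gauss-peak spectral templates for diatom pigments in 100% acetone.
# SYNTHETIC stand-in library: a constructed parameterization with
# literature-plausible band positions for each pigment, not a transcription
# of any published GPS table. Internally consistent for forward modelling
# and round-trip unmixing; absolute concentrations are in template units
# (absorbance of the unit-concentration template at its main peak ~ 1 AU).
# Columns: pigment, center_nm, sigma_nm, amplitude
pigment,center_nm,sigma_nm,amplitude
chl_a,430,12,1.00
chl_a,410,15,0.35
chl_a,617,12,0.12
chl_a,662,9,0.80
chl_c,444,12,1.00
chl_c,581,12,0.18
chl_c,630,10,0.30
pheophytin_a,409,13,1.00
pheophytin_a,505,15,0.12
pheophytin_a,535,12,0.10
pheophytin_a,667,10,0.55
beta_carotene,452,17,1.00
beta_carotene,480,16,0.90
fucoxanthin,445,28,1.00
fucoxanthin,485,30,0.75
diadinoxanthin,414,8,0.70
diadinoxanthin,442,9,1.00
diadinoxanthin,471,9,0.85
diatoxanthin,430,8,0.70
diatoxanthin,458,9,1.00
diatoxanthin,488,9,0.85
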