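# Antihypertensive drug classes (British National Formulary) mapped to
# DrugBank-style target genes.  Users may supply their own map; gene regions
# for these symbols must be provided separately.
adrenergic neuron blockers: [SLC6A2]
alpha-adrenoceptor blockers: [ADRA1A, ADRA1B, ADRA1D]
angiotensin-II receptor antagonists: [AGTR1]
angiotensin converting enzyme inhibitors: [ACE]
beta-adrenoceptor blockers: [ADRB1, ADRB2]
calcium channel blockers: [CACNA1C, CACNA1D, CACNA2D1, CACNB2]
centrally acting antihypertensives: [ADRA2A, ADRA2B, ADRA2C]
loop diuretics: [SLC12A1]
potassium-sparing diuretics and aldosterone antagonists: [NR3C2, SCNN1A, SCNN1B, SCNN1G]
renin inhibitors: [REN]
thiazides and related diuretics: [SLC12A3]
vasodilator antihypertensives: [ABCC9, KCNJ8, EDNRA]
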