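name,difference
hydrogenation,H2
oxidation,O
hydration,H2O
methylation,CH2
formylation,CO
carboxylation,CO2
hydroxymethylation,CH2O
formic acid condensation,CH2O2
acetylation,C2H2O
ethylation,C2H4
dehydrogenation (diyl),C2H2
glycolylation,C2H2O2
acetic acid condensation,C2H4O2
malonylation,C3H2O3
propionylation,C3H4O
lactoylation,C3H4O2
glycerol condensation,C3H6O2
crotonylation,C4H4O
succinylation,C4H4O3
isoprenylation,C5H8
amination,NH
ammonia addition,NH3
cyanation,CHN
carbamoylation,CHNO
methylamine condensation,CH3N
ethanolamine condensation,C2H5NO
phosphorylation,HPO3
pyrophosphate transfer,H2P2O6
sulfation,SO3
thiolation,S
sulfanylation,H2S
hexosylation,C6H10O5
pentosylation,C5H8O4
deoxyhexosylation,C6H10O4
glucuronidation,C6H8O6
sialylation,C11H17NO8
acetamido sugar transfer,C8H13NO5
choline condensation,C5H13NO
taurine conjugation,C2H5NO2S
glycine residue,C2H3NO
alanine residue,C3H5NO
serine residue,C3H5NO2
proline residue,C5H7NO
valine residue,C5H9NO
threonine residue,C4H7NO2
cysteine residue,C3H5NOS
leucine/isoleucine residue,C6H11NO
asparagine residue,C4H6N2O2
aspartate residue,C4H5NO3
glutamine residue,C5H8N2O2
lysine residue,C6H12N2O
glutamate residue,C5H7NO3
methionine residue,C5H9NOS
histidine residue,C6H7N3O
phenylalanine residue,C9H9NO
arginine residue,C6H12N4O
tyrosine residue,C9H9NO2
tryptophan residue,C11H10N2O
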