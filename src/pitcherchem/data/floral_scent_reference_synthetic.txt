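# Curated stand-in (synthetic) list of floral scent volatiles, assembled
# from compound classes commonly recorded from intact flowers.  The
# reference list used for the original accession tables is unpublished;
# edit or replace this file for serious use.  One compound name per line;
# matching is case-insensitive with collapsed whitespace.
nonanal
octanal
heptanal
decanal
benzaldehyde
phenylacetaldehyde
benzyl alcohol
2-phenylethanol
methyl salicylate
methyl benzoate
benzyl acetate
phenethyl acetate
eugenol
linalool
geraniol
nerol
citronellol
alpha-terpineol
limonene
alpha-pinene
beta-pinene
sabinene
camphene
myrcene
ocimene
p-cymene
terpinolene
1,8-cineole
pulegone
trans-jasmone
cis-jasmone
actinidine
indole
beta-ionone
farnesene
caryophyllene
6-methyl-5-hepten-2-one
tetradecanoic acid
hexadecanoic acid
(Z)-9-hexadecenoic acid
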