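name,cas_rn,dnel_mg_per_m3
D-Limonene,5989-27-5,16.6
Linalool,78-70-6,0.7
Methyl 2-octynoate,111-12-6,
Citral,5392-40-5,2.7
Citronellol,106-22-9,47.8
Geraniol,106-24-1,47.8
α-Isomethyl ionone,127-51-5,1.45
Benzyl alcohol,100-51-6,5.4
Hydroxycitronellal,107-75-5,
Methyl eugenol,93-15-2,1.74
Cinnamaldehyde,104-55-2,1.09
Lilial,80-54-6,
Eugenol,97-53-0,5.22
α-Amylcinnamaldehyde,122-40-7,
Anise alcohol,105-13-5,0.37
Cinnamyl alcohol,104-54-1,0.465
Isoeugenol,97-54-1,5.22
α-Hexylcinnamaldehyde,101-86-0,
Farnesol,4602-84-0,0.457
Coumarin,91-64-5,
HICC,31906-04-4,
α-Amylcinnamyl alcohol,101-85-9,
Benzyl benzoate,120-51-4,1.25
Benzyl salicylate,118-58-1,1.37
Benzyl cinnamate,103-41-3,1.74
Menthol,89-78-1,8.17
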