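compound,average_content_ug_per_cigarette,maximum_content_ug_per_cigarette
D-Limonene,119.47,818.21
Linalool,23.22,301.86
Citral,15.12,255.67
Citronellol,1.6,26.15
Geraniol,4.27,130.58
α-Isomethyl ionone,0.04,0.08
Benzyl alcohol,33.1,474.41
Methyl eugenol,0.05,0.35
Cinnamaldehyde,8.15,182.95
Eugenol,0.27,1.38
Anise alcohol,0.33,1.16
Cinnamyl alcohol,0.09,0.43
Isoeugenol,0.33,1.27
Farnesol,0.86,1.12
Benzyl benzoate,0.33,5.24
Benzyl salicylate,0.61,0.82
Benzyl cinnamate,0.33,6.41
Menthol,1565.01,7870.83
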