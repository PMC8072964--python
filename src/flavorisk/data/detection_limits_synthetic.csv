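# synthetic per-compound limits: published ranges only give method-wide min-max
name,lod_solvent,loq_solvent,mdl_tobacco,loq_tobacco,mdl_filter_tip,loq_filter_tip
D-Limonene,0.8844,2.948,2.068,6.893,1.738,5.793
Linalool,0.4783,1.594,1.328,4.427,1.177,3.923
Methyl 2-octynoate,3.023,10.08,5.015,16.72,3.787,12.62
Citral,1.635,5.45,3.22,10.73,2.565,8.55
Citronellol,5.59,18.63,7.81,26.03,5.59,18.63
Geraniol,0.12,0.4,0.49,1.633,0.49,1.633
α-Isomethyl ionone,0.3518,1.173,1.064,3.547,0.9688,3.229
Benzyl alcohol,2.593,8.643,4.489,14.96,3.435,11.45
Hydroxycitronellal,0.6504,2.168,1.657,5.523,1.43,4.767
Methyl eugenol,0.1632,0.544,0.6115,2.038,0.5954,1.985
Cinnamaldehyde,4.794,15.98,6.991,23.3,5.071,16.9
Lilial,1.402,4.673,2.882,9.607,2.327,7.757
Eugenol,0.1903,0.6343,0.6831,2.277,0.6562,2.187
α-Amylcinnamaldehyde,1.203,4.01,2.58,8.6,2.111,7.037
Anise alcohol,1.907,6.357,3.597,11.99,2.827,9.423
Cinnamyl alcohol,0.2219,0.7397,0.7631,2.544,0.7234,2.411
Isoeugenol,3.526,11.75,5.602,18.67,4.174,13.91
α-Hexylcinnamaldehyde,0.4102,1.367,1.188,3.96,1.068,3.56
Farnesol,2.223,7.41,4.018,13.39,3.117,10.39
Coumarin,4.111,13.7,6.258,20.86,4.601,15.34
HICC,0.5578,1.859,1.483,4.943,1.297,4.323
α-Amylcinnamyl alcohol,0.1399,0.4663,0.5474,1.825,0.5401,1.8
Benzyl benzoate,0.2587,0.8623,0.8525,2.842,0.7973,2.658
Benzyl salicylate,0.7585,2.528,1.851,6.17,1.576,5.253
Benzyl cinnamate,0.3017,1.006,0.9523,3.174,0.8789,2.93
Menthol,1.031,3.437,2.31,7.7,1.915,6.383
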