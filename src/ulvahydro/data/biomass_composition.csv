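compound,g_per_kg,class
D-Glucose,403.4788,carbohydrate
L-Rhamnose,195.0048,carbohydrate
D-Xylose,106.028,carbohydrate
Glucuronic Acid,47.1232,carbohydrate
L-Aspartic acid,10.9134,amino_acid
L-Threonine,5.33826,amino_acid
L-Serine,5.87124,amino_acid
L-Glutamic acid,10.94724,amino_acid
L-Proline,3.48552,amino_acid
Glycine,5.6259,amino_acid
L-Alanine,7.74936,amino_acid
L-Valine,7.7409,amino_acid
L-Methionine,2.01348,amino_acid
Cystine,1.64124,amino_acid
L-Isoleucine,4.02696,amino_acid
L-Leucine,6.9795,amino_acid
L-Tyrosine,5.06754,amino_acid
L-Phenylalanine,2.2842,amino_acid
L-Histidine,1.17594,amino_acid
L-Lysine,5.499,amino_acid
L-Arginine,5.23674,amino_acid
Myristic acid,1.8888,fatty_acid
Palmitic acid,46.7478,fatty_acid
Palmitoleic acid,5.40669,fatty_acid
Stearic acid,1.47169,fatty_acid
Oleic acid,12.53691,fatty_acid
Linoleic acid,1.91241,fatty_acid
alpha-Linolenic acid,2.5184,fatty_acid
Arachidic acid,0.88931,fatty_acid
Eicosenoic acid,1.19624,fatty_acid
Behenic acid,3.28179,fatty_acid
Docosahexaenoic acid,0.8657,fatty_acid
L-Iduronic Acid,36.2304,uronic_acid
Other undigested particles,23.04824,inert
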