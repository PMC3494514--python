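name,pubchem_cid,kegg_id,hmdb_id,monoisotopic_mw
L-alanine,5950,C00041,HMDB0000161,89.04768
glycine,750,C00037,HMDB0000123,75.03203
L-serine,5951,C00065,HMDB0000187,105.04259
L-proline,145742,C00148,HMDB0000162,115.06333
L-valine,6287,C00183,HMDB0000883,117.07898
L-threonine,6288,C00188,HMDB0000167,119.05824
L-cysteine,5862,C00097,HMDB0000574,121.01975
L-leucine,6106,C00123,HMDB0000687,131.09463
L-isoleucine,6306,C00407,HMDB0000172,131.09463
L-asparagine,6267,C00152,HMDB0000168,132.05349
L-aspartate,5960,C00049,HMDB0000191,133.03751
L-glutamine,5961,C00064,HMDB0000641,146.06914
L-lysine,5962,C00047,HMDB0000182,146.10553
L-glutamate,33032,C00025,HMDB0000148,147.05316
L-methionine,6137,C00073,HMDB0000696,149.05105
L-histidine,6274,C00135,HMDB0000177,155.06948
L-phenylalanine,6140,C00079,HMDB0000159,165.07898
L-arginine,6322,C00062,HMDB0000517,174.11168
L-tyrosine,6057,C00082,HMDB0000158,181.07389
L-tryptophan,6305,C00078,HMDB0000929,204.08988
pyruvate,1060,C00022,HMDB0000243,88.01604
L-lactate,107689,C00186,HMDB0000190,90.03169
fumarate,444972,C00122,HMDB0000134,116.01096
succinate,1110,C00042,HMDB0000254,118.02661
malate,525,C00149,HMDB0000156,134.02152
alpha-ketoglutarate,51,C00026,HMDB0000208,146.02152
citrate,311,C00158,HMDB0000094,192.02700
D-glucose,5793,C00031,HMDB0000122,180.06339
creatinine,588,C00791,HMDB0000562,113.05898
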