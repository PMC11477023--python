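# Previously proposed Fabry-disease biomarkers with their cross-validated
# classifier performance. Only B2M's plasma measurability is asserted by the
# study text; the plasma flags of the other rows are synthetic fixture
# assumptions (MAPK11 is marked non-measurable because the study passed it
# over in favour of the first *easily measurable* candidate).
gene_symbol,uniprot,cv_accuracy,cv_pvalue,plasma_measurable
MAPK11,Q15759,76,7.41e-20,False
B2M,P61769,71,1.18e-10,True
CD80,P33681,68,2.14e-7,True
CCL2,P13500,66,4.77e-6,True
NOS3,P29474,63,9.04e-6,True
GPX1,P07203,61,3.54e-6,True
ACTB,P60709,61,7.72e-5,True
TGFB1,P01137,61,8.01e-4,True
AGTR1,P30556,60,4e-3,False
MMP9,P14780,59,2e-3,True
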