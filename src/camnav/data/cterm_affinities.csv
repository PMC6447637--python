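isoform,construct,species,kd_nM,kd_err_nM,neg_dg_kcal_per_mol
NaV1.4,Long,apo,17,3,10.59
NaV1.4,Long,4,275,26,8.94
NaV1.4,Long,2C,154,9,9.29
NaV1.4,Long,2N,121,7,9.43
NaV1.5,Long,apo,48,5,9.98
NaV1.5,Long,4,89,7,9.61
NaV1.5,Long,2C,3600,200,7.43
NaV1.5,Long,2N,90,4,9.58
NaV1.4,Short,apo,114,11,9.47
NaV1.4,Short,4,305,21,8.88
NaV1.4,Short,2C,156,5,9.28
NaV1.4,Short,2N,282,6,8.93
NaV1.5,Short,apo,39,3,10.10
NaV1.5,Short,4,1520,90,7.93
NaV1.5,Short,2C,5260,240,7.20
NaV1.5,Short,2N,376,12,8.76
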