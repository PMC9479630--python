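subject_id,group,age,sex,amb_type,amb_eye,acuity_de_logmar,acuity_nde_logmar,stereo_arcsec,mrs_quality_flag
A1,PWA,52,F,Aniso,OD,-0.097,0.418,,False
A2,PWA,30,F,Aniso,OS,-0.184,0.398,,False
A3,PWA,19,M,Aniso,OD,-0.085,0.538,,False
A4,PWA,50,F,Aniso,OS,-0.164,0.398,,False
A5,PWA,24,F,Aniso,OS,-0.057,0.281,,True
A6,PWA,61,F,Aniso,OS,-0.097,0.497,,False
A7,PWA,39,F,Aniso,OS,-0.097,0.244,,False
A8,PWA,44,F,Aniso,OS,-0.204,0.261,,False
A9,PWA,46,M,Aniso,OD,-0.097,0.281,,False
A10,PWA,33,M,Aniso,OS,-0.097,0.358,,True
A11,PWA,36,M,Aniso,OD,-0.204,0.117,,False
A12,PWA,25,M,Aniso,OS,-0.202,0.244,,False
M1,PWA,43,F,Mixed,OS,-0.077,0.756,,False
M2,PWA,33,F,Mixed,OS,-0.085,1.176,,False
M3,PWA,61,F,Mixed,OS,0.077,0.602,,False
M4,PWA,25,M,Mixed,OS,0.000,0.224,,False
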