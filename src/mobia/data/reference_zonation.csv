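method,class,total_area,n_objects,mound_area
DNN,CRUB,676.12,3680,474.37
DNN,DC,199.38,1641,199.37
DNN,HEMS,703.39,3197,433.87
DNN,HESDR,549.40,2000,324.01
DNN,SPG,46.22,739,56.62
DNN,LCN,81.94,1041,32.38
DNN,OTHER,76.98,1630,66.21
LR,CRUB,235.67,1567,169.24
LR,DC,354.44,2521,354.44
LR,HEMS,809.45,3952,506.74
LR,HESDR,767.45,2841,410.05
LR,SPG,44.67,824,43.34
LR,LCN,69.36,1105,57.94
LR,OTHER,52.39,1118,45.08
RF,CRUB,449.11,2273,297.74
RF,DC,300.98,2224,299.24
RF,HEMS,693.42,3187,460.60
RF,HESDR,696.60,2734,369.75
RF,SPG,44.41,1308,36.96
RF,LCN,94.01,852,69.52
RF,OTHER,54.90,1350,53.02
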