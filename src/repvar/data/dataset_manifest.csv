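dataset_name,short_name,n_variants,seq_length
AMIE_PSEAE_Whitehead,AMIE,4507,346
B3VI55_LIPSTSTABLE,B3VI55_LIPSTSTABLE,6541,439
B3VI55_LIPST_Whitehead2015,B3VI55_LIPST,6327,439
BF520_env_Bloom2018,BF520,12236,852
BG505_env_Bloom2018,BG505,12217,860
BG_STRSQ_hmmerbit,BG_STRSQ,2635,501
BLAT_ECOLX_Ostermeier2014,BLAT_2014,4595,286
BLAT_ECOLX_Palzkill2012,BLAT_2012,4789,286
BLAT_ECOLX_Ranganathan2015,BLAT_2015,4788,286
BLAT_ECOLX_Tenaillon2013,BLAT_2013,949,286
BRCA1_HUMAN_BRCT,BRCA1_BRCT,1185,1863
BRCA1_HUMAN_RING,BRCA1_RING,492,1863
CALM1_HUMAN_Roth2017,CALM1_Roth2017,1730,149
DLG4_RAT_Ranganathan2012,DLG4_RAT,1558,724
GAL4_YEAST_Shendure2015,GAL4,1104,881
HG_FLU_Bloom2016,HG_FLU,10337,565
HSP82_YEAST_Bolon2016,HSP82,4104,709
IF1_ECOLI_Kishony,IF1_ECOLI,1312,72
MK01_HUMAN_Johannessen,MK01,5463,360
MTH3_HAEAESTABILIZED_Tawfik2015,MTH3,1719,330
P84126_THETH_b0,P84126,1519,254
PABP_YEAST_Fields2013-singles,PABP,1187,577
PA_FLU_Sun2015,PA_FLU,1848,716
POLG_HCVJF_Sun2014,POLG_HCVJF,1631,3033
PTEN_HUMAN_Fowler2018,PTEN,3014,403
RASH_HUMAN_Kuriyan,RASH,3078,189
RL401_YEAST_Bolon2013,RL401_2013,1160,76
RL401_YEAST_Bolon2014,RL401_2014,1294,76
RL401_YEAST_Fraser2016,RL401_2016,1168,76
SUMO1_HUMAN_Roth2017,SUMO1,1329,101
TIM_SULSO_b0,TIM_SULSO,1519,248
TIM_THEMA_b0,TIM_THEMA,1519,252
TPK1_HUMAN_Roth2017,TPK1_2017,2608,243
TPMT_HUMAN_Fowler2018,TPMT_2018,2659,245
UBC9_HUMAN_Roth2017,UBC9,2281,159
UBE4B_MOUSE_Klevit2013-singles,UBE4B,603,1173
YAP1_HUMAN_Fields2012-singles,YAP1,313,504
HIV_Tat,HIV_Tat,1615,86
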