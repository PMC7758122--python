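compound,target_name,uniprot_ac,binding_energy
4CQA,Progesterone receptor,P06401,-9.15
,5'-AMP-activated protein kinase subunit beta-2,O43741,-9.06
,Thiopurine S-methyltransferase,P51580,-8.98
,Complement C1q subcomponent subunit C,P02747,-8.51
,Histamine H1 receptor,P35367,-8.42
5CQA,Progesterone receptor,P06401,-9.05
,5'-AMP-activated protein kinase subunit beta-2,O43741,-8.69
,"Phospholipase A2, membrane associated",P14555,-8.56
,Glutathione S-transferase A2,P09210,-8.4
,Retinoic acid receptor alpha,P10276,-8.38
CGA,Thiopurine S-methyltransferase,P51580,-8.74
,Androgen receptor,P10275,-8.32
,"Phospholipase A2, membrane associated",P14555,-8.28
Gen,Thiopurine S-methyltransferase,P51580,-8.41
Gep,Corticosteroid 11-beta-dehydrogenase isozyme 1,P28845,-8.19
IsoA,"Phospholipase A2, membrane associated",P14555,-11.82
,5'-AMP-activated protein kinase subunit beta-2,O43741,-10.32
,Thiopurine S-methyltransferase,P51580,-10.24
,Peroxisome proliferator-activated receptor gamma,P37231,-9.08
,Glucocorticoid receptor,P04150,-9.02
,"Fatty acid-binding protein, intestinal",P12104,-8.82
,Aldose reductase,P15121,-8.66
,Histamine H1 receptor,P35367,-8.51
,"Nitric oxide synthase, endothelial",P29474,-8.28
IsoB,Progesterone receptor,P06401,-10.62
,Thiopurine S-methyltransferase,P51580,-10.52
,Peroxisome proliferator-activated receptor gamma,P37231,-9.18
,Prostaglandin reductase 2,Q8N8N7,-8.91
,Peroxisome proliferator-activated receptor alpha,Q07869,-8.89
,Glucocorticoid receptor,P04150,-8.29
IsoC,5'-AMP-activated protein kinase subunit beta-2,O43741,-10.61
,Progesterone receptor,P06401,-10.4
,"Phospholipase A2, membrane associated",P14555,-9.97
,Peroxisome proliferator-activated receptor gamma,P37231,-9.97
,Retinoic acid receptor beta,P10826,-9.46
,Thiopurine S-methyltransferase,P51580,-8.89
,Myeloperoxidase,P05164,-8.54
,Histamine H1 receptor,P35367,-8.29
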