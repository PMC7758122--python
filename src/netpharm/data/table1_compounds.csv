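abbrev,name,cas,pubchem_cid,mw,content_mg_per_ml,metabolite_of
5CQA,Neochlorogenic acid,906-33-2,5280633,354.31,2.51,NA
CGA,Chlorogenic acid,327-97-9,1794427,354.31,4.36,NA
4CQA,Cryptochlorogenic acid,905-99-7,9798666,354.31,2.01,NA
CAA,Caffeic acid,331-39-5,689043,180.15,0.09,NA
IsoB,Isochlorogenic acid B,14534-61-3,5281780,516.45,0.33,NA
IsoA,Isochlorogenic acid A,89919-62-0,6474310,516.45,0.19,NA
IsoC,Isochlorogenic acid C,57378-72-0,6474309,516.45,0.34,NA
Gen,Geniposide,169799-41-1,107848,404.36,8.16,NA
Sec,Secoxyloganin,58822-47-2,162868,404.36,0.81,NA
FA,Ferulic acid,537-98-4,445858,194.18,NA,CAA
DFA,Dihydroferulic acid,NA,17865499,196.20,NA,CAA
Gep,Genipin,6902-77-8,442424,226.22,NA,Gen
3HCA,3'-Hydroxycinnamic acid,588-30-7,637541,164.16,NA,CAA
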