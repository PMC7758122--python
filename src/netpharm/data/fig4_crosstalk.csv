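from_pathway,to_pathway,connector,is_feedback
estrogen signaling pathway,NF-κB signaling pathway,ER/BCL2,0
estrogen signaling pathway,MAPK signaling pathway,Ras,0
PI3K-AKT signaling pathway,NF-κB signaling pathway,IKK/IκBα,0
PI3K-AKT signaling pathway,MAPK signaling pathway,Ras,0
PI3K-AKT signaling pathway,cGMP-PKG signaling pathway,AKT/eNOS/NO,0
cGMP-PKG signaling pathway,MAPK signaling pathway,Ras,0
cGMP-PKG signaling pathway,calcium signaling pathway,PKG/PLCβ/IP3R,0
cGMP-PKG signaling pathway,NF-κB signaling pathway,PKG/CREB,0
cAMP signaling pathway,PI3K-AKT signaling pathway,cAMP,0
cAMP signaling pathway,calcium signaling pathway,cAMP/Ca2+,0
cAMP signaling pathway,NF-κB signaling pathway,cAMP,0
cAMP signaling pathway,MAPK signaling pathway,Ras,0
MAPK signaling pathway,NF-κB signaling pathway,Ras,0
calcium signaling pathway,NF-κB signaling pathway,PKC,0
calcium signaling pathway,cAMP signaling pathway,AC/PKCθ,1
NF-κB signaling pathway,PI3K-AKT signaling pathway,IL-1β/TNFα/IκBα,1
NF-κB signaling pathway,estrogen signaling pathway,IL-6/PTGS2/MMPs,1
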