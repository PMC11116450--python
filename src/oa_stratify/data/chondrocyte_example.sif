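# Illustrative chondrocyte-like signed regulatory graph.
# 8 synovial-fluid inputs -> 3 internal signalling hubs -> 8 output TFs.
# source<TAB>sign<TAB>target
IL-6	+	STAT
IFNg	+	STAT
IL-8	+	IKK
TNFa	+	IKK
IL-18	+	IKK
IL-17	+	MAPK
IL-4	-	IKK
IL-4	+	FOXO
IL-4	+	SOX9
VEGF	+	HIF2a
IKK	+	NFkB
MAPK	+	AP1
STAT	+	AP1
STAT	+	CREB
NFkB	-	FOXO
NFkB	-	SOX9
NFkB	+	Runx2
MAPK	-	FOXO
AP1	-	CITED2
SOX9	+	CITED2
HIF2a	+	Runx2
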