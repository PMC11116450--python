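# Default mapping from synovial-fluid analyte columns to the example
# network's input nodes.  The panel's remaining analytes (IL-1RA, MCP1,
# LEPTIN) have no corresponding input in the simplified graph.
IL-6: IL-6
IL-8: IL-8
IL-4: IL-4
TNFa: TNFa
IL-18: IL-18
IFNg: IFNg
IL-17: IL-17
VEGF-A: VEGF
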