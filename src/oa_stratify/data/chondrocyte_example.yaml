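# Roles for the bundled illustrative chondrocyte-like network.
roles:
  IL-6: input
  IL-8: input
  IL-4: input
  TNFa: input
  IL-18: input
  IFNg: input
  IL-17: input
  VEGF: input
  IKK: internal
  MAPK: internal
  STAT: internal
  CITED2: output_tf
  CREB: output_tf
  Runx2: output_tf
  FOXO: output_tf
  SOX9: output_tf
  HIF2a: output_tf
  NFkB: output_tf
  AP1: output_tf
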