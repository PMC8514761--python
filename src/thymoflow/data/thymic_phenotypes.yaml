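# Default marker phenotypes of human thymic cell populations used by the
# synthetic-data generator and by the panel-calibrated fixed gates.
#
# Intensities are log-normal on the raw fluorescence scale: a population's
# marker draws exp(Normal(log(level), sigma)). The four named levels are
# geometric means chosen so that adjacent levels sit >= 3 sigma apart on the
# asinh scale (cofactor 150) at the default sigma of 0.4.
#
# Unlisted markers default to "neg". Edit freely; the file is data, not code.
cofactor: 150.0
sigma: 0.4
levels:
  neg: 20.0
  lo: 500.0
  int: 3000.0
  hi: 20000.0
markers:
  [CD45, EpCAM, pdpn, CD49f, CD200, CD31, HLA-DR, CD11c, CD11b, CD3, CD1a, CD4, CD8]
populations:
  cTEC:      {EpCAM: lo, pdpn: hi, CD49f: hi, HLA-DR: hi}
  mTEC:      {EpCAM: hi, pdpn: int, CD49f: lo, CD200: hi, HLA-DR: hi}
  FB:        {pdpn: lo, CD49f: lo, CD200: int}
  EC:        {CD31: hi, CD49f: int, CD200: int}
  LEC:       {CD31: hi, pdpn: hi, CD49f: hi, CD200: hi}
  DC:        {CD45: hi, HLA-DR: hi, CD11c: hi, CD11b: hi}
  MP:        {CD45: hi, HLA-DR: hi, CD11b: hi}
  thymocyte_immature: {CD45: hi, CD3: int, CD1a: hi, CD4: int, CD8: int}
  thymocyte_CD4SP:    {CD45: hi, CD3: hi, CD1a: lo, CD4: hi}
  thymocyte_CD8SP:    {CD45: hi, CD3: hi, CD1a: lo, CD8: hi}
  B:         {CD45: hi, HLA-DR: hi}
  other:     {CD49f: lo}
# Gate node each simulated population should land in (B cells and the
# unspecified CD45- remainder fall outside every gate by design).
expected_gate:
  cTEC: cTEC
  mTEC: mTEC
  FB: FB
  EC: EC
  LEC: LEC
  DC: DC
  MP: MP
  thymocyte_immature: thymocyte
  thymocyte_CD4SP: CD4SP
  thymocyte_CD8SP: CD8SP
  B: ungated
  other: ungated
# Retention class per population for the stepwise-enrichment emulation.
enrichment_class:
  cTEC: stromal
  mTEC: stromal
  FB: stromal
  EC: stromal
  LEC: stromal
  DC: cd45pos
  MP: cd45pos
  thymocyte_immature: cd45pos
  thymocyte_CD4SP: cd45pos
  thymocyte_CD8SP: cd45pos
  B: cd45pos
  other: cd45neg_nonstromal
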