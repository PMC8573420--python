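{
  "LFOA": ["CH02", "CH03", "CH04", "CH10", "CH11"],
  "RFOA": ["CH04", "CH05", "CH06", "CH12", "CH13"],
  "LOFA": ["CH18", "CH19"],
  "ROFA": ["CH19", "CH20"],
  "LPTBA": ["CH08"],
  "RPTBA": ["CH15"],
  "LDLPFC": ["CH01", "CH09", "CH17"],
  "RDLPFC": ["CH07", "CH14", "CH21"],
  "LIPFG": ["CH16"],
  "RIPFG": ["CH22"]
}
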