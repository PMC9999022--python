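# The 11 guideline treatment sequences: first-line regimen, second-line
# regimen, then best supportive care until death.
strategies:
  ND:  {first_line: N+C,   second_line: docetaxel}
  NT:  {first_line: N+C,   second_line: tislelizumab}
  NN:  {first_line: N+C,   second_line: nivolumab}
  CD:  {first_line: chemo, second_line: docetaxel}
  CT:  {first_line: chemo, second_line: tislelizumab}
  CN:  {first_line: chemo, second_line: nivolumab}
  PED: {first_line: P+C,   second_line: docetaxel}
  SID: {first_line: SI+C,  second_line: docetaxel}
  CAD: {first_line: CA+C,  second_line: docetaxel}
  TID: {first_line: T+C,   second_line: docetaxel}
  SUD: {first_line: SU+C,  second_line: docetaxel}
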