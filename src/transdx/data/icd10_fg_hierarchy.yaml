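# Two-level convenience hierarchy for ICD-10 chapters V (F) and VI (G):
# each first-level block with every second-level code it spans.
- range: F00-F09
  narrow: [F00, F01, F02, F03, F04, F05, F06, F07, F08, F09]
- range: F10-F19
  narrow: [F10, F11, F12, F13, F14, F15, F16, F17, F18, F19]
- range: F20-F29
  narrow: [F20, F21, F22, F23, F24, F25, F26, F27, F28, F29]
- range: F30-F39
  narrow: [F30, F31, F32, F33, F34, F35, F36, F37, F38, F39]
- range: F40-F48
  narrow: [F40, F41, F42, F43, F44, F45, F46, F47, F48]
- range: F50-F59
  narrow: [F50, F51, F52, F53, F54, F55, F56, F57, F58, F59]
- range: F60-F69
  narrow: [F60, F61, F62, F63, F64, F65, F66, F67, F68, F69]
- range: F70-F79
  narrow: [F70, F71, F72, F73, F74, F75, F76, F77, F78, F79]
- range: F80-F89
  narrow: [F80, F81, F82, F83, F84, F85, F86, F87, F88, F89]
- range: F90-F98
  narrow: [F90, F91, F92, F93, F94, F95, F96, F97, F98]
- range: F99
  narrow: [F99]
- range: G00-G09
  narrow: [G00, G01, G02, G03, G04, G05, G06, G07, G08, G09]
- range: G10-G14
  narrow: [G10, G11, G12, G13, G14]
- range: G20-G26
  narrow: [G20, G21, G22, G23, G24, G25, G26]
- range: G30-G32
  narrow: [G30, G31, G32]
- range: G35-G37
  narrow: [G35, G36, G37]
- range: G40-G47
  narrow: [G40, G41, G42, G43, G44, G45, G46, G47]
- range: G50-G59
  narrow: [G50, G51, G52, G53, G54, G55, G56, G57, G58, G59]
- range: G60-G64
  narrow: [G60, G61, G62, G63, G64]
- range: G70-G73
  narrow: [G70, G71, G72, G73]
- range: G80-G83
  narrow: [G80, G81, G82, G83]
- range: G90-G99
  narrow: [G90, G91, G92, G93, G94, G95, G96, G97, G98, G99]
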