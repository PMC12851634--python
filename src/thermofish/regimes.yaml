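# Seasonal sinusoid parameters fitted to western Wadden Sea temperatures
# for a cooler (1980-1989) and a warmer (2010-2019) decade.
"1980s":
  T_mean: 12.85
  a: 5.3
  omega: 187
  GS: 250
"2010s":
  T_mean: 14.3
  a: 5.25
  omega: 187
  GS: 250
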