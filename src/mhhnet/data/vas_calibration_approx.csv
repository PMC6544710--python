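# Approximate VAS-vs-tDCS calibration points (synthetic example file).
# Mean 0-10 visual-analog-scale pain levels around 0 / 1 / 2 mA motor-cortex
# tDCS, read approximately from published group means; NOT measured data and
# NOT authoritative -- supply your own calibration CSV for real use.
# Columns: dose [mA], response [VAS 0-10], source
dose,response,source
0.0,6.8,approximate literature mean (no stimulation)
1.0,3.2,approximate literature mean (1 mA anodal M1)
2.0,2.7,approximate literature mean (2 mA anodal M1)
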