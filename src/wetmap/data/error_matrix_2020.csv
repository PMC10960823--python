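# Validation error matrix (2020) of the global 30 m wetland dataset whose
# tile format this package implements, as printed: reference classes in
# rows, map classes in columns, entries in percent of area.  The Total row
# and column are the independently rounded printed marginals.
class,NWT,PWT,SWP,MSH,FFT,SLE,MGV,SMH,TFT,Total
NWT,45.741,0.233,1.114,0.511,0.092,0.035,0.088,0.066,0.326,48.206
PWT,0.313,7.390,0,0,0,0,0,0,0,7.703
SWP,0.313,0.145,7.646,0.739,0,0.044,0.048,0,0.004,8.94
MSH,0.079,0.524,2.874,7.034,0.198,0.079,0.035,0.088,0.057,10.969
FFT,0.189,0,0.352,0.445,1.747,0.018,0.009,0.009,0.022,2.791
SLE,0.110,0.026,0.013,0.075,0.185,3.658,0,0.004,0.004,4.076
MGV,0.044,0.044,0.207,0.057,0.009,0,4.745,0.048,0.031,5.185
SMH,0.357,0.233,0.172,0.242,0.374,0.009,0.546,3.847,0.665,6.444
TFT,0.048,0.092,0.013,0.013,0.150,0.035,0.031,0.163,5.141,5.687
Total,47.194,8.689,12.391,9.116,2.755,3.878,5.502,4.226,6.25,
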