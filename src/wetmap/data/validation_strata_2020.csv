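# Validation-point stratum sizes for the 2020 assessment of the global
# 30 m wetland dataset: expert-interpreted points per sampling stratum.
stratum,wetland,count
non_wetland,0,10952
inland_wetland,1,7833
coastal_wetland,1,3934
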