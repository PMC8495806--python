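# trophicflux assimilation-efficiency table; comma-separated, dot-decimal, UTF-8
# e is the proportion of ingested energy assimilated through the gut wall.
resource_type,e,reference_temperature_C,source
detritus,0.158,20,Lang et al. 2017 literature mean for detrital resources
plant,0.545,20,Lang et al. 2017 literature mean for autotroph resources
animal,0.906,20,Lang et al. 2017 literature mean for heterotroph resources
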