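# trophicflux length-mass regression table; comma-separated, dot-decimal, UTF-8
# mass = base^(intercept + exp_length*log(L_mm) [+ exp_width*log(W_mm)]), base per 'scale'
# COEFFICIENTS ARE SYNTHETIC PLACEHOLDERS in a realistic range; replace with
# published fits (Sohlstrom et al. 2018, Mercer et al. 2001, Ruiz-Lupion et al. 2019).
key,scale,intercept,exp_length,exp_width,mass_basis,in_unit,out_unit,source
default,log10,-0.85,2.5,,fresh,mm,mg,synthetic placeholder (generic arthropod)
beetle,log10,-0.80,2.6,,fresh,mm,mg,synthetic placeholder
spider,log10,-0.90,2.4,,dry,mm,mg,synthetic placeholder (dry-mass output)
length_width,log10,-0.70,1.6,1.0,fresh,mm,mg,synthetic placeholder (two-dimension model)
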