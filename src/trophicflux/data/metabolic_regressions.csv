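# trophicflux metabolic-rate regression table; comma-separated, dot-decimal, UTF-8
# ln X = ln_x0 + mass_exp * ln(M) - activation_energy_eV / (k * T_Kelvin), k = 8.62e-5 eV/K
# COEFFICIENTS ARE SYNTHETIC PLACEHOLDERS in a realistic range; replace with
# taxon-specific fits (e.g. Ehnes et al. 2011 for soil invertebrates) before
# drawing scientific conclusions from absolute flux values.
key,scale,ln_x0,mass_exp,activation_energy_eV,mass_unit,out_unit,source
default,ln,21.0,0.71,0.69,mg fresh,J/h,synthetic placeholder (generic invertebrate)
detritivore,ln,21.0,0.71,0.69,mg fresh,J/h,synthetic placeholder
herbivore,ln,21.0,0.71,0.69,mg fresh,J/h,synthetic placeholder
omnivore,ln,21.0,0.71,0.69,mg fresh,J/h,synthetic placeholder
predator,ln,21.2,0.75,0.69,mg fresh,J/h,synthetic placeholder
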