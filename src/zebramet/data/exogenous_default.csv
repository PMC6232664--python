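name,formula,monoisotopic_mass,adducts,max_isotope
HEPES,C8H18N2O4S,,M+H;M+Na;M+K,2
gentamicin,C21H43N5O7,,M+H;M+Na;M+K,2
paracetamol,C8H9NO2,,M+H;M+Na;M+K,2
tenofovir_disoproxil,C19H30N5O10P,,M+H;M+Na;M+K,2
tenofovir,C9H14N5O4P,,M+H;M+Na;M+K,2
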