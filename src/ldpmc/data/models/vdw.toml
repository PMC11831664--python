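# Water-like van der Waals fluid: constants chosen so the critical point
# matches water (T_c = 647.096 K, rho_c = 322 kg/m^3 = 10.76 nm^-3).
# Used as the closed-form oracle backend throughout the test suite.
kind = "vdw"
name = "vdw"
a_K_nm3 = 67.63
b_nm3 = 0.03097
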