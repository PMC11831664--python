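# Single-site Mie(8, 6) water fitted to saturated liquid density and
# interfacial tension, with temperature-dependent epsilon(T) and sigma(T).
#
# PLACEHOLDER COEFFICIENTS: see vle.toml; replace with the published
# polynomials before quantitative use.
kind = "saft-vr-mie"
name = "ift"
lambda_r = 8.0
lambda_a = 6.0
epsilon_coeffs = [360.0]   # K; placeholder, constant in T
sigma_coeffs = [0.284]     # nm; placeholder, constant in T
T_range = [280.0, 440.0]
provenance = "placeholder"
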