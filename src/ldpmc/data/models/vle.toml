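# Single-site Mie(8, 6) water fitted to saturated liquid density and vapor
# pressure, with temperature-dependent epsilon(T) and sigma(T).
#
# PLACEHOLDER COEFFICIENTS: the published temperature polynomials for this
# model live in the supplementary material of the original parametrization
# and are not redistributed here.  The constant values below only give a
# structurally valid, water-like stand-in; replace them with the published
# polynomials (ascending coefficients, T in kelvin) before quantitative use.
kind = "saft-vr-mie"
name = "vle"
lambda_r = 8.0
lambda_a = 6.0
epsilon_coeffs = [370.0]   # K; placeholder, constant in T
sigma_coeffs = [0.282]     # nm; placeholder, constant in T
T_range = [360.0, 520.0]
provenance = "placeholder"
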