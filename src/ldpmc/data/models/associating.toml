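# Single-site associating water: Mie(17.02, 6) plus four square-well
# association sites (2 H + 2 e).  The Mie block is the published single-site
# SAFT-VR Mie water parametrization.  The association well depth and bonding
# volume were re-fitted for this package's contact-value TPT1 closure of the
# association strength (see ldpmc.eos.association) against water saturation
# data (rho_l and p_v, 300-550 K); the published values belong to a
# different, tabulated correlation-integral closure and are not transferable.
kind = "saft-vr-mie"
name = "associating"
lambda_r = 17.02
lambda_a = 6.0
epsilon_over_kB = 266.68   # K
sigma_nm = 0.30063
citation = "single-site SAFT-VR Mie water with 4 association sites (2H + 2e)"

[assoc]
epsilon_over_kB = 1816.2       # K; re-fitted (published: 1985.4 with tabulated closure)
bond_volume_nm3 = 0.0014352    # re-fitted (published: 0.10169 with tabulated closure)
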