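# Ideal gas: zero excess free energy.  Degenerate reference model for
# engine validation (every move accepted, exact analytic observables).
kind = "ideal"
name = "ideal"
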