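# Example configuration for `etspin h2-pipeline --config <file>`
#
# Collinear H2···H2+ coupling-vs-distance study: FCI per spin sector,
# GMH diabatization, exponential decay fit.
#
# arrangement "parallel" (side-by-side stack, default) or "collinear"
# d_intra     intramolecular H-H bond length (Å): 0.74 equilibrium, 2.50 stretched
# grid        center-of-mass separations (Å)
# basis       one of the vendored bases: sto-3g, cc-pvdz, aug-cc-pvdz, aug-cc-pvtz
# drop_d      drop d shells from the dimer basis (keeps the FCI desk-scale)
# sectors     spin sectors to solve ("doublet" = LS, "quartet" = HS)
# n_states    FCI roots per sector (>= 2; extra roots guard CT-state selection)
# convention  decay convention: "half" (A·e^(-βd/2)) or "full" (A·e^(-βd))

[pipeline]
d_intra = 0.74
arrangement = "parallel"
grid = [4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0]
basis = "aug-cc-pvtz"
drop_d = true
sectors = ["doublet", "quartet"]
n_states = 3
convention = "half"
seed = 0
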