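# rWAIL, flexible version.  Names and units mirror the published
# parameter table exactly.  Internal model units: kcal/mol, Å, e, deg.
variant: flexible
q_M: -1.3464          # e
q_H: 0.6732           # e
a: 0.2                # dimensionless M-site factor
A_OO: 240900.0        # kcal/mol (table value 240.9e3)
alpha: 4.098          # 1/Å
C_OO: 610.578         # kcal Å^6/mol
A_4: 78.759           # kcal Å^4/mol
r_c: 2.483            # Å
r_e: 0.9507           # Å
k2: 1263.0            # kcal/(mol Å^2)
k3: -4831.0           # kcal/(mol Å^3)
k4: 10777.0           # kcal/(mol Å^4)
theta_e: 106.66       # deg
k_theta: 80.81        # kcal/(mol rad^2)
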