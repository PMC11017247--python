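# rWAIL, rigid ensemble-geometry variant built from the 273 K geometry.
variant: EG273
q_M: -1.3464          # e
q_H: 0.6732           # e
a: 0.2                # dimensionless M-site factor
A_OO: 240900.0        # kcal/mol (table value 240.9e3)
alpha: 4.098          # 1/Å
C_OO: 610.578         # kcal Å^6/mol
A_4: 78.759           # kcal Å^4/mol
r_c: 2.483            # Å
r_e: 0.9709           # Å
theta_e: 105.34       # deg
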