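"""Evaluate the elastic-foundation cartilage pressure law.

Computes the foundation stiffness K from the cartilage elastic modulus
and Poisson ratio, then the contact pressure at a few penetration
depths of the 0.4 mm layer.
"""
import numpy as np

from tmjsim import ef_pressure, ef_stiffness

E, nu, h = 2.7e6, 0.49, 0.4e-3
K = ef_stiffness(E, nu)
print(f"foundation stiffness K = {K/1e6:.3f} MPa  (negative: p = K ln(1-d/h) > 0)")
for frac in (0.05, 0.1, 0.25, 0.5, 0.9):
    p = ef_pressure(frac * h, h, K)
    print(f"  d = {frac:4.2f} h  ->  p = {p/1e6:7.3f} MPa")
print("The pressure rises logarithmically and diverges toward full-layer")
print("compression - deep penetrations are strongly resisted.")
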