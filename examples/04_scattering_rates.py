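"""Separate single scattering, multiple scattering and noise by symmetry.

Reciprocity makes the single- and multiple-scattering parts of a focused
matrix symmetric under exchange of the focal points, while electronic
noise splits evenly between the symmetric and anti-symmetric subspaces.
The anti-symmetry degree beta on the de-scanned support therefore
resolves the incoherent background into its two origins:
alpha_M = (1 - 2 beta) alpha_B and alpha_N = 2 beta alpha_B.

The demonstration first calibrates beta on synthetic matrices, then
recovers rates injected into a full acquisition.
"""

import numpy as np

import umi
from umi.studies import beta_calibration_study, rate_recovery_study

cal = beta_calibration_study(seed=0, n_realizations=25)
print("beta on an exactly symmetric matrix:      "
      f"{cal['beta_symmetric']:.4f} (reciprocal -> 0)")
print("beta on an exactly anti-symmetric matrix: "
      f"{cal['beta_antisymmetric']:.4f} (non-reciprocal -> 1)")
print("beta on iid complex Gaussian matrices:    "
      f"{cal['beta_iid_mean']:.4f} +- {cal['beta_iid_std']:.4f} (noise -> 1/2)")

print("\nend-to-end recovery from a calibrated three-component acquisition")
print("(speckle + reciprocal multiple-scattering surrogate + noise, "
      "injected rates 0.25 / 0.25) — takes a minute ...")
rec = rate_recovery_study(seed=5)
print(f"measured beta = {rec['beta']:.3f}, background fraction "
      f"alpha_B = {rec['alpha_b']:.3f}")
print(f"recovered alpha_M = {rec['alpha_m']:.3f}, "
      f"alpha_N = {rec['alpha_n']:.3f} (injected 0.250 / 0.250)")
print(f"local contrast F = alpha_S / alpha_B = {rec['contrast']:.2f}")
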