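"""Reverse and forward mode of the consumer budget model.

Reverse mode answers "what must a lobster eat to grow at G?"; forward mode
answers "what growth and waste follow from these intakes?".  The two are
exact inverses, and every evaluation closes the carbon and nitrogen books.
"""

from geostoich import GSParameters, forward_mode, reverse_mode

params = GSParameters(f_V=0.1, phi=0.5, k_N=0.8, beta_V=0.9, beta_H=0.8)
growth = 0.01  # day^-1, i.e. 1% of body carbon per day

intake, ledger = reverse_mode(growth, params)
print(f"to grow at {growth} day^-1 the consumer must ingest")
print(f"  protein C     I_V = {intake.I_V:.6f} mol C (mol C)^-1 day^-1")
print(f"  non-protein C I_H = {intake.I_H:.6f} mol C (mol C)^-1 day^-1")
print(f"  respiration R = {ledger.R:.6f}, faecal C = {ledger.F_C:.6f}")
print(f"  faecal N = {ledger.F_N:.6f}, excreted N = {ledger.U_N:.6f}")

forward = forward_mode(intake, params)
print(f"feeding those intakes back in returns G = {forward.G:.6f} "
      f"({forward.limiting} pathways)")

c_gap = intake.total - (forward.G + forward.R + forward.F_C)
n_gap = intake.I_V / params.theta_V - (
    forward.G / params.theta_Z + forward.U_N + forward.F_N
)
print(f"carbon closure error {c_gap:.2e}, nitrogen closure error {n_gap:.2e}")
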