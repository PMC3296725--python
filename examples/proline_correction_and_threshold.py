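"""From a measured global dG_HX to the metastable-state threshold dG_X.

Uses the cobrotoxin-style ledger: a small three-finger toxin whose global
exchange free energy (3.9 kcal/mol) exceeds its unfolding free energy
(2.3 kcal/mol). Two trans prolines (preceded by Thr and a cystine Cys)
account for only ~0.1 kcal/mol of the gap, so the remaining discrepancy
points at the exchange side, and the metastable search threshold becomes
dG_X = dG_U* + (dG_HX - dG_HX*).
"""

from hxfold import (EnergyLedger, ProlineContext, ProlineIsomerTable,
                    compare_energies, proline_correction)

dg_hx = 3.9      # global exchange free energy, kcal/mol (mean of 4 largest)
dg_u = 2.3       # from the melting curve
prolines = [ProlineContext("T", "trans"), ProlineContext("C", "trans")]

table = ProlineIsomerTable.load()
dg_hx_star = proline_correction(dg_hx, prolines, table, T=298.0)
print(f"dG_HX  = {dg_hx:.1f} kcal/mol")
print(f"dG_HX* = {dg_hx_star:.2f} kcal/mol "
      f"(proline correction {dg_hx - dg_hx_star:.2f})")
print(f"dG_HX* vs dG_U: {compare_energies(dg_hx_star, dg_u)} "
      "(tolerance 0.4 kcal/mol)")

ledger = EnergyLedger(dg_u=dg_u, dg_u_star=dg_u, dg_hx=dg_hx,
                      dg_hx_star=round(dg_hx_star, 1))
print(f"dG_X   = {ledger.dg_x:.1f} kcal/mol  "
      "(residues with dG_HX above this are metastable-state candidates)")
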