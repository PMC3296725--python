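"""Intrinsic (random-coil) exchange rates for each backbone amide.

Builds the per-NH k_rc profile of a short sequence under typical native
H/D-exchange conditions (pH-meter reading 6.6 in D2O, 298 K) and shows
how pD moves the rates. k_rc is what an amide would exchange at with no
structural protection; measured rates are slower by the protection
factor.
"""

from hxfold import ExchangeConditions, ReferenceRateTable
from hxfold.rates import krc_sequence_profile

sequence = "MQIFVKTLTG"   # residue 1 has a free amine, no amide NH
table = ReferenceRateTable.load()
conditions = ExchangeConditions(pH_read=6.6, temperature=298.0)

print(f"sequence: {sequence}  (pD {conditions.pD:.1f}, "
      f"{conditions.temperature:.0f} K, D2O)")
print("pos  aa   k_rc (min^-1)")
for pos, k in krc_sequence_profile(sequence, conditions, table):
    print(f"{pos + 1:3d}   {sequence[pos]}   {k:10.3g}")

print("\nAn NH with measured k_ex 1000-fold slower than its k_rc has a")
print("protection factor of 1000, i.e. dG_HX = RT ln 1000 ~ 4.1 kcal/mol.")
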