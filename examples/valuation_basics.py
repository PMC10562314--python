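"""Standard equivalent, value coefficient table, and a one-hectare ESV.

The unit value E_n is one seventh of the annual grain output value of a
hectare of farmland; scaling the dimensionless equivalent matrix by E_n
gives per-hectare service values for each land class, and class areas
turn those into a total ecosystem service value.
"""

import numpy as np

import esvdyn as e

# E_n from the regional grain price (RMB/kg) and average yield (kg/ha)
en = e.standard_equivalent(price=1.23, yield_=6591.33)
print(f"standard equivalent E_n = {en.rounded:.2f} RMB/ha")

table = e.build_value_table()
print("\nper-hectare totals by land class (RMB/ha):")
for cls, total in table.column_totals().items():
    print(f"  {cls:13s} {total:10.2f}")

# one hectare of plowland, no adjustment: the plowland column total
result = e.esv(np.array([1.0, 0, 0, 0, 0, 0]), table)
print(f"\n1 ha plowland, S = PI = 1: total ESV = {result.total:.2f} RMB")

# a small mixed landscape with adjustment factors
areas = np.array([1200.0, 400.0, 300.0, 50.0, 600.0, 10.0])  # hectares
adjusted = e.esv(areas, table, s_factor=1.1, pi_factor=0.95)
print(f"\nmixed landscape ({areas.sum():.0f} ha), S=1.1, PI=0.95:")
print(f"  total ESV = {adjusted.total / 1e8:.3f} x10^8 RMB")
print("  by category (x10^8 RMB):")
for cat, v in adjusted.by_category.items():
    print(f"    {cat:12s} {v / 1e8:.3f}")
# the four category values sum to the total; contributions sum to 1
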