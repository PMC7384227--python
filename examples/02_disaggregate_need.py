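"""District counts to per-cell need for care.

Builds a miniature two-municipality district by hand, splits a district
diagnosis count proportionally by stratum population, spreads it evenly
over grid cells, and shows that the total is conserved at every level.
"""

import pandas as pd

from fcavisits import assign_to_grid, disaggregate_to_municipality, normalize_per_capita

district_need = pd.DataFrame(
    {
        "district_id": [0, 0],
        "age_group": ["70-74", "70-74"],
        "sex": ["male", "female"],
        "diagnosis": ["I48", "I48"],
        "count": [100, 80],
    }
)
strata = pd.DataFrame(
    {
        "municipality_id": [0, 0, 1, 1],
        "age_group": ["70-74"] * 4,
        "sex": ["male", "female", "male", "female"],
        "population": [300.0, 350.0, 700.0, 450.0],
    }
)

muni = disaggregate_to_municipality(district_need, strata, {0: 0, 1: 0})
print("municipality allocations:")
print(muni.to_string(index=False))
print(f"district total preserved: {muni['count'].sum():.1f} (input {100 + 80})")

cells = pd.DataFrame(
    {
        "cell_id": range(6),
        "x_km": [0.5, 1.5, 2.5, 0.5, 1.5, 2.5],
        "y_km": [0.5, 0.5, 0.5, 1.5, 1.5, 1.5],
        "population": [200.0, 250.0, 200.0, 400.0, 350.0, 400.0],
        "municipality_id": [0, 0, 0, 1, 1, 1],
        "district_id": 0,
    }
)
cells = assign_to_grid(muni, cells)
print("\nper-cell need (even split within each municipality):")
print(cells[["cell_id", "municipality_id", "need_I48"]].to_string(index=False))

rate = normalize_per_capita(cells, "I48")
print("\nper-capita rate (cases per person-year) per cell:")
print(rate.round(4).to_string())
# The rate surface is what reveals geographic variation in disease burden
# independently of where people live.
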