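"""Fixed-depth vs equivalent-soil-mass (ESM) SOC stocks.

Fixed-depth accounting compares carbon within the same 0-50 cm depth, which
flatters denser profiles (they simply contain more soil). ESM accounting
evaluates cumulative stock at common reference soil masses — here the
lightest profile's masses — removing that bulk-density bias.
"""

from soilfq.carbon import (
    reference_masses_lightest,
    stock_equivalent_soil_mass,
    stock_profile_fixed,
)
from soilfq.io import SoilLayerRecord


def profile(treatment, bds, socs):
    return [SoilLayerRecord(treatment, 1, 10 * i, 10 * (i + 1), bd, 12.0, soc)
            for i, (bd, soc) in enumerate(zip(bds, socs))]


# same SOC concentrations, but the "plowed" profile is denser throughout
loose = profile("no-till", [1.15, 1.25, 1.35, 1.40, 1.45], [10, 8, 6, 5, 4])
dense = profile("plowed",  [1.30, 1.40, 1.45, 1.50, 1.55], [10, 8, 6, 5, 4])

ref = reference_masses_lightest([loose, dense])
print("reference cumulative masses (Mg/ha):", [f"{m:.0f}" for m in ref])

for prof in (loose, dense):
    fixed = stock_profile_fixed(prof)
    esm = stock_equivalent_soil_mass(prof, ref)
    print(f"\n{prof[0].treatment}:")
    print(f"  fixed-depth 0-50 cm stock: {fixed.cumulative_stock_0_50:.2f} Mg/ha")
    print(f"  ESM stock at reference:    {esm.cumulative_stock_0_50:.2f} Mg/ha")

print("\nFixed-depth accounting credits the denser profile with extra carbon")
print("that is only extra soil; at equal soil mass the gap closes.")
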