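"""Generate a virtual tillage experiment and inspect its structure.

The design mirrors a replicated summer-fallow tillage trial: 3 treatments
(FNT no-till, FST subsoiling, FPT plowing) x 5 soil layers of 10 cm x 3
replicates, with planted treatment effects and replicate noise.
"""

from soilfq.simulate import default_paper_like_design, generate_experiment

design = default_paper_like_design(seed=42)
exp = generate_experiment(design)

print(f"soil records:      {len(exp.soil)} (3 treatments x 5 layers x 3 reps)")
print(f"fraction sets:     {len(exp.fractions)}")
print(f"yield records:     {len(exp.yields)} (plot level, no layer index)")

r = exp.soil[0]
print(f"\nfirst soil record: {r.treatment} rep {r.replicate}, "
      f"{r.depth_top:g}-{r.depth_bottom:g} cm")
print(f"  BD = {r.bulk_density:.3f} g/cm^3, SWC = {r.water_content:.1f} %, "
      f"SOC = {r.soc_content:.2f} g/kg")
print("\nBD is drawn around the treatment x layer effect grid; rerunning with")
print("the same seed reproduces the table byte for byte.")
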