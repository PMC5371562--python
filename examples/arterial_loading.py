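"""Inert-gas loading of blood along the brain arterial path.

After decompression the tissue around an artery can hold far more
dissolved inert gas than the arterial blood (here 500 vs 101 kPa).  Gas
diffuses through the vessel wall into the blood, fastest in distal
segments where flow is low and walls are thin.  This script prints the
tension at the exit of each segment of the packaged
aorta-to-anterior-cerebral path, then shows how a local flow reduction
in the terminal segment amplifies the loading.
"""

from decobubble import TensionQuery, default_brain_path, flow_reduction_scan, tree_tension_profile

tree = default_brain_path()
query = TensionQuery(entrance_kpa=101.0, tissue_kpa=500.0)

profile = tree_tension_profile(query, tree)
print("tension at segment exits (full flow):")
for name in [s.name for s in tree.segments]:
    seg = profile[profile["segment"] == name]
    print(f"  {name:18s} {seg['tension_kpa'].iloc[-1]:8.3f} kPa")

scan = flow_reduction_scan(query, tree, "anterior_cerebral", [1.0, 0.5, 0.2, 0.1])
print("\nflow reduction in the anterior cerebral artery:")
for _, row in scan.iterrows():
    print(f"  flow x{row.flow_scale:4.2f} -> exit {row.exit_kpa:7.3f} kPa "
          f"(rise {row.rise_pct:5.2f}% of entrance tension)")

print("\nThe rise at full flow is ~1% of the entrance tension; cutting the"
      "\nterminal segment's flow multiplies its loading exponent and raises"
      "\nthe exit tension, priming distal arteries for local bubble growth.")
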