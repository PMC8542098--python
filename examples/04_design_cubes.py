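"""Re-derive the cube design from the original gram cutoffs.

Converts each group's original cutoffs to volumes using the shipped mean
densities, clusters the resulting 52 cube side lengths into 8 core cubes
(complete-linkage agglomeration), and appends the two flank cubes that
carry no cutoff.  The recovered sides land close to the printed cube sizes
(22, 27, 32, 38, 46, 52, 55, 89 mm) — the authors' exact grouping is not
recoverable, so agreement is approximate by design.
"""

from gdqs import boundaries_to_volumes, cluster_cubes, load_taxonomy

taxonomy = load_taxonomy()
raw = boundaries_to_volumes(taxonomy)
print(f"{len(raw)} cutoff volumes span {raw.side_mm.min():.1f}-{raw.side_mm.max():.1f} mm")

design = cluster_cubes(raw, k_core=8)
print("\ncore cube sides (mm) with member cutoffs:")
for cube in design.clustered_cubes:
    members = ", ".join(f"{g}/{b}" for g, b in cube["members"][:3])
    extra = "" if len(cube["members"]) <= 3 else f", +{len(cube['members']) - 3} more"
    print(f"  {cube['side_mm']:6.1f}  ({members}{extra})")
print(f"\nfull set incl. flanks: {[round(s, 1) for s in design.cube_sides]}")
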