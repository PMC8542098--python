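"""Load the shipped taxonomy and audit the cutoff/cube design.

Prints the structural counts (26 collection groups carrying 54 cutoffs,
merged to 25 groups / 51 cutoffs for reporting, 10 cubes) and the boundaries
where the printed gram cutoff deviates most from density x cube volume —
the two fish-and-shellfish cutoffs are known outliers of the design.
"""

from gdqs import cutoff_consistency_report, load_taxonomy

taxonomy = load_taxonomy()
print(f"collection groups : {len(taxonomy.groups)}")
print(f"boundaries        : {len(taxonomy.boundaries)}")
print(f"reporting groups  : {len(set(taxonomy.reporting_group_ids()))}")
print(f"reporting cutoffs : {taxonomy.reporting_boundary_count()}")
print(f"cubes             : {len(taxonomy.cubes)}")

report = cutoff_consistency_report(taxonomy)
worst = report.nlargest(4, "rel_deviation")
print("\nlargest cutoff-vs-density deviations (printed grams vs density x volume):")
print(
    worst[["group_id", "boundary", "operationalized_g", "predicted_g", "rel_deviation"]]
    .to_string(index=False, float_format=lambda v: f"{v:.3f}")
)
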