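"""Score every complete record and rank breed groups by weighted composite.

Each record gets quintile scores on 11 variables plus an untreated flag,
combined into production (/10), health (/6) and fatty-acid (/45) components
and two weighted composites with maximum 1. Breeds are ranked by mean
composite, ties broken by lower SD.
"""

from liprod import (
    apply_inclusion_criteria,
    default_config,
    generate_herd,
    rank_breeds,
    score_dataset,
)

herd = generate_herd(default_config(seed=1))
retained, included = apply_inclusion_criteria(herd)
scored = score_dataset(included, scope="pooled")

print(f"retained breed groups: {', '.join(sorted(retained))}")
print(f"scored records: {len(scored)}")
for composite in ("weighted_health", "weighted_production"):
    table = rank_breeds(scored, composite).table
    print(f"\n{composite} (mean ± SD, rank):")
    for breed, row in table.iterrows():
        print(f"  {breed:5s} {row['mean']:.2f} ± {row['sd']:.3f}  rank {int(row['rank'])}")
print("\n-> A composite of 1.0 would mean best quintile on every variable and")
print("   no treatments; group means near 0.6 match the published range.")
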