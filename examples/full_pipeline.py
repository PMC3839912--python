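"""The whole comparative-adsorption analysis on synthetic data.

simulate -> partition -> features -> compare -> census: generates a
31/46/24 AP/NAP/intermediate pool with planted compositional shifts,
recovers the groups from spot-volume ratios, identifies the discriminating
sequence features, and contrasts interaction censuses of toy structures.
"""

from siliprot import (
    ADSORBED,
    INTERMEDIATE,
    NON_ADSORBED,
    SeqGenParams,
    StructGenParams,
    census,
    compare_groups,
    feature_matrix,
    gen_sequences,
    gen_spot_tables,
    gen_structure,
    group_summary,
    partition,
)

# 1. sequences with planted aromatic depletion / Arg-Glu enrichment in APs
records, labels = gen_sequences(SeqGenParams(seed=1))
pool = dict(labels)
pool.update({f"INT_{i:03d}": INTERMEDIATE for i in range(24)})

# 2. spot tables and partitioning
gels = gen_spot_tables(pool, seed=2)
result = partition(*gels)
print("partition:", result.counts)

# 3. feature battery and group comparison
table = compare_groups(feature_matrix(records), result.table["label"])
print("\ntop discriminating features:")
print(table[["feature", "direction", "p_value", "p_adjusted"]]
      .head(5).to_string(index=False))

# 4. structural census of two toy groups (non-adsorbed-like group denser)
ap_like = [census(gen_structure(StructGenParams(
    30, planted=(("ionic", 1), ("pi_pi", 1)), seed=s))[0]) for s in range(3)]
nap_like = [census(gen_structure(StructGenParams(
    30, planted=(("ionic", 1), ("pi_pi", 2), ("cation_pi", 1)), seed=s))[0])
    for s in range(3, 6)]
summary = group_summary(ap_like, nap_like)
print("\npercent increase of interactions (NAP-like over AP-like):")
print({t: v for t, v in summary.formatted().items()})
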