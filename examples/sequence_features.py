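"""Compute the physicochemical feature battery for protein sequences.

Each protein yields 34 named features: residue-class fractions (aromatic,
polar, beta-strand, hydrophobic, alpha-helix, basic, acidic, neutral), the
20 per-residue fractions, length, molecular weight, isoelectric point,
Kyte-Doolittle GRAVY, and the positive/negative sliding-window charge
cluster ratios (12-residue window, >= 3 charges).
"""

from siliprot import ProteinRecord, SeqGenParams, feature_matrix, gen_sequences

records, labels = gen_sequences(SeqGenParams(n_ap=3, n_nap=3, seed=5))
features = feature_matrix(records)

cols = ["aromatic", "basic", "R", "length", "molecular_weight",
        "isoelectric_point", "gravy", "positive_cluster_ratio"]
print(features[cols].round(3))
print()

# a hand-made example: a lysine-rich tail forms a positive charge cluster
rich = ProteinRecord("k_rich", "KKKKKKKKKKKK" + "A" * 24)
print(feature_matrix([rich])[["basic", "positive_cluster_ratio"]].round(3))
# positive_cluster_ratio is the fraction of 12-residue windows holding at
# least three Arg/Lys residues - high values mark local charge patches.
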