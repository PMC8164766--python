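"""Tabulate motif hits against externally supplied ANTAR-protein counts.

The protein search itself (an HMM domain scan) is outside this package; its
per-genome counts are consumed as a TSV-like table and joined with the
scanner's per-genome RNA counts.
"""

import pandas as pd

from antarscan.cooccur import cooccurrence_summary

proteins = pd.DataFrame(
    [
        ("GCF_0001", "Trueperella pyogenes", 1),
        ("GCF_0002", "Xylanimonas cellulosilytica", 3),
        ("GCF_0003", "Mycobacterium smegmatis", 2),
        ("GCF_0004", "Corynebacterium glutamicum", 0),
    ],
    columns=["genome_id", "species", "n_antar_proteins"],
)
rna_counts = {"GCF_0001": 12, "GCF_0002": 1, "GCF_0004": 2}

table, buckets, _ = cooccurrence_summary(rna_counts, proteins)
print(table[["genome_id", "species", "n_rnas", "n_antar_proteins", "bucket"]]
      .to_string(index=False))
print("buckets:", buckets)
# RNA and protein counts need not match one-to-one: a single protein can act
# through many RNAs (many hits, one protein) and vice versa; the buckets
# summarize which genomes have only one side of the system
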