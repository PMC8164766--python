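"""Co-occurrence of motif hits and ANTAR-domain protein counts per genome.

Protein identification is consumed, never computed: any table with columns
``genome_id``, ``species`` and ``n_antar_proteins`` (optionally ``genus``)
works.  The summary tabulates per-genome RNA/protein counts and the marginal
RNA-only / protein-only / both / neither buckets.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

PROTEIN_COLUMNS = ("genome_id", "species", "n_antar_proteins")
BUCKETS = ("both", "rna_only", "protein_only", "neither")


def read_protein_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROTEIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protein table missing columns: {sorted(missing)}")
    return df


def cooccurrence_summary(
    rna_counts: Mapping[str, int],
    proteins: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int], pd.DataFrame | None]:
    """Join per-genome RNA counts with the protein table.

    Returns (per-genome table, bucket counts, per-genus quartiles or None).
    Genomes present only in ``rna_counts`` are included with zero proteins.
    """
    missing = set(PROTEIN_COLUMNS) - set(proteins.columns)
    if missing:
        raise ValueError(f"protein table missing columns: {sorted(missing)}")
    if proteins["genome_id"].duplicated().any():
        dups = proteins.loc[proteins["genome_id"].duplicated(), "genome_id"]
        raise ValueError(f"duplicate genome ids in protein table: {sorted(set(dups))}")
    if (proteins["n_antar_proteins"] < 0).any():
        raise ValueError("protein counts must be non-negative")

    table = proteins.copy()
    extra = sorted(set(rna_counts) - set(table["genome_id"]))
    if extra:
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "genome_id": extra,
                        "species": ["?"] * len(extra),
                        "n_antar_proteins": [0] * len(extra),
                    }
                ),
            ],
            ignore_index=True,
        )
    table["n_rnas"] = table["genome_id"].map(lambda g: rna_counts.get(g, 0))

    def bucket(row) -> str:
        has_rna, has_prot = row["n_rnas"] > 0, row["n_antar_proteins"] > 0
        if has_rna and has_prot:
            return "both"
        if has_rna:
            return "rna_only"
        if has_prot:
            return "protein_only"
        return "neither"

    table["bucket"] = table.apply(bucket, axis=1)
    table = table.sort_values("genome_id").reset_index(drop=True)
    buckets = {b: int((table["bucket"] == b).sum()) for b in BUCKETS}

    genus_quartiles = None
    if "genus" in table.columns:
        genus_quartiles = (
            table.groupby("genus")[["n_rnas", "n_antar_proteins"]]
            .quantile([0.25, 0.5, 0.75])
            .unstack()
        )
    return table, buckets, genus_quartiles
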