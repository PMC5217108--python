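"""Bundled reference dataset: the published per-specimen ITS2 summary.

The package ships the printed summary table for 88 Victorian mosquito
specimens (26 species) whose ITS2 barcode was characterized both by
Sanger sequencing and by MiSeq amplicon sequencing: per specimen, the
number of NGS alleles, the allele size range and average, the percentage
of Sanger bases above Q20, the post-trim Sanger length and the coverage
of the NGS alleles by the trimmed Sanger sequence. The three *Anopheles
annulipes* specimens are flagged ``full_length = 0``: their ~600 bp ITS2
exceeds what 2×250 bp reads can span, so their assembled alleles are
truncated and their coverage values exceed 100%.

Also bundled: the 2×2 per-individual monophyly concordance counts between
the Sanger and NGS neighbor-joining trees of the same study (56 individuals
monophyletic under both, 24 resolved only by NGS, 8 by neither).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Sanger-vs-NGS per-individual monophyly counts
#: (both mono, Sanger-only mono, NGS-only mono, neither).
MONOPHYLY_CONCORDANCE = (56, 0, 24, 8)


def load_specimen_summary() -> pd.DataFrame:
    """The per-specimen ITS2 summary table (88 rows)."""
    with resources.files("allelecap.data").joinpath("mosquito_its2_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["full_length"] = df["full_length"].astype(bool)
    return df


def allele_count_summary(df: pd.DataFrame | None = None) -> dict:
    """Allele-count arithmetic over the summary table."""
    if df is None:
        df = load_specimen_summary()
    per_genus = df.groupby("species")["n_alleles"].sum()
    return {
        "total_alleles": int(df["n_alleles"].sum()),
        "n_specimens": int(len(df)),
        "mean_alleles_per_individual": float(df["n_alleles"].mean()),
        "individuals_with_1_to_3_alleles": int(df["n_alleles"].between(1, 3).sum()),
        "per_species_totals": per_genus.to_dict(),
    }


def species_length_extremes(df: pd.DataFrame | None = None) -> tuple[int, int]:
    """(min, max) allele length of the shortest- and longest-ITS2 species.

    Species are ranked by mean allele size; specimens flagged as not
    full-length (truncated assemblies) are excluded. Returns the size-range
    minimum of the shortest species and the maximum of the longest.
    """
    if df is None:
        df = load_specimen_summary()
    d = df[df["full_length"]]
    means = d.groupby("species")["avg_size"].mean()
    shortest = means.idxmin()
    longest = means.idxmax()
    return (
        int(d.loc[d["species"] == shortest, "size_min"].min()),
        int(d.loc[d["species"] == longest, "size_max"].max()),
    )
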