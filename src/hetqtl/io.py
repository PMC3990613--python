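"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* Count tables are TSV with the 17-base signature in the first column and one
  column of raw counts per library.
* Library metadata is CSV with columns ``library, genotype, tissue, replicate``
  (genotype in {P1, P2, F1}, tissue in {leaf, root, meristem}).
* Genotype matrices are CSV, lines as rows, markers as columns, homozygous
  codes ``A`` (P1 allele) / ``B`` (93-11-type P2 allele) / ``NA``; in memory
  they are float frames coded +1 / -1 / NaN.
* Gene models travel as GFF3 with 1-based inclusive coordinates.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPE_CODES = {"A": 1.0, "B": -1.0}

# ---------------------------------------------------------------------------
# count tables / metadata

def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a signature x library raw-count TSV (signatures as index)."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return tab.astype(np.int64)


def write_count_table(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="signature")


def read_library_meta(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"library", "genotype", "tissue", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"library metadata missing columns: {sorted(missing)}")
    return meta


def write_library_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# marker map / genotypes / phenotypes

def read_marker_map(path: str | os.PathLike) -> pd.DataFrame:
    mm = pd.read_csv(path)
    required = {"marker", "chrom", "cm", "bp"}
    missing = required - set(mm.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    return mm


def write_marker_map(marker_map: pd.DataFrame, path: str | os.PathLike) -> None:
    marker_map.to_csv(path, index=False)


def read_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read an A/B/NA genotype CSV into a +1/-1/NaN float frame."""
    raw = pd.read_csv(path, index_col=0, dtype=str)
    geno = raw.apply(lambda col: col.map(GENOTYPE_CODES))
    return geno.astype(float)


def write_genotypes(genotypes: pd.DataFrame, path: str | os.PathLike) -> None:
    coded = genotypes.copy()
    out = pd.DataFrame(
        np.select([coded.values > 0, coded.values < 0], ["A", "B"], default="NA"),
        index=coded.index,
        columns=coded.columns,
    )
    out.to_csv(path, index_label="line")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    ph = pd.read_csv(path)
    required = {"line", "environment", "trait", "value"}
    missing = required - set(ph.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return ph


def write_phenotypes(phenotypes: pd.DataFrame, path: str | os.PathLike) -> None:
    phenotypes.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sequences / annotations

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a frame with columns ``gene_id, chrom, start, end, strand``
    (1-based inclusive coordinates, GFF3 convention).
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    tab = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"seqid": str})
    genes = tab[tab["type"] == "gene"].copy()
    gene_ids = genes["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "gene_id": gene_ids.values,
            "chrom": genes["seqid"].values,
            "start": genes["start"].astype(int).values,
            "end": genes["end"].astype(int).values,
            "strand": genes["strand"].values,
        }
    )
    return out.reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path: str | os.PathLike, source: str = "hetqtl") -> None:
    """Write gene models (``gene_id, chrom, start, end, strand``) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{int(row.start)}\t{int(row.end)}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )
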