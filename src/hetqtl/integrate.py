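"""Assignment of expressed genes to QTL intervals and candidate reports.

The physical window of a merged QTL is the bp span between its flanking
markers; genes whose start coordinate falls inside that closed window are the
QTL's candidates.  Each candidate is joined to its per-tissue expression
pattern and to annotation categories supplied as input lists (transcription
factor family, chromatin-related flag, functional category labels), yielding
per-QTL pattern counts, cross-tissue pattern summaries and global tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .qtlmap import MergedQTL


def marker_physical_interval(
    qtl: MergedQTL, marker_map: pd.DataFrame
) -> tuple[object, int, int]:
    """Closed, 1-based bp interval spanned by a merged QTL's flanking markers."""
    mm = marker_map.set_index("marker")
    bps = []
    for name in (qtl.marker_lo, qtl.marker_hi):
        if name not in mm.index:
            raise KeyError(f"marker {name} absent from the marker map")
        bp = mm.loc[name, "bp"]
        if pd.isna(bp):
            raise ValueError(f"marker {name} has no physical (bp) position")
        bps.append(int(bp))
    return qtl.chrom, min(bps), max(bps)


def genes_in_interval(
    interval: tuple[object, int, int],
    genes: pd.DataFrame,
    *,
    mode: str = "start",
) -> list[str]:
    """Genes assigned to a physical interval, sorted by start coordinate.

    ``mode="start"`` (default) includes a gene iff its start coordinate lies
    within the closed interval; ``mode="overlap"`` includes any gene whose
    span intersects it.
    """
    chrom, lo, hi = interval
    same = genes[genes["chrom"].astype(str) == str(chrom)]
    if mode == "start":
        hit = same[(same["start"] >= lo) & (same["start"] <= hi)]
    elif mode == "overlap":
        hit = same[(same["start"] <= hi) & (same["end"] >= lo)]
    else:
        raise ValueError(f"unknown interval mode {mode!r}")
    return hit.sort_values("start")["gene_id"].to_list()


@dataclass
class IntegrationReport:
    """Candidate-gene report across merged QTLs."""

    table: pd.DataFrame  # one row per QTL x gene
    pattern_counts: pd.DataFrame  # QTL x tissue x pattern counts
    cross_tissue: pd.DataFrame  # genes with the same pattern in every tissue
    tallies: dict


def annotate_gene_sets(
    qtl_genes: Mapping[str, Sequence[str]],
    gene_annotation: pd.DataFrame,
    pattern_calls: pd.DataFrame,
    *,
    tf: pd.DataFrame | None = None,
    chromatin: Iterable[str] | None = None,
    functional: pd.DataFrame | None = None,
    tissues: Sequence[str] = ("leaf", "root", "meristem"),
) -> IntegrationReport:
    """Join in-QTL genes to patterns and annotation categories.

    ``qtl_genes`` maps QTL name -> gene ids inside its physical interval.
    Genes carrying a pattern call but missing from ``gene_annotation`` are
    warned about and excluded from coordinate-based counts.  Empty category
    tables yield a patterns-only report with zero TF/chromatin tallies.
    """
    ann = gene_annotation.set_index("gene_id")
    called = set(pattern_calls["gene_id"])
    orphans = called - set(ann.index)
    if orphans:
        warnings.warn(
            f"{len(orphans)} genes have pattern calls but no annotation entry; excluded"
        )
    tf_map = (
        tf.set_index("gene_id")["family"] if tf is not None and len(tf) else pd.Series(dtype=object)
    )
    chromatin_set = set(chromatin or [])
    func_map: dict[str, list[str]] = {}
    if functional is not None and len(functional):
        for row in functional.itertuples(index=False):
            func_map.setdefault(row.gene_id, []).append(row.category)

    calls_wide = pattern_calls.pivot_table(
        index="gene_id", columns="tissue", values="pattern", aggfunc="first"
    )

    rows = []
    for qtl_name, genes in qtl_genes.items():
        for g in genes:
            if g not in ann.index:
                continue
            row = {
                "qtl": qtl_name,
                "gene_id": g,
                "chrom": ann.loc[g, "chrom"],
                "start": int(ann.loc[g, "start"]),
                "end": int(ann.loc[g, "end"]),
                "tf_family": tf_map.get(g, None),
                "chromatin": g in chromatin_set,
                "categories": ";".join(func_map.get(g, [])),
            }
            for t in tissues:
                row[f"pattern_{t}"] = (
                    calls_wide.loc[g, t] if g in calls_wide.index and t in calls_wide else None
                )
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["qtl", "gene_id", "chrom", "start", "end"]
        + [f"pattern_{t}" for t in tissues]
        + ["tf_family", "chromatin", "categories"],
    )

    count_rows = []
    for qtl_name, grp in table.groupby("qtl", sort=False):
        for t in tissues:
            vc = grp[f"pattern_{t}"].value_counts()
            for pattern, n in vc.items():
                count_rows.append(
                    {"qtl": qtl_name, "tissue": t, "pattern": pattern, "n_genes": int(n)}
                )
    pattern_counts = pd.DataFrame(count_rows, columns=["qtl", "tissue", "pattern", "n_genes"])

    cross_rows = []
    for row in table.itertuples(index=False):
        pats = {getattr(row, f"pattern_{t}") for t in tissues}
        if len(pats) == 1 and None not in pats and pd.notna(next(iter(pats))):
            cross_rows.append(
                {
                    "qtl": row.qtl,
                    "gene_id": row.gene_id,
                    "pattern": next(iter(pats)),
                    "tf_family": row.tf_family,
                    "chromatin": row.chromatin,
                }
            )
    cross_tissue = pd.DataFrame(
        cross_rows, columns=["qtl", "gene_id", "pattern", "tf_family", "chromatin"]
    )

    in_qtl = table["gene_id"].unique()
    tf_in = table[table["tf_family"].notna()]["gene_id"].unique()
    tallies = {
        "n_qtl": int(table["qtl"].nunique()),
        "n_genes": int(len(in_qtl)),
        "n_tf_genes": int(len(tf_in)),
        "n_tf_families": int(table[table["tf_family"].notna()]["tf_family"].nunique()),
        "n_chromatin_genes": int(table[table["chromatin"]]["gene_id"].nunique()),
    }
    return IntegrationReport(
        table=table, pattern_counts=pattern_counts, cross_tissue=cross_tissue, tallies=tallies
    )
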