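"""Tag-based digital expression: signatures, TPM, filters, annotation.

A 17-base signature is the substring starting at the 3'-most DpnII site
(GATC) of a transcript that still has 13 bases downstream; its count in a
library is the expression measure of the transcript.  Counts are normalized
to transcripts per million (TPM), screened with two filters

* reliable    — the signature has a non-zero count in at least two libraries,
* significant — the signature reaches >= 4 TPM in at least one library,

matched against both parental references, classified by position relative to
annotated genes, and summarised per library group (mirroring the library
characteristics table of MPSS-style studies).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIGNATURE_LENGTH = 17
ANCHOR = "GATC"
SIGNIFICANT_TPM = 4.0
BIN_LABELS = ("1-100", "101-1000", "1001-10000", ">10000")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# signatures

def extract_signature(sequence: str) -> str | None:
    """17-base signature at the 3'-most qualifying GATC of a transcript.

    Scans GATC occurrences from the 3' end and returns GATC plus the next 13
    bases for the first occurrence with at least 13 downstream bases; ``None``
    if no occurrence qualifies.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    pos = seq.rfind(ANCHOR)
    while pos != -1:
        if len(seq) - pos >= SIGNATURE_LENGTH:
            return seq[pos : pos + SIGNATURE_LENGTH]
        pos = seq.rfind(ANCHOR, 0, pos + len(ANCHOR) - 1)
    return None


# ---------------------------------------------------------------------------
# normalization and filters

def normalize_tpm(counts: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Scale each library column of raw counts to transcripts per million.

    If ``meta`` carries a ``total`` column it must agree with the column sums
    of the raw table (consistency check).
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        empty = totals[totals <= 0].index.to_list()
        raise ValueError(f"libraries with zero total count: {empty}")
    if meta is not None and "total" in meta.columns:
        declared = meta.set_index("library")["total"]
        for lib in counts.columns:
            if lib in declared.index and int(declared[lib]) != int(totals[lib]):
                raise ValueError(
                    f"library {lib}: declared total {int(declared[lib])} != "
                    f"column sum {int(totals[lib])}"
                )
    return counts * 1e6 / totals


def apply_filters(counts: pd.DataFrame, tpm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-signature reliability and significance flags.

    reliable: raw count > 0 in >= 2 libraries.  significant: >= 4 TPM in at
    least one library.  The conjunction is the "reliable and significant"
    category of library summaries.
    """
    if tpm is None:
        tpm = normalize_tpm(counts)
    reliable = (counts > 0).sum(axis=1) >= 2
    significant = (tpm >= SIGNIFICANT_TPM).any(axis=1)
    return pd.DataFrame({"reliable": reliable, "significant": significant})


# ---------------------------------------------------------------------------
# reference matching

def _match_one(sig: str, sequences: Iterable[str], revcomp: bool) -> bool:
    rc = reverse_complement(sig) if revcomp else None
    for seq in sequences:
        if sig in seq:
            return True
        if rc is not None and rc in seq:
            return True
    return False


def match_to_references(
    signatures: Sequence[str],
    p1_sequences: Mapping[str, str],
    p2_sequences: Mapping[str, str],
    *,
    revcomp: bool = False,
) -> pd.Series:
    """Exact-substring match status of each signature against both parents.

    Returns a Series with values ``P1-only``, ``P2-only``, ``both`` or
    ``none``.  Matching is sense-strand by default (tag signatures are
    strand-specific); ``revcomp=True`` also searches the reverse complement.
    """
    p1_seqs = [s.upper() for s in p1_sequences.values()]
    p2_seqs = [s.upper() for s in p2_sequences.values()]
    status = []
    for sig in signatures:
        in1 = _match_one(sig.upper(), p1_seqs, revcomp)
        in2 = _match_one(sig.upper(), p2_seqs, revcomp)
        status.append(
            "both" if in1 and in2 else "P1-only" if in1 else "P2-only" if in2 else "none"
        )
    return pd.Series(status, index=list(signatures), name="match_status")


def match_percentages(tpm: pd.DataFrame, status: pd.Series) -> pd.DataFrame:
    """Per-library percentage of expressed (>= 4 TPM) signatures matching each parent."""
    rows = {}
    for lib in tpm.columns:
        expressed = tpm.index[tpm[lib] >= SIGNIFICANT_TPM]
        st = status.loc[expressed]
        n = len(st)
        p1 = st.isin(["P1-only", "both"]).sum()
        p2 = st.isin(["P2-only", "both"]).sum()
        rows[lib] = {
            "n_expressed": n,
            "pct_match_p1": 100.0 * p1 / n if n else 0.0,
            "pct_match_p2": 100.0 * p2 / n if n else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# positional classification

class PositionalClassifier:
    """Classify genome-matched signatures by location relative to gene models.

    Decision table (precedence 1 > 2 > ... > 7):

    1. sense match at the 3'-most qualifying GATC of an annotated transcript
    2. sense match elsewhere in an exon
    3. antisense match in an exon
    4. sense match in an intron
    5. antisense match in an intron
    6. within 500 bp downstream of a gene (3' side, gene strand)
    7. intergenic

    Without exon sub-features every gene is treated as single-exon, so
    classes 4 and 5 require an ``exons`` table (gene_id, start, end).
    """

    def __init__(
        self,
        chromosomes: Mapping[str, str],
        genes: pd.DataFrame,
        exons: pd.DataFrame | None = None,
        downstream: int = 500,
    ) -> None:
        self.chromosomes = {c: s.upper() for c, s in chromosomes.items()}
        self.genes = genes.reset_index(drop=True)
        self.exons = exons
        self.downstream = downstream
        self._canonical: dict[str, str | None] = {}
        for row in self.genes.itertuples(index=False):
            tx = self.chromosomes[str(row.chrom)][row.start - 1 : row.end]
            if row.strand == "-":
                tx = reverse_complement(tx)
            try:
                self._canonical[row.gene_id] = extract_signature(tx)
            except ValueError:
                self._canonical[row.gene_id] = None

    def _occurrences(self, sig: str) -> list[tuple[str, int, int, str]]:
        """(chrom, start_1based, end_1based, strand) of every exact match."""
        hits = []
        rc = reverse_complement(sig)
        for chrom, seq in self.chromosomes.items():
            for query, strand in ((sig, "+"), (rc, "-")):
                pos = seq.find(query)
                while pos != -1:
                    hits.append((chrom, pos + 1, pos + len(query), strand))
                    pos = seq.find(query, pos + 1)
        return hits

    def _gene_exonic(self, gene_id: str, lo: int, hi: int) -> bool:
        if self.exons is None:
            return True
        ex = self.exons[self.exons["gene_id"] == gene_id]
        if ex.empty:
            return True
        return bool(((ex["start"] <= lo) & (ex["end"] >= hi)).any())

    def classify(self, signature: str) -> int:
        sig = signature.upper()
        hits = self._occurrences(sig)
        if not hits:
            raise ValueError(f"signature {sig} has no genome match; class undefined")
        best = 7
        for chrom, lo, hi, strand in hits:
            overlapping = self.genes[
                (self.genes["chrom"].astype(str) == chrom)
                & (self.genes["start"] <= hi)
                & (self.genes["end"] >= lo)
            ]
            if overlapping.empty:
                down = self.genes[self.genes["chrom"].astype(str) == chrom]
                for g in down.itertuples(index=False):
                    if g.strand == "-":
                        window = (g.start - self.downstream, g.start - 1)
                    else:
                        window = (g.end + 1, g.end + self.downstream)
                    if lo <= window[1] and hi >= window[0]:
                        best = min(best, 6)
                        break
                continue
            for g in overlapping.itertuples(index=False):
                sense = strand == g.strand
                exonic = self._gene_exonic(g.gene_id, lo, hi)
                if sense and exonic and sig == self._canonical.get(g.gene_id):
                    cls = 1
                elif sense and exonic:
                    cls = 2
                elif exonic:
                    cls = 3
                elif sense:
                    cls = 4
                else:
                    cls = 5
                best = min(best, cls)
        return best

    def classify_many(self, signatures: Sequence[str]) -> pd.Series:
        return pd.Series(
            {s: self.classify(s) for s in signatures}, name="positional_class"
        )


# ---------------------------------------------------------------------------
# group means and bins

def replicate_means(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    by: Sequence[str] = ("genotype", "tissue"),
) -> pd.DataFrame:
    """Mean TPM per signature over replicate libraries of each group.

    Zeros count: a signature absent from a replicate contributes 0 to the
    group mean, so tags seen in only a subset of replicates are retained.
    Columns are ``<genotype>_<tissue>`` (joined group keys).
    """
    groups = meta.groupby(list(by), sort=False)
    out = {}
    for key, grp in groups:
        libs = grp["library"].to_list()
        missing = [l for l in libs if l not in tpm.columns]
        if missing:
            raise ValueError(f"libraries in metadata but not in table: {missing}")
        if not libs:
            raise ValueError(f"empty library group {key}")
        name = "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        out[name] = tpm[libs].mean(axis=1)
    if not out:
        raise ValueError("no library groups in metadata")
    return pd.DataFrame(out)


def abundance_bins(tpm_column: pd.Series) -> pd.Series:
    """Counts of signatures per abundance bin in one library.

    TPM values are rounded half away from zero to integers first, so the
    integer bin edges 1-100, 101-1000, 1001-10000, >10000 partition every
    expressed (rounded TPM >= 1) signature.
    """
    vals = np.floor(np.asarray(tpm_column, dtype=float) + 0.5).astype(np.int64)
    counts = {
        "1-100": int(((vals >= 1) & (vals <= 100)).sum()),
        "101-1000": int(((vals >= 101) & (vals <= 1000)).sum()),
        "1001-10000": int(((vals >= 1001) & (vals <= 10000)).sum()),
        ">10000": int((vals > 10000).sum()),
    }
    return pd.Series(counts, name=getattr(tpm_column, "name", None))


# ---------------------------------------------------------------------------
# library summaries

def library_summary(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    gene_of_signature: pd.Series | None = None,
    match_status: pd.Series | None = None,
) -> pd.DataFrame:
    """Per genotype x tissue summary of library characteristics.

    Reports, per library, total reads, distinct signatures, the counts
    passing the reliability / significance filters and their conjunction,
    abundance-bin counts, distinct genes hit by reliable-and-significant
    signatures (if a signature -> gene mapping is given) and genome-match
    counts and percentages among expressed signatures (if a match-status
    series is given); groups with replicates report the replicate mean.
    """
    totals = counts.sum(axis=0)
    if len(counts) and (totals > 0).all():
        tpm = normalize_tpm(counts, meta)
    else:
        # empty table or silent libraries: report zeros instead of failing
        tpm = counts * 1e6 / totals.replace(0, 1)
    flags = apply_filters(counts, tpm)
    per_lib = {}
    for lib in counts.columns:
        col = counts[lib]
        present = col > 0
        stats = {
            "total_reads": float(col.sum()),
            "distinct": float(present.sum()),
            "reliable": float((present & flags["reliable"]).sum()),
            "significant": float((present & flags["significant"]).sum()),
            "reliable_and_significant": float(
                (present & flags["reliable"] & flags["significant"]).sum()
            ),
        }
        bins = abundance_bins(tpm[lib])
        for label in BIN_LABELS:
            stats[f"bin_{label}"] = float(bins[label])
        if gene_of_signature is not None:
            keep = counts.index[(present & flags["reliable"] & flags["significant"])]
            genes = gene_of_signature.reindex(keep).dropna()
            stats["distinct_genes"] = float(genes.nunique())
        if match_status is not None:
            expressed = tpm.index[tpm[lib] >= SIGNIFICANT_TPM]
            st = match_status.reindex(expressed)
            n = len(st)
            p1 = float(st.isin(["P1-only", "both"]).sum())
            p2 = float(st.isin(["P2-only", "both"]).sum())
            stats["match_p1"] = p1
            stats["match_p2"] = p2
            stats["pct_match_p1"] = 100.0 * p1 / n if n else 0.0
            stats["pct_match_p2"] = 100.0 * p2 / n if n else 0.0
        per_lib[lib] = stats
    lib_table = pd.DataFrame.from_dict(per_lib, orient="index")
    merged = lib_table.join(meta.set_index("library")[["genotype", "tissue"]])
    return merged.groupby(["genotype", "tissue"], sort=False).mean()
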