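"""F1-versus-parent expression-pattern classification.

Each gene (per tissue) is placed into one of eight patterns by comparing its
mean F1 abundance with the two parental means (TPM):

========  =====================================================
AHPL      above high parent level (positive expression heterosis)
HPL       high parent level (dominance toward the high parent)
MPL       mid parent level (additivity)
LPL       low parent level (dominance toward the low parent)
BLPL      below low parent level (negative expression heterosis)
SEF1      expressed specifically in F1, absent in both parents
EOPF1     expressed in exactly one parent and in F1
EPAF1     expressed in parent(s) but absent in F1
========  =====================================================

Presence means group-mean TPM >= 4 (the significance constant).  Level bands
are defined by a multiplicative tolerance tau (default 2): the F1 value is
AHPL above HP * tau and BLPL below LP / tau; otherwise it is assigned to the
nearest of low parent, mid-parent and high parent in log space (ties prefer
HPL, then LPL).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PRESENCE_TPM = 4.0
DEFAULT_TAU = 2.0

PATTERNS = ("AHPL", "HPL", "MPL", "LPL", "BLPL", "SEF1", "EOPF1", "EPAF1")
DISTRIBUTION_PATTERNS = ("AHPL", "HPL", "MPL", "LPL", "BLPL", "SEF1")

VENN_REGIONS = ("P1_only", "P2_only", "F1_only", "P1_P2", "P1_F1", "P2_F1", "P1_P2_F1")


def classify_pattern(
    p1: float,
    p2: float,
    f1: float,
    *,
    threshold: float = PRESENCE_TPM,
    tau: float = DEFAULT_TAU,
) -> str | None:
    """Classify one (P1, P2, F1) mean-abundance triple; ``None`` if all absent."""
    if min(p1, p2, f1) < 0:
        raise ValueError("mean abundances must be non-negative")
    if tau <= 1:
        raise ValueError("tau must exceed 1")
    pres1, pres2, presf = p1 >= threshold, p2 >= threshold, f1 >= threshold
    if not presf:
        return "EPAF1" if (pres1 or pres2) else None
    if not pres1 and not pres2:
        return "SEF1"
    if pres1 != pres2:
        return "EOPF1"
    hp, lp = max(p1, p2), min(p1, p2)
    if f1 > hp * tau:
        return "AHPL"
    if f1 < lp / tau:
        return "BLPL"
    mp = (hp + lp) / 2.0
    logf = math.log(f1)
    candidates = [
        ("HPL", abs(logf - math.log(hp))),
        ("LPL", abs(logf - math.log(lp))),
        ("MPL", abs(logf - math.log(mp))),
    ]
    # stable sort: ties keep the HPL > LPL > MPL preference order
    return min(candidates, key=lambda c: c[1])[0]


def call_patterns(
    means: pd.DataFrame,
    *,
    tissues: Iterable[str] = ("leaf", "root", "meristem"),
    genotypes: Mapping[str, str] | None = None,
    threshold: float = PRESENCE_TPM,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Classify every gene in every tissue from a group-mean table.

    ``means`` has one row per gene and columns ``<genotype>_<tissue>`` as
    produced by :func:`hetqtl.expression.replicate_means`; genes with all
    three genotypes absent in a tissue are skipped for that tissue.
    """
    genotypes = dict(genotypes or {"P1": "P1", "P2": "P2", "F1": "F1"})
    rows = []
    for tissue in tissues:
        cols = {role: f"{name}_{tissue}" for role, name in genotypes.items()}
        missing = [c for c in cols.values() if c not in means.columns]
        if missing:
            raise ValueError(f"group-mean table lacks columns {missing}")
        for gene, row in means[list(cols.values())].iterrows():
            p1, p2, f1 = (float(row[cols[r]]) for r in ("P1", "P2", "F1"))
            pattern = classify_pattern(p1, p2, f1, threshold=threshold, tau=tau)
            if pattern is None:
                continue
            rows.append(
                {"gene_id": gene, "tissue": tissue, "p1": p1, "p2": p2, "f1": f1,
                 "pattern": pattern, "tau": tau}
            )
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "p1", "p2", "f1", "pattern", "tau"])


def pattern_distribution(calls: pd.DataFrame, tissue: str) -> pd.Series:
    """Percentage share of the six level categories in one tissue.

    Only AHPL, HPL, MPL, LPL, BLPL and SEF1 enter the denominator (the
    presence-only categories EOPF1/EPAF1 are excluded from the distribution).
    """
    sub = calls[(calls["tissue"] == tissue) & calls["pattern"].isin(DISTRIBUTION_PATTERNS)]
    if sub.empty:
        raise ValueError(f"no eligible pattern calls for tissue {tissue!r}")
    shares = sub["pattern"].value_counts(normalize=True) * 100.0
    return shares.reindex(DISTRIBUTION_PATTERNS, fill_value=0.0).rename("pct")


def expression_venn(presence: pd.DataFrame) -> pd.Series:
    """Sizes of the 7 regions of the three-set (P1, P2, F1) presence Venn.

    ``presence`` is a boolean frame indexed by gene with columns P1, P2, F1
    (any restriction — e.g. to signatures matching both parental genomes — is
    applied by the caller before set algebra).  The triple intersection is the
    commonly-expressed set; single-set regions are the specifically-expressed
    sets; region sizes sum to the union size.
    """
    p1 = presence["P1"].astype(bool)
    p2 = presence["P2"].astype(bool)
    f1 = presence["F1"].astype(bool)
    return pd.Series(
        {
            "P1_only": int((p1 & ~p2 & ~f1).sum()),
            "P2_only": int((~p1 & p2 & ~f1).sum()),
            "F1_only": int((~p1 & ~p2 & f1).sum()),
            "P1_P2": int((p1 & p2 & ~f1).sum()),
            "P1_F1": int((p1 & ~p2 & f1).sum()),
            "P2_F1": int((~p1 & p2 & f1).sum()),
            "P1_P2_F1": int((p1 & p2 & f1).sum()),
        },
        name="n_genes",
    )


def cross_tissue_common(
    presence_by_tissue: Mapping[str, pd.DataFrame], genotype: str
) -> int:
    """Number of genes present in the given genotype in every tissue."""
    sets = [
        set(frame.index[frame[genotype].astype(bool)])
        for frame in presence_by_tissue.values()
    ]
    if not sets:
        return 0
    return len(set.intersection(*sets))
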