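"""Synthetic study generator with emitted ground truth.

Builds a complete in-silico version of a two-parent / F1-hybrid heterosis
study on a RIL mapping population:

* a pair of parental references (chromosome sequences plus single-exon gene
  models) diverged by point substitutions, every transcript carrying an
  extractable 17-base tag signature (a GATC anchor with 13 downstream bases);
* per-gene inheritance truth — one of eight modes (additive, dominant toward
  either parent, over-/under-dominant, F1-specific, F1-silenced,
  single-parent-plus-F1) with true mean abundances in TPM;
* tag-count libraries per genotype x tissue x replicate (negative-binomial,
  Poisson, or exact-expectation noise models);
* a marker map, RIL genotypes (selfing, Haldane-Waddington map expansion,
  Kosambi cM <-> r transform, no crossover interference), and
  multi-environment phenotypes driven by planted QTLs.

The default scale (around 240 genes, 250,000 tags per library, 266 lines,
131 markers on 12 chromosomes, 6 environments) mimics the design of an
MPSS-era rice heterosis study at a size that runs in seconds.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .expression import ANCHOR, SIGNATURE_LENGTH, extract_signature, reverse_complement
from .qtlmap import expected_qtl_code, kosambi_cm_to_r, ril_recomb

BASES = np.array(list("ACGT"))

MODES = (
    "additive",
    "high-parent-dominant",
    "low-parent-dominant",
    "over-dominant",
    "under-dominant",
    "F1-specific",
    "F1-silenced",
    "single-parent-and-F1",
)

MODE_TO_PATTERN = {
    "additive": "MPL",
    "high-parent-dominant": "HPL",
    "low-parent-dominant": "LPL",
    "over-dominant": "AHPL",
    "under-dominant": "BLPL",
    "F1-specific": "SEF1",
    "F1-silenced": "EPAF1",
    "single-parent-and-F1": "EOPF1",
}

ORDINAL_SCALES = {"PTY": (1, 9), "LOG": (0, 9)}  # tiller angle, lodging


def residual_sd_for_fraction(additive_effect: float, fraction: float) -> float:
    """Residual SD giving a single QTL the target variance fraction.

    With homozygous +1/-1 codes (unit variance), f = a^2 / (a^2 + sd^2).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return abs(additive_effect) * math.sqrt(1.0 / fraction - 1.0)


# ---------------------------------------------------------------------------
# reference pair

@dataclass
class ReferencePair:
    """Two parental references sharing gene ids and coordinates."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    chromosomes: dict[str, dict[str, str]]  # parent -> chrom -> sequence
    transcripts: dict[str, dict[str, str]]  # parent -> gene_id -> sequence
    divergence: float

    def signatures(self) -> pd.DataFrame:
        """Per-gene 17-base signatures of both parents."""
        rows = []
        for gene_id in self.genes["gene_id"]:
            s1 = extract_signature(self.transcripts["P1"][gene_id])
            s2 = extract_signature(self.transcripts["P2"][gene_id])
            rows.append(
                {"gene_id": gene_id, "sig_p1": s1, "sig_p2": s2, "differs": s1 != s2}
            )
        return pd.DataFrame(rows)


def _random_seq_without_anchor(rng: np.random.Generator, length: int) -> str:
    seq = "".join(rng.choice(BASES, size=length))
    while ANCHOR in seq:
        pos = seq.index(ANCHOR)
        # replacing the C with A cannot re-create the anchor across the edit
        seq = seq[: pos + 3] + "A" + seq[pos + 4 :]
    return seq


def generate_reference(
    *,
    n_genes: int = 240,
    n_chromosomes: int = 12,
    gene_length: tuple[int, int] = (300, 600),
    divergence: float = 0.02,
    signature_snp_fraction: float = 0.25,
    intergenic_gap: tuple[int, int] = (200, 800),
    minus_strand_fraction: float = 0.2,
    seed: int | None = None,
) -> ReferencePair:
    """Generate a diverged parental reference pair.

    Every transcript gets its GATC anchor implanted 17 bases from the 3' end
    (and no other anchor), so the tag signature is well defined and is the
    3'-most qualifying site by construction.  Parent 2 differs from parent 1
    by iid substitutions at rate ``divergence`` outside the signature region;
    a fraction ``signature_snp_fraction`` of genes additionally carries one
    substitution inside the 13 signature bases downstream of the anchor, so
    those signatures match exactly one parent.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence rate must be in [0, 0.2]")
    if gene_length[0] < 40:
        raise ValueError("gene length must be at least 40 bases to host GATC + 13")
    if not 0.0 <= signature_snp_fraction <= 1.0:
        raise ValueError("signature_snp_fraction must be in [0, 1]")
    if n_genes < n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    rng = np.random.default_rng(seed)

    n_snp_genes = int(round(signature_snp_fraction * n_genes))
    snp_flags = np.zeros(n_genes, dtype=bool)
    snp_flags[:n_snp_genes] = True
    rng.shuffle(snp_flags)

    tx1: dict[str, str] = {}
    tx2: dict[str, str] = {}
    gene_rows = []
    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes)
    per_chrom[: n_genes % n_chromosomes] += 1

    chrom1: dict[str, str] = {}
    chrom2: dict[str, str] = {}
    gene_idx = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        parts1: list[str] = []
        parts2: list[str] = []
        cursor = 0
        for _ in range(per_chrom[c]):
            gap = int(rng.integers(intergenic_gap[0], intergenic_gap[1] + 1))
            spacer = _random_seq_without_anchor(rng, gap)
            parts1.append(spacer)
            parts2.append(spacer)
            cursor += gap
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            body = _random_seq_without_anchor(rng, length)
            t1 = body[: length - SIGNATURE_LENGTH] + ANCHOR + body[length - SIGNATURE_LENGTH + len(ANCHOR) :]
            # parent 2: substitutions outside the final 17 bases
            arr = np.array(list(t1))
            editable = np.arange(0, length - SIGNATURE_LENGTH)
            if divergence > 0 and editable.size:
                hits = editable[rng.random(editable.size) < divergence]
                for h in hits:
                    choices = [b for b in "ACGT" if b != arr[h]]
                    arr[h] = choices[int(rng.integers(3))]
            t2 = "".join(arr)
            while ANCHOR in t2[: length - SIGNATURE_LENGTH + len(ANCHOR) - 1]:
                # a substitution re-created an anchor upstream; neutralize it
                pos = t2.index(ANCHOR)
                t2 = t2[: pos + 3] + "A" + t2[pos + 4 :]
            if snp_flags[gene_idx]:
                h = int(rng.integers(length - SIGNATURE_LENGTH + len(ANCHOR), length))
                choices = [b for b in "ACGT" if b != t2[h]]
                t2 = t2[:h] + choices[int(rng.integers(3))] + t2[h + 1 :]
            gene_id = f"gene{gene_idx + 1:04d}"
            strand = "-" if rng.random() < minus_strand_fraction else "+"
            start = cursor + 1  # 1-based inclusive
            end = cursor + length
            gene_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end, "strand": strand}
            )
            tx1[gene_id] = t1
            tx2[gene_id] = t2
            parts1.append(t1 if strand == "+" else reverse_complement(t1))
            parts2.append(t2 if strand == "+" else reverse_complement(t2))
            cursor += length
            gene_idx += 1
        tail = _random_seq_without_anchor(rng, int(rng.integers(intergenic_gap[0], intergenic_gap[1] + 1)))
        parts1.append(tail)
        parts2.append(tail)
        chrom1[chrom] = "".join(parts1)
        chrom2[chrom] = "".join(parts2)

    genes = pd.DataFrame(gene_rows)
    return ReferencePair(
        genes=genes,
        chromosomes={"P1": chrom1, "P2": chrom2},
        transcripts={"P1": tx1, "P2": tx2},
        divergence=divergence,
    )


# ---------------------------------------------------------------------------
# inheritance truth

def generate_inheritance_truth(
    gene_ids: Sequence[str],
    *,
    seed: int | None = None,
    mode_fractions: Mapping[str, float] | None = None,
    low_parent_tpm: tuple[float, float] = (20.0, 80.0),
    parent_ratio: tuple[float, float] = (3.0, 12.0),
    kappa_over: float = 3.0,
    kappa_under: float = 1.0 / 3.0,
    tau: float = 2.0,
    presence_tpm: float = 4.0,
) -> pd.DataFrame:
    """Assign an inheritance mode and true mean TPM triple to every gene.

    The over-/under-dominance multipliers must sit outside the tau band
    (kappa_over > tau, kappa_under < 1/tau) or the planted mode could not be
    recovered even from noise-free data — that is a configuration error.
    Low-parent abundance and the high/low parent ratio are drawn
    log-uniformly; which parent is the high one is random per gene.
    """
    if kappa_over <= tau:
        raise ValueError(
            f"kappa_over ({kappa_over}) must exceed tau ({tau}); planted over-dominance "
            "would be indistinguishable from high-parent level"
        )
    if kappa_under >= 1.0 / tau:
        raise ValueError(
            f"kappa_under ({kappa_under}) must be below 1/tau ({1.0 / tau:.3f})"
        )
    if low_parent_tpm[0] * kappa_under < presence_tpm:
        raise ValueError(
            "low_parent_tpm lower bound too small: under-dominant F1 means would fall "
            "below the presence threshold"
        )
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    if mode_fractions is None:
        mode_fractions = {m: 1.0 / len(MODES) for m in MODES}
    counts = np.floor(np.array([mode_fractions.get(m, 0.0) for m in MODES]) * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(np.array([mode_fractions.get(m, 0.0) for m in MODES]) * n - counts))] += 1
    modes = np.repeat(list(MODES), counts)[:n]
    rng.shuffle(modes)

    lp = np.exp(rng.uniform(math.log(low_parent_tpm[0]), math.log(low_parent_tpm[1]), size=n))
    ratio = np.exp(rng.uniform(math.log(parent_ratio[0]), math.log(parent_ratio[1]), size=n))
    hp = lp * ratio
    p1_is_high = rng.random(n) < 0.5

    rows = []
    for i, gene_id in enumerate(gene_ids):
        mode = modes[i]
        lo, hi = float(lp[i]), float(hp[i])
        if mode == "F1-specific":
            p1 = p2 = 0.0
            f1 = hi
        elif mode == "F1-silenced":
            p1, p2 = (hi, lo) if p1_is_high[i] else (lo, hi)
            f1 = 0.0
        elif mode == "single-parent-and-F1":
            present = hi
            p1, p2 = (present, 0.0) if p1_is_high[i] else (0.0, present)
            f1 = present
        else:
            p1, p2 = (hi, lo) if p1_is_high[i] else (lo, hi)
            if mode == "additive":
                f1 = (lo + hi) / 2.0
            elif mode == "high-parent-dominant":
                f1 = hi
            elif mode == "low-parent-dominant":
                f1 = lo
            elif mode == "over-dominant":
                f1 = kappa_over * hi
            else:  # under-dominant
                f1 = kappa_under * lo
        rows.append(
            {
                "gene_id": gene_id,
                "mode": mode,
                "pattern": MODE_TO_PATTERN[mode],
                "p1_tpm": p1,
                "p2_tpm": p2,
                "f1_tpm": f1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker map and RIL population

def generate_marker_map(
    *,
    markers_per_chromosome: Sequence[int] | None = None,
    chrom_cm: float | Sequence[float] = 110.0,
    chrom_bp: int | Sequence[int] = 25_000_000,
    positions_cm: Mapping[str, Sequence[float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a marker map (cM and bp positions, co-monotone per chromosome).

    The default layout places 131 markers on 12 chromosomes (11 on each of
    the first eleven, 10 on the last).  Markers sit at both chromosome ends
    with interior positions drawn uniformly; bp positions are proportional
    to cM, so the two orders agree by construction.
    """
    if markers_per_chromosome is None:
        markers_per_chromosome = [11] * 11 + [10]
    n_chrom = len(markers_per_chromosome)
    cm_lengths = (
        [float(chrom_cm)] * n_chrom if np.isscalar(chrom_cm) else [float(x) for x in chrom_cm]
    )
    bp_lengths = (
        [int(chrom_bp)] * n_chrom if np.isscalar(chrom_bp) else [int(x) for x in chrom_bp]
    )
    rng = np.random.default_rng(seed)
    rows = []
    for c, n_mark in enumerate(markers_per_chromosome):
        if n_mark < 2:
            raise ValueError("need at least 2 markers per chromosome")
        chrom = f"chr{c + 1:02d}"
        if positions_cm is not None and chrom in positions_cm:
            cms = np.asarray(positions_cm[chrom], dtype=float)
            if np.any(np.diff(cms) < 0):
                raise ValueError(f"requested positions on {chrom} are not non-decreasing")
        else:
            interior = np.sort(rng.uniform(0, cm_lengths[c], size=n_mark - 2))
            cms = np.concatenate([[0.0], interior, [cm_lengths[c]]])
        span = cms[-1] - cms[0] if cms[-1] > cms[0] else 1.0
        bps = np.round((cms - cms[0]) / span * bp_lengths[c]).astype(np.int64) + 1
        for i, (cm, bp) in enumerate(zip(cms, bps)):
            rows.append(
                {"marker": f"M{c + 1:02d}_{i + 1:02d}", "chrom": chrom,
                 "cm": float(cm), "bp": int(bp)}
            )
    return pd.DataFrame(rows)


def simulate_ril_genotypes(
    marker_map: pd.DataFrame, n_lines: int = 266, seed: int | None = None
) -> pd.DataFrame:
    """Simulate fully homozygous RIL genotypes along the marker map.

    The first marker of each chromosome is a fair coin per line; each
    following interval switches genotype with the RIL-by-selfing probability
    R = 2r / (1 + 2r), with r from the inverse Kosambi transform of the
    interval length.  Intervals are independent (no crossover interference).
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(seed)
    lines = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    columns = {}
    for _, grp in marker_map.groupby("chrom", sort=False):
        grp = grp.sort_values("cm")
        markers = grp["marker"].to_list()
        cms = grp["cm"].to_numpy(dtype=float)
        state = np.where(rng.random(n_lines) < 0.5, 1.0, -1.0)
        columns[markers[0]] = state.copy()
        for j in range(1, len(markers)):
            r = kosambi_cm_to_r(cms[j] - cms[j - 1])
            big_r = ril_recomb(r)
            flip = rng.random(n_lines) < big_r
            state = np.where(flip, -state, state)
            columns[markers[j]] = state.copy()
    geno = pd.DataFrame(columns, index=lines)
    return geno[marker_map["marker"].to_list()]


# ---------------------------------------------------------------------------
# phenotypes

@dataclass
class QTLTruth:
    """A planted QTL: trait, location, effect, realized variance fractions."""

    trait: str
    chrom: str
    pos_cm: float
    additive_effect: float  # trait units per allele substitution; + = P1 allele increases
    variance_fraction: dict[str, float] = field(default_factory=dict)


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    qtl_truth: Sequence[QTLTruth],
    *,
    n_envs: int = 6,
    env_shifts: Mapping[str, float] | None = None,
    residual_sd: float | Mapping[str, float] = 1.0,
    traits: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate multi-environment trait values from planted QTLs.

    Per line and environment the trait value is the sum of additive QTL
    contributions a_q * x_q, an environment shift and a Gaussian residual.
    The +1/-1 QTL code x_q of a line is sampled once per QTL from its
    conditional distribution given the flanking-marker genotypes,
    P(x = +1) = (1 + E[x]) / 2 with E[x] the Haley-Knott expectation, so a
    QTL sitting on a marker inherits that marker's code exactly.
    Ordinal traits (tiller angle PTY on 1-9, lodging LOG on 0-9) are binned
    from the latent value at fixed integer cut points.  Realized variance
    fractions are written back into each :class:`QTLTruth`.
    """
    if n_envs < 1:
        raise ValueError("need at least one environment")
    envs = [f"env{e + 1}" for e in range(n_envs)]
    shifts = {e: 0.0 for e in envs}
    if env_shifts:
        shifts.update(env_shifts)
    if traits is None:
        traits = sorted({q.trait for q in qtl_truth})
    rng = np.random.default_rng(seed)

    span = {
        chrom: (float(grp["cm"].min()), float(grp["cm"].max()))
        for chrom, grp in marker_map.groupby("chrom")
    }
    for q in qtl_truth:
        if q.chrom not in span or not span[q.chrom][0] <= q.pos_cm <= span[q.chrom][1]:
            raise ValueError(
                f"QTL for trait {q.trait} at {q.chrom}:{q.pos_cm} cM lies off the map"
            )

    codes = {}
    for q in qtl_truth:
        expect = expected_qtl_code(genotypes, marker_map, q.chrom, q.pos_cm)
        draw = rng.random(len(expect))
        codes[(q.trait, q.chrom, q.pos_cm)] = np.where(draw < (1.0 + expect) / 2.0, 1.0, -1.0)
    n = len(genotypes.index)
    rows = []
    for trait in traits:
        sd = float(residual_sd[trait]) if isinstance(residual_sd, Mapping) else float(residual_sd)
        trait_qtls = [q for q in qtl_truth if q.trait == trait]
        genetic = np.zeros(n)
        for q in trait_qtls:
            genetic = genetic + q.additive_effect * codes[(q.trait, q.chrom, q.pos_cm)]
        for env in envs:
            latent = genetic + shifts[env] + rng.normal(0.0, sd, size=n)
            total_var = float(np.var(latent))
            for q in trait_qtls:
                x = codes[(q.trait, q.chrom, q.pos_cm)]
                q.variance_fraction[env] = (
                    float(q.additive_effect**2 * np.var(x) / total_var) if total_var > 0 else 0.0
                )
            if trait in ORDINAL_SCALES:
                lo, hi = ORDINAL_SCALES[trait]
                values = np.clip(np.floor(latent + 0.5), lo, hi)
            else:
                values = latent
            rows.extend(
                {"line": line, "environment": env, "trait": trait, "value": float(v)}
                for line, v in zip(genotypes.index, values)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tag libraries

DEFAULT_REPLICATES = {"leaf": 4, "root": 2, "meristem": 1}


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, noise_model: str
) -> np.ndarray:
    mean = np.maximum(mean, 0.0)
    if noise_model == "none":
        return mean
    if noise_model == "poisson" or dispersion == 0:
        return rng.poisson(mean).astype(float)
    if noise_model != "negative_binomial":
        raise ValueError(f"unknown noise model {noise_model!r}")
    size = 1.0 / dispersion
    out = np.zeros_like(mean)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p).astype(float)
    return out


def simulate_tag_libraries(
    reference: ReferencePair,
    truth: pd.DataFrame,
    *,
    library_size: int = 250_000,
    replicates: Mapping[str, int] | None = None,
    dispersion: float = 0.1,
    noise_model: str = "negative_binomial",
    n_background: int = 2000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate signature x library tag counts for all genotypes and tissues.

    Each gene's count in a library is drawn around its true mean TPM scaled
    by the library size.  Parental libraries emit the parent's own signature;
    F1 libraries split the gene's count equally between the two parental
    signatures where they differ (both alleles expressed).  A population of
    ``n_background`` unannotated signatures (constant across genotypes, tags
    from transcripts outside the modeled gene set) fills each library to its
    nominal size, so per-million normalization returns abundances on the
    scale of the planted true means.  Returns the count table, library
    metadata (with realized totals) and the signature -> gene mapping
    (NaN for background signatures).
    """
    if library_size < 10_000:
        raise ValueError("library size must be at least 10,000 tags")
    replicates = dict(replicates or DEFAULT_REPLICATES)
    missing = set(truth["gene_id"]) - set(reference.genes["gene_id"])
    if missing:
        raise ValueError(f"truth genes absent from reference: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(seed)

    sigs = reference.signatures().set_index("gene_id")
    truth = truth.set_index("gene_id")
    gene_ids = truth.index.to_list()
    sig_p1 = sigs.loc[gene_ids, "sig_p1"].to_numpy()
    sig_p2 = sigs.loc[gene_ids, "sig_p2"].to_numpy()

    gene_sigs = sorted(set(sig_p1) | set(sig_p2))
    total_gene_tpm = float(
        max(truth["p1_tpm"].sum(), truth["p2_tpm"].sum(), truth["f1_tpm"].sum())
    )
    if total_gene_tpm >= 1e6:
        raise ValueError("planted true means exceed one million TPM in total")
    bg_sigs: list[str] = []
    taken = set(gene_sigs)
    while len(bg_sigs) < n_background:
        s = ANCHOR + "".join(rng.choice(BASES, size=SIGNATURE_LENGTH - len(ANCHOR)))
        if s not in taken:
            taken.add(s)
            bg_sigs.append(s)
    # fixed background composition (log-normal abundances, shared by libraries)
    bg_shape = np.exp(rng.normal(0.0, 1.5, size=n_background)) if n_background else np.array([])
    bg_tpm = (
        bg_shape / bg_shape.sum() * (1e6 - total_gene_tpm) if n_background else bg_shape
    )

    all_sigs = gene_sigs + bg_sigs
    sig_index = {s: i for i, s in enumerate(all_sigs)}
    bg_slice = slice(len(gene_sigs), len(all_sigs))
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype, mean_col in (("P1", "p1_tpm"), ("P2", "p2_tpm"), ("F1", "f1_tpm")):
        means_tpm = truth[mean_col].to_numpy(dtype=float)
        expected = means_tpm * library_size / 1e6
        bg_expected = bg_tpm * library_size / 1e6
        for tissue, n_rep in replicates.items():
            for rep in range(1, n_rep + 1):
                lib = f"{genotype}_{tissue}_{rep}"
                gene_counts = _draw_counts(rng, expected, dispersion, noise_model)
                col = np.zeros(len(all_sigs))
                if genotype == "P1":
                    np.add.at(col, [sig_index[s] for s in sig_p1], gene_counts)
                elif genotype == "P2":
                    np.add.at(col, [sig_index[s] for s in sig_p2], gene_counts)
                else:
                    same = sig_p1 == sig_p2
                    np.add.at(col, [sig_index[s] for s in sig_p1[same]], gene_counts[same])
                    split = gene_counts[~same]
                    if noise_model == "none":
                        half = split / 2.0
                    else:
                        half = rng.binomial(split.astype(np.int64), 0.5).astype(float)
                    np.add.at(col, [sig_index[s] for s in sig_p1[~same]], half)
                    np.add.at(col, [sig_index[s] for s in sig_p2[~same]], split - half)
                if n_background:
                    col[bg_slice] = _draw_counts(rng, bg_expected, dispersion, noise_model)
                counts[lib] = col
                meta_rows.append(
                    {"library": lib, "genotype": genotype, "tissue": tissue,
                     "replicate": rep, "total": float(col.sum())}
                )

    table = pd.DataFrame(counts, index=all_sigs)
    if noise_model != "none":
        table = table.astype(np.int64)
    meta = pd.DataFrame(meta_rows)

    gene_of_sig: dict[str, str] = {}
    for g, s1, s2 in zip(gene_ids, sig_p1, sig_p2):
        gene_of_sig[s1] = g
        gene_of_sig[s2] = g
    mapping = pd.Series(gene_of_sig, name="gene_id").reindex(all_sigs)
    return table, meta, mapping


def aggregate_to_genes(tpm: pd.DataFrame, gene_of_signature: pd.Series) -> pd.DataFrame:
    """Sum signature-level abundances to gene level (allelic tags combine)."""
    genes = gene_of_signature.reindex(tpm.index)
    keep = genes.notna()
    return tpm.loc[keep].groupby(genes[keep]).sum()


# ---------------------------------------------------------------------------
# annotation categories

def generate_annotation_categories(
    gene_ids: Sequence[str],
    *,
    tf_fraction: float = 0.15,
    chromatin_fraction: float = 0.05,
    tf_families: Sequence[str] = ("HLH", "MYB", "WRKY", "bZIP", "AP2-EREBP", "C2H2", "HB", "GRAS"),
    functional_categories: Sequence[str] = (
        "carbohydrate metabolism", "energy metabolism", "nucleotide metabolism",
        "amino acid metabolism", "translation",
    ),
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Random TF-family, chromatin-related and functional-category annotations."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    tf_genes = rng.choice(gene_ids, size=int(round(tf_fraction * n)), replace=False)
    tf = pd.DataFrame(
        {"gene_id": tf_genes, "family": rng.choice(tf_families, size=len(tf_genes))}
    )
    chromatin = sorted(rng.choice(gene_ids, size=int(round(chromatin_fraction * n)), replace=False))
    rows = []
    for g in gene_ids:
        for cat in functional_categories:
            if rng.random() < 0.1:
                rows.append({"gene_id": g, "category": cat})
    functional = pd.DataFrame(rows, columns=["gene_id", "category"])
    return tf, list(chromatin), functional


# ---------------------------------------------------------------------------
# truth emission

def emit_truth(
    inheritance_truth: pd.DataFrame,
    qtl_truth: Sequence[QTLTruth],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write tab-delimited truth tables (for tests and audits only)."""
    os.makedirs(out_dir, exist_ok=True)
    patterns_path = os.path.join(out_dir, "truth_patterns.tsv")
    qtl_path = os.path.join(out_dir, "truth_qtls.tsv")
    inheritance_truth.to_csv(patterns_path, sep="\t", index=False)
    rows = []
    for q in qtl_truth:
        row = {
            "trait": q.trait,
            "chrom": q.chrom,
            "pos_cm": q.pos_cm,
            "additive_effect": q.additive_effect,
        }
        for env, frac in q.variance_fraction.items():
            row[f"vf_{env}"] = frac
        rows.append(row)
    pd.DataFrame(
        rows, columns=["trait", "chrom", "pos_cm", "additive_effect"]
        + sorted({k for r in rows for k in r if k.startswith("vf_")})
    ).to_csv(qtl_path, sep="\t", index=False)
    return {"patterns": patterns_path, "qtls": qtl_path}


def read_truth(out_dir: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-trip reader for :func:`emit_truth` outputs."""
    patterns = pd.read_csv(os.path.join(out_dir, "truth_patterns.tsv"), sep="\t")
    qtls = pd.read_csv(os.path.join(out_dir, "truth_qtls.tsv"), sep="\t")
    return patterns, qtls


# ---------------------------------------------------------------------------
# convenience: write a full synthetic study to disk

def write_study(
    out_dir: str | os.PathLike,
    *,
    reference: ReferencePair,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    marker_map: pd.DataFrame,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> None:
    """Write every simulated input in its external text format."""
    os.makedirs(out_dir, exist_ok=True)
    p = lambda name: os.path.join(out_dir, name)
    hio.write_fasta(reference.transcripts["P1"], p("p1_transcripts.fasta"))
    hio.write_fasta(reference.transcripts["P2"], p("p2_transcripts.fasta"))
    hio.write_fasta(reference.chromosomes["P1"], p("p1_chromosomes.fasta"))
    hio.write_fasta(reference.chromosomes["P2"], p("p2_chromosomes.fasta"))
    hio.write_gff3(reference.genes, p("genes.gff3"))
    hio.write_count_table(counts, p("counts.tsv"))
    hio.write_library_meta(meta, p("libraries.csv"))
    hio.write_marker_map(marker_map, p("marker_map.csv"))
    hio.write_genotypes(genotypes, p("genotypes.csv"))
    hio.write_phenotypes(phenotypes, p("phenotypes.csv"))
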