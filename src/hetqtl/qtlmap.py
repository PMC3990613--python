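"""Regression-based QTL mapping for recombinant inbred lines.

The scan follows the regression-on-expectation idea (Haley-Knott): at every
grid position the unobserved QTL genotype is replaced by its conditional
expectation given the flanking-marker genotypes, with recombination fractions
obtained from the Kosambi map function and inflated to the RIL-by-selfing
scale R = 2r / (1 + 2r) (Haldane-Waddington).  Background variance from other
QTLs is absorbed by stepwise-selected marker cofactors, excluded within a
window around the evaluated position (composite interval mapping in the
regression formulation).  Genome-wide significance comes from permuting the
phenotype across lines and taking an upper quantile of the per-permutation
maximum LOD.

LOD is defined through residual sums of squares,

    LOD = (n / 2) * log10(RSS_reduced / RSS_full),

with the reduced model holding the intercept and active cofactors only.

QTLs detected in several environments are merged by marker-interval overlap
and summarised by their average peak LOD (rounded half away from zero to one
decimal), reproducing the reporting convention of multi-environment RIL
studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "kosambi_cm_to_r",
    "kosambi_r_to_cm",
    "ril_recomb",
    "estimate_map_distances",
    "select_cofactors",
    "scan",
    "max_scan_lods",
    "permutation_threshold",
    "call_qtls",
    "aggregate_environments",
    "select_by_mean_lod",
    "round_half_away",
    "LODProfile",
    "QTLRecord",
    "MergedQTL",
]


# ---------------------------------------------------------------------------
# map functions

def kosambi_r_to_cm(r: float) -> float:
    """Kosambi map distance (cM) for a meiotic recombination fraction.

    d = (1/4) * ln((1 + 2r) / (1 - 2r)) Morgans, returned in centimorgans.
    """
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_cm_to_r(cm) :
    """Inverse Kosambi transform: r = (1/2) * tanh(2 d) with d in Morgans."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(0.02 * cm)
    return float(r) if r.ndim == 0 else r


def ril_recomb(r):
    """RIL-by-selfing recombination probability R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (3.65 -> 3.7, -3.65 -> -3.7)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# map distance estimation

def estimate_map_distances(
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    *,
    max_cm: float = 50.0,
) -> pd.DataFrame:
    """Estimate cM positions from RIL genotypes for markers in given order.

    Adjacent-marker RIL recombinant fractions R are counted from discordant
    genotype pairs, corrected to the meiotic scale r = R / (2 (1 - R)) and
    converted to cM with the Kosambi function; positions accumulate per
    chromosome.  Intervals whose corrected r reaches 0.5 are flagged unlinked
    and capped at ``max_cm`` with a warning.

    Parameters
    ----------
    genotypes : lines x markers frame coded +1 / -1 / NaN.
    markers : frame with columns ``marker`` and ``chrom`` in map order.
    """
    out = markers.copy().reset_index(drop=True)
    cms = np.zeros(len(out))
    for _, grp in out.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = 0.0
        cms[idx[0]] = 0.0
        for prev, cur in zip(idx[:-1], idx[1:]):
            a = genotypes[out.loc[prev, "marker"]].to_numpy(dtype=float)
            b = genotypes[out.loc[cur, "marker"]].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() == 0:
                raise ValueError(
                    f"no informative lines between {out.loc[prev, 'marker']} "
                    f"and {out.loc[cur, 'marker']}"
                )
            big_r = float(np.mean(a[ok] != b[ok]))
            if big_r >= 0.5:
                warnings.warn(
                    f"markers {out.loc[prev, 'marker']} and {out.loc[cur, 'marker']} "
                    f"appear unlinked (R = {big_r:.3f}); capping interval at {max_cm} cM"
                )
                d = max_cm
            else:
                r = big_r / (2.0 * (1.0 - big_r))
                d = max_cm if r >= 0.5 else min(kosambi_r_to_cm(r), max_cm)
            pos += d
            cms[idx[np.where(idx == cur)[0][0]]] = pos
    out["cm"] = cms
    return out


# ---------------------------------------------------------------------------
# expected QTL codes

def _single_flank_expectation(g: np.ndarray, d_cm: float) -> np.ndarray:
    big_r = ril_recomb(kosambi_cm_to_r(d_cm))
    return g * (1.0 - 2.0 * big_r)


def _double_flank_expectation(
    g_left: np.ndarray, g_right: np.ndarray, d_left: float, d_right: float
) -> np.ndarray:
    a = ril_recomb(kosambi_cm_to_r(d_left))
    b = ril_recomb(kosambi_cm_to_r(d_right))
    same = g_left == g_right
    out = np.empty_like(g_left, dtype=float)
    denom_same = (1.0 - a) * (1.0 - b) + a * b
    out[same] = g_left[same] * ((1.0 - a) * (1.0 - b) - a * b) / denom_same
    denom_diff = (1.0 - a) * b + a * (1.0 - b)
    out[~same] = (
        g_left[~same] * (1.0 - a) * b + g_right[~same] * a * (1.0 - b)
    ) / denom_diff
    return out


def expected_qtl_code(
    genotypes: pd.DataFrame, marker_map: pd.DataFrame, chrom, pos_cm: float
) -> np.ndarray:
    """Conditional expectation of the RIL QTL code (+1/-1) at a map position.

    Uses the flanking markers of the position; lines with missing flanks fall
    back to the nearest non-missing markers (single-flank attenuation if only
    one side is informative, zero if neither is).
    """
    chrom_map = marker_map[marker_map["chrom"] == chrom].sort_values("cm")
    if chrom_map.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    names = chrom_map["marker"].to_list()
    cms = chrom_map["cm"].to_numpy(dtype=float)
    G = genotypes[names].to_numpy(dtype=float)
    n = G.shape[0]
    out = np.zeros(n)

    complete = ~np.isnan(G).any(axis=1)
    left = int(np.searchsorted(cms, pos_cm, side="right")) - 1
    right = int(np.searchsorted(cms, pos_cm, side="left"))
    left = min(max(left, 0), len(cms) - 1)
    right = min(max(right, 0), len(cms) - 1)

    def expectation(rows: np.ndarray, i_left: int, i_right: int) -> np.ndarray:
        if i_left == i_right or cms[i_right] <= cms[i_left]:
            return G[rows, i_left]
        if pos_cm <= cms[i_left]:
            return G[rows, i_left]
        if pos_cm >= cms[i_right]:
            return G[rows, i_right]
        return _double_flank_expectation(
            G[rows, i_left], G[rows, i_right], pos_cm - cms[i_left], cms[i_right] - pos_cm
        )

    if complete.any():
        rows = np.where(complete)[0]
        out[rows] = expectation(rows, left, right)

    for i in np.where(~complete)[0]:
        row = G[i]
        present = ~np.isnan(row)
        lefts = np.where(present & (cms <= pos_cm))[0]
        rights = np.where(present & (cms >= pos_cm))[0]
        if lefts.size and rights.size:
            il, ir = lefts[-1], rights[0]
            if il == ir:
                out[i] = row[il]
            else:
                out[i] = _double_flank_expectation(
                    row[il : il + 1], row[ir : ir + 1], pos_cm - cms[il], cms[ir] - pos_cm
                )[0]
        elif lefts.size:
            il = lefts[-1]
            out[i] = _single_flank_expectation(row[il : il + 1], pos_cm - cms[il])[0]
        elif rights.size:
            ir = rights[0]
            out[i] = _single_flank_expectation(row[ir : ir + 1], cms[ir] - pos_cm)[0]
        else:
            out[i] = 0.0
    return out


def grid_codes(
    genotypes: pd.DataFrame, marker_map: pd.DataFrame, grid: pd.DataFrame
) -> np.ndarray:
    """Expected QTL codes (lines x grid positions) for a whole scan grid.

    Equivalent to calling :func:`expected_qtl_code` per position but with the
    per-chromosome marker arrays prepared once.  Lines with missing genotypes
    fall back to the slow per-line path.
    """
    n = len(genotypes.index)
    out = np.zeros((n, len(grid)))
    col = 0
    for chrom, gpos in grid.groupby("chrom", sort=False):
        chrom_map = marker_map[marker_map["chrom"] == chrom].sort_values("cm")
        names = chrom_map["marker"].to_list()
        cms = chrom_map["cm"].to_numpy(dtype=float)
        G = genotypes[names].to_numpy(dtype=float)
        has_nan = np.isnan(G).any()
        for pos_cm in gpos["cm"].to_numpy(dtype=float):
            if has_nan:
                out[:, col] = expected_qtl_code(genotypes, marker_map, chrom, pos_cm)
            else:
                left = min(max(int(np.searchsorted(cms, pos_cm, side="right")) - 1, 0), len(cms) - 1)
                right = min(max(int(np.searchsorted(cms, pos_cm, side="left")), 0), len(cms) - 1)
                if left == right or pos_cm <= cms[left]:
                    out[:, col] = G[:, left]
                elif pos_cm >= cms[right]:
                    out[:, col] = G[:, right]
                else:
                    out[:, col] = _double_flank_expectation(
                        G[:, left], G[:, right], pos_cm - cms[left], cms[right] - pos_cm
                    )
            col += 1
    return out


def _scan_grid(marker_map: pd.DataFrame, step: float) -> pd.DataFrame:
    """Evaluation positions covering [first, last] marker per chromosome."""
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        lo = float(grp["cm"].min())
        hi = float(grp["cm"].max())
        pos = np.arange(lo, hi + 1e-9, step)
        if pos.size == 0 or pos[-1] < hi - 1e-9:
            pos = np.append(pos, hi)
        rows.append(pd.DataFrame({"chrom": chrom, "cm": pos}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# containers

@dataclass
class LODProfile:
    """Position-wise LOD scan for one trait in one environment."""

    positions: pd.DataFrame  # columns: chrom, cm, lod
    n: int
    cofactors: tuple[str, ...] = ()
    trait: str | None = None
    environment: str | None = None

    def max_lod(self) -> float:
        return float(self.positions["lod"].max())


@dataclass
class QTLRecord:
    """A called QTL in one environment."""

    trait: str
    environment: str
    chrom: object
    peak_cm: float
    marker_lo: str
    marker_hi: str
    cm_lo: float
    cm_hi: float
    r2_pct: float
    additive_effect: float
    lod: float
    threshold: float


@dataclass
class MergedQTL:
    """Cross-environment aggregate of overlapping per-environment QTLs."""

    name: str
    trait: str
    chrom: object
    marker_lo: str
    marker_hi: str
    cm_lo: float
    cm_hi: float
    mean_lod: float
    environments: tuple[str, ...]
    records: tuple[QTLRecord, ...] = field(repr=False, default=())


# ---------------------------------------------------------------------------
# regression helpers

def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _align(genotypes: pd.DataFrame, phenotype: pd.Series):
    y = phenotype.dropna()
    common = genotypes.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 lines with genotype and phenotype")
    return genotypes.loc[common], y.loc[common].to_numpy(dtype=float)


def _imputed_marker_matrix(genotypes: pd.DataFrame, markers: Sequence[str]) -> np.ndarray:
    X = genotypes[list(markers)].to_numpy(dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(means, idx[1])
    return X


def select_cofactors(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    *,
    max_cofactors: int = 5,
    f_enter: float = 2.5,
) -> list[str]:
    """Forward stepwise marker selection for the CIM background model.

    Markers enter by largest residual-sum-of-squares reduction until
    ``max_cofactors`` is reached or the partial F statistic of the best
    candidate falls below ``f_enter``.  A constant phenotype selects nothing.
    """
    if max_cofactors <= 0:
        return []
    geno, y = _align(genotypes, phenotype)
    if np.ptp(y) == 0:
        return []
    markers = list(geno.columns)
    C = _imputed_marker_matrix(geno, markers)
    n = len(y)
    selected: list[str] = []
    design = np.ones((n, 1))
    for _ in range(max_cofactors):
        Q, _ = np.linalg.qr(design)
        r = y - Q @ (Q.T @ y)
        rss_old = float(r @ r)
        C_res = C - Q @ (Q.T @ C)
        norms = np.einsum("ij,ij->j", C_res, C_res)
        with np.errstate(divide="ignore", invalid="ignore"):
            reductions = np.where(norms > 1e-12, (C_res.T @ r) ** 2 / norms, 0.0)
        best = int(np.argmax(reductions))
        rss_new = rss_old - float(reductions[best])
        dof = n - design.shape[1] - 1
        if dof <= 0 or rss_new <= 0:
            break
        f_stat = (rss_old - rss_new) / (rss_new / dof)
        if f_stat < f_enter:
            break
        selected.append(markers[best])
        design = np.column_stack([design, C[:, best]])
        C[:, best] = 0.0
    return selected


# ---------------------------------------------------------------------------
# the scan

def _marker_positions(marker_map: pd.DataFrame) -> dict:
    return {
        row.marker: (row.chrom, float(row.cm)) for row in marker_map.itertuples(index=False)
    }


def _active_cofactors(
    cofactors: Sequence[str],
    marker_pos: dict,
    chrom,
    pos_cm: float,
    window: float,
) -> tuple[str, ...]:
    if not cofactors:
        return ()
    active = []
    for m in cofactors:
        loc = marker_pos.get(m)
        if loc is not None and loc[0] == chrom and abs(loc[1] - pos_cm) <= window:
            continue
        active.append(m)
    return tuple(active)


def scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    marker_map: pd.DataFrame,
    *,
    step: float = 1.0,
    cofactors: Sequence[str] = (),
    window: float = 10.0,
    trait: str | None = None,
    environment: str | None = None,
) -> LODProfile:
    """Composite-interval-mapping LOD scan over the whole map.

    Cofactor markers within ``window`` cM of the evaluated position (same
    chromosome) are dropped from the model at that position; the reduced
    model contains the intercept and the active cofactors only.
    """
    geno, y = _align(genotypes, phenotype)
    n = len(y)
    grid = _scan_grid(marker_map, step)
    lods = np.zeros(len(grid))
    if np.ptp(y) > 0:
        codes = grid_codes(geno, marker_map, grid)
        cof_matrix = (
            _imputed_marker_matrix(geno, cofactors) if len(cofactors) else np.empty((n, 0))
        )
        cof_index = {m: j for j, m in enumerate(cofactors)}
        marker_pos = _marker_positions(marker_map)
        # per active-cofactor-set cache: orthonormal basis, residual y, its RSS
        red_cache: dict[tuple, tuple[np.ndarray, np.ndarray, float]] = {}
        skipped: list[str] = []
        for i, row in enumerate(grid.itertuples(index=False)):
            active = _active_cofactors(cofactors, marker_pos, row.chrom, row.cm, window)
            if active not in red_cache:
                X_red = np.column_stack(
                    [np.ones(n)] + [cof_matrix[:, cof_index[m]] for m in active]
                )
                Q, _ = np.linalg.qr(X_red)
                y_res = y - Q @ (Q.T @ y)
                red_cache[active] = (Q, y_res, float(y_res @ y_res))
            Q, y_res, rss_red = red_cache[active]
            x = codes[:, i]
            if np.ptp(x) < 1e-12:
                continue
            x_res = x - Q @ (Q.T @ x)
            nx2 = float(x_res @ x_res)
            if nx2 < 1e-10:
                skipped.append(f"{row.chrom}:{row.cm:.1f}")
                continue
            rss_full = rss_red - float(x_res @ y) ** 2 / nx2
            rss_full = max(rss_full, np.finfo(float).tiny)
            lods[i] = max(0.0, (n / 2.0) * math.log10(rss_red / rss_full))
        if skipped:
            warnings.warn(
                f"singular design at {len(skipped)} positions "
                f"({skipped[0]} ... {skipped[-1]}); skipped"
            )
    positions = grid.assign(lod=lods)
    return LODProfile(
        positions=positions,
        n=n,
        cofactors=tuple(cofactors),
        trait=trait,
        environment=environment,
    )


def max_scan_lods(
    genotypes: pd.DataFrame,
    phenotypes: np.ndarray,
    marker_map: pd.DataFrame,
    *,
    step: float = 1.0,
    cofactors: Sequence[str] = (),
    window: float = 10.0,
) -> np.ndarray:
    """Genome-wide maximum LOD for each column of a phenotype matrix.

    The design matrices depend only on the genotypes, so many phenotypes
    (e.g. permutations, or batches of simulated null traits) are scanned with
    shared factorizations.  Rows of ``phenotypes`` follow ``genotypes.index``.
    """
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(genotypes.index)
    if Y.shape[0] != n:
        raise ValueError("phenotype matrix rows must match genotype lines")
    grid = _scan_grid(marker_map, step)
    codes = grid_codes(genotypes, marker_map, grid)
    total_ss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))

    if not len(cofactors):
        Xc = codes - codes.mean(axis=0)
        norms = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
        keep = norms > 1e-12
        Xn = np.where(keep, Xc / np.where(keep, norms, 1.0), 0.0)
        Yc = Y - Y.mean(axis=0)
        C = Xn.T @ Yc  # positions x phenotypes
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(total_ss > 0, C**2 / total_ss, 0.0)
        ratio = np.clip(ratio, 0.0, 1.0 - 1e-12)
        lods = -(n / 2.0) * np.log10(1.0 - ratio)
        return lods.max(axis=0)

    cof_matrix = _imputed_marker_matrix(genotypes, cofactors)
    cof_index = {m: j for j, m in enumerate(cofactors)}
    sq = np.einsum("ij,ij->j", Y, Y)
    maxima = np.zeros(Y.shape[1])
    marker_pos = _marker_positions(marker_map)
    red_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for p, row in enumerate(grid.itertuples(index=False)):
        active = _active_cofactors(cofactors, marker_pos, row.chrom, row.cm, window)
        if active not in red_cache:
            X_red = np.column_stack(
                [np.ones(n)] + [cof_matrix[:, cof_index[m]] for m in active]
            )
            Q_red, _ = np.linalg.qr(X_red)
            red_cache[active] = (X_red, Q_red)
        X_red, Q_red = red_cache[active]
        x = codes[:, p]
        if np.ptp(x) < 1e-12:
            continue
        Q_full, _ = np.linalg.qr(np.column_stack([X_red, x]))
        rss_red = sq - np.einsum("ij,ij->j", Q_red.T @ Y, Q_red.T @ Y)
        rss_full = sq - np.einsum("ij,ij->j", Q_full.T @ Y, Q_full.T @ Y)
        rss_full = np.maximum(rss_full, np.finfo(float).tiny)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = np.where(rss_red > 0, (n / 2.0) * np.log10(rss_red / rss_full), 0.0)
        maxima = np.maximum(maxima, np.maximum(lod, 0.0))
    return maxima


def permutation_threshold(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    marker_map: pd.DataFrame,
    *,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | None = None,
    step: float = 1.0,
    cofactors: Sequence[str] = (),
    window: float = 10.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype values are shuffled across lines with genotypes fixed; the
    threshold is the empirical (1 - alpha) quantile of the per-permutation
    maximum LOD, taken as order statistic ceil((1 - alpha) * n_perm) of the
    sorted maxima.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    geno, y = _align(genotypes, phenotype)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: permutation threshold undefined")
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    maxima = np.sort(
        max_scan_lods(geno, Y, marker_map, step=step, cofactors=cofactors, window=window)
    )
    k = math.ceil((1.0 - alpha) * n_perm)
    k = min(max(k, 1), n_perm)
    return float(maxima[k - 1])


# ---------------------------------------------------------------------------
# calling and aggregation

def _flanking_markers(marker_map: pd.DataFrame, chrom, lo: float, hi: float):
    mm = marker_map[marker_map["chrom"] == chrom].sort_values("cm")
    cms = mm["cm"].to_numpy(dtype=float)
    names = mm["marker"].to_list()
    i_lo = int(np.searchsorted(cms, lo + 1e-9, side="right")) - 1
    i_lo = max(i_lo, 0)
    i_hi = int(np.searchsorted(cms, hi - 1e-9, side="left"))
    i_hi = min(i_hi, len(names) - 1)
    return names[i_lo], names[i_hi], float(cms[i_lo]), float(cms[i_hi])


def call_qtls(
    profile: LODProfile,
    threshold: float,
    marker_map: pd.DataFrame,
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    *,
    cofactors: Sequence[str] | None = None,
    window: float = 10.0,
) -> list[QTLRecord]:
    """Call one QTL per maximal contiguous super-threshold region.

    The additive effect at the peak is half the difference between the mean
    phenotype of lines with positive and negative expected QTL code (positive
    effect: the P1 allele increases the trait); R^2 is the percentage of the
    total sum of squares removed by the peak term on top of the active
    cofactors.
    """
    if cofactors is None:
        cofactors = profile.cofactors
    geno, y = _align(genotypes, phenotype)
    n = len(y)
    records: list[QTLRecord] = []
    pos = profile.positions
    for chrom, grp in pos.groupby("chrom", sort=False):
        above = grp["lod"].to_numpy() >= threshold
        if not above.any():
            continue
        cms = grp["cm"].to_numpy(dtype=float)
        lods = grp["lod"].to_numpy(dtype=float)
        boundaries = np.flatnonzero(np.diff(above.astype(int)))
        starts = [0] if above[0] else []
        starts += [b + 1 for b in boundaries if above[b + 1]]
        ends = [b for b in boundaries if above[b]]
        if above[-1]:
            ends.append(len(above) - 1)
        for s, e in zip(starts, ends):
            seg = slice(s, e + 1)
            peak_idx = s + int(np.argmax(lods[seg]))
            peak_cm = float(cms[peak_idx])
            marker_lo, marker_hi, cm_lo, cm_hi = _flanking_markers(
                marker_map, chrom, float(cms[s]), float(cms[e])
            )
            x = expected_qtl_code(geno, marker_map, chrom, peak_cm)
            p1 = x > 0
            p2 = x < 0
            if p1.any() and p2.any():
                effect = (float(y[p1].mean()) - float(y[p2].mean())) / 2.0
            else:
                effect = float("nan")
            active = _active_cofactors(cofactors, _marker_positions(marker_map), chrom, peak_cm, window)
            cof_cols = (
                _imputed_marker_matrix(geno, active) if len(active) else np.empty((n, 0))
            )
            X_red = np.column_stack([np.ones(n), cof_cols])
            X_full = np.column_stack([X_red, x])
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 100.0 * (_rss(X_red, y) - _rss(X_full, y)) / tss if tss > 0 else 0.0
            records.append(
                QTLRecord(
                    trait=profile.trait or "trait",
                    environment=profile.environment or "env",
                    chrom=chrom,
                    peak_cm=peak_cm,
                    marker_lo=marker_lo,
                    marker_hi=marker_hi,
                    cm_lo=cm_lo,
                    cm_hi=cm_hi,
                    r2_pct=r2,
                    additive_effect=effect,
                    lod=float(lods[peak_idx]),
                    threshold=float(threshold),
                )
            )
    return records


def aggregate_environments(records: Iterable[QTLRecord]) -> list[MergedQTL]:
    """Merge per-environment QTLs of a trait by marker-interval overlap.

    Records of the same trait on the same chromosome whose cM marker intervals
    overlap (including a shared endpoint marker) collapse into one QTL; chains
    of pairwise-overlapping intervals merge transitively.  The summary LOD is
    the arithmetic mean of the constituent peak LODs, rounded half away from
    zero to one decimal.  Names are ``q<trait>-<k>`` in chromosome order
    within trait.
    """
    records = list(records)
    merged_by_trait: dict[str, list[dict]] = {}
    for trait in sorted({r.trait for r in records}):
        groups: list[dict] = []
        trait_recs = [r for r in records if r.trait == trait]
        for chrom in sorted({r.chrom for r in trait_recs}, key=lambda c: (str(c).zfill(8))):
            chrom_recs = sorted(
                [r for r in trait_recs if r.chrom == chrom], key=lambda r: (r.cm_lo, r.cm_hi)
            )
            current: list[QTLRecord] = []
            hi = -math.inf
            for rec in chrom_recs:
                if current and rec.cm_lo > hi:
                    groups.append({"chrom": chrom, "records": current})
                    current = []
                    hi = -math.inf
                current.append(rec)
                hi = max(hi, rec.cm_hi)
            if current:
                groups.append({"chrom": chrom, "records": current})
        merged_by_trait[trait] = groups

    out: list[MergedQTL] = []
    for trait, groups in merged_by_trait.items():
        groups.sort(key=lambda g: (str(g["chrom"]).zfill(8), min(r.cm_lo for r in g["records"])))
        for k, grp in enumerate(groups, start=1):
            recs = tuple(grp["records"])
            cm_lo = min(r.cm_lo for r in recs)
            cm_hi = max(r.cm_hi for r in recs)
            lo_rec = min(recs, key=lambda r: r.cm_lo)
            hi_rec = max(recs, key=lambda r: r.cm_hi)
            mean_lod = round_half_away(sum(r.lod for r in recs) / len(recs), 1)
            out.append(
                MergedQTL(
                    name=f"q{trait.lower()}-{k}",
                    trait=trait,
                    chrom=grp["chrom"],
                    marker_lo=lo_rec.marker_lo,
                    marker_hi=hi_rec.marker_hi,
                    cm_lo=cm_lo,
                    cm_hi=cm_hi,
                    mean_lod=mean_lod,
                    environments=tuple(r.environment for r in recs),
                    records=recs,
                )
            )
    return out


def select_by_mean_lod(merged: Iterable[MergedQTL], minimum: float = 5.0) -> list[MergedQTL]:
    """Retain merged QTLs whose (rounded) mean LOD is at least ``minimum``."""
    return [m for m in merged if m.mean_lod >= minimum]


def merged_to_frame(merged: Iterable[MergedQTL]) -> pd.DataFrame:
    """Tabular view of merged QTLs (one row per QTL)."""
    rows = []
    for m in merged:
        rows.append(
            {
                "name": m.name,
                "trait": m.trait,
                "chrom": m.chrom,
                "marker_lo": m.marker_lo,
                "marker_hi": m.marker_hi,
                "cm_lo": m.cm_lo,
                "cm_hi": m.cm_hi,
                "mean_lod": m.mean_lod,
                "n_environments": len(m.environments),
                "environments": ";".join(str(e) for e in m.environments),
            }
        )
    return pd.DataFrame(rows)
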