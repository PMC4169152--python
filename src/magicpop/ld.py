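"""Linkage disequilibrium in inbred-line populations: D, D', r2, heatmap
matrices on padded genome coordinates, and lowess-smoothed decay curves.

RILs are treated as inbred: each line homozygous and non-missing at both
markers of a pair contributes its single two-locus haplotype, and lines
heterozygous at either marker are excluded (residual heterozygosity at F7 is
~1.6%, so the bias is negligible).  D' is reported as |D|/Dmax in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import MISSING, GeneticMap, GenotypeMatrix

__all__ = [
    "LDPair",
    "LDUndefinedError",
    "InsufficientDataError",
    "haplotype_counts",
    "ld_pair",
    "ld_matrix",
    "ld_square",
    "heatmap_matrix",
    "concat_map_padded",
    "ld_decay",
    "LDDecayCurve",
]


class LDUndefinedError(ValueError):
    """LD undefined (a monomorphic margin)."""


class InsufficientDataError(ValueError):
    """Too few informative lines to form haplotype counts."""


@dataclass
class LDPair:
    """Two-locus LD coefficients from haplotype frequencies."""

    D: float
    Dprime: float
    r2: float
    marker_a: str | None = None
    marker_b: str | None = None
    distance_cM: float | None = None


def haplotype_counts(genotypes: GenotypeMatrix, marker_a: str, marker_b: str) -> np.ndarray:
    """2x2 two-locus haplotype counts over lines homozygous and non-missing at
    both markers.  Rows index the allele at marker_a (0/1), columns at
    marker_b; each informative line contributes one haplotype."""
    ia, ib = genotypes.marker_index(marker_a), genotypes.marker_index(marker_b)
    a, b = genotypes.calls[:, ia], genotypes.calls[:, ib]
    hom = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    if hom.sum() < 2:
        raise InsufficientDataError(
            f"only {int(hom.sum())} doubly homozygous lines for ({marker_a}, {marker_b})"
        )
    ha, hb = (a[hom] // 2).astype(int), (b[hom] // 2).astype(int)
    table = np.zeros((2, 2), dtype=int)
    np.add.at(table, (ha, hb), 1)
    return table


def ld_pair(table: np.ndarray, **meta) -> LDPair:
    """LD coefficients from a 2x2 haplotype count table.

    With haplotype frequency p_AB and allele frequencies p_A, p_B:
    D = p_AB - p_A p_B; r2 = D^2 / (p_A(1-p_A) p_B(1-p_B));
    D' = |D| / Dmax with Dmax = min(p_A(1-p_B), (1-p_A)p_B) for D > 0 and
    min(p_A p_B, (1-p_A)(1-p_B)) otherwise.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise InsufficientDataError("empty haplotype table")
    p = table / n
    p_a = p[1, :].sum()  # frequency of allele 1 at marker A
    p_b = p[:, 1].sum()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LDUndefinedError("monomorphic margin; LD undefined")
    d = p[1, 1] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return LDPair(D=float(d), Dprime=float(dprime), r2=float(r2), **meta)


def _pair_distance(gmap: GeneticMap | None, ma: str, mb: str) -> float:
    if gmap is None:
        return np.nan
    try:
        ca, pa = gmap.position_of(ma)
        cb, pb = gmap.position_of(mb)
    except KeyError:
        return np.nan
    return abs(pa - pb) if ca == cb else np.nan


def ld_matrix(
    genotypes: GenotypeMatrix,
    markers: list[str] | None = None,
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """All-pairs LD as a long table (marker_a, marker_b, distance_cM, D,
    Dprime, r2, defined).  Pairs with undefined LD (monomorphic margin or too
    few informative lines) are flagged with defined=False, not dropped.
    Distance is NaN for inter-chromosome or unmapped pairs."""
    markers = list(markers) if markers is not None else list(genotypes.markers)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    pos = {m: gmap.position_of(m) if gmap is not None else None for m in markers}
    rows = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            ma, mb = markers[i], markers[j]
            if gmap is not None:
                ca, pa = pos[ma]
                cb, pb = pos[mb]
                dist = abs(pa - pb) if ca == cb else np.nan
            else:
                dist = np.nan
            try:
                pair = ld_pair(haplotype_counts(genotypes, ma, mb))
                rows.append((ma, mb, dist, pair.D, pair.Dprime, pair.r2, True))
            except (LDUndefinedError, InsufficientDataError):
                rows.append((ma, mb, dist, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "distance_cM", "D", "Dprime", "r2", "defined"]
    )


def ld_square(pairs: pd.DataFrame, markers: list[str], statistic: str = "r2") -> pd.DataFrame:
    """Symmetric square matrix of one LD statistic with unit diagonal."""
    mat = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    wanted = set(markers)
    for _, row in pairs.iterrows():
        if row["marker_a"] not in wanted or row["marker_b"] not in wanted:
            continue
        v = row[statistic]
        mat.loc[row["marker_a"], row["marker_b"]] = v
        mat.loc[row["marker_b"], row["marker_a"]] = v
    return mat


def heatmap_matrix(pairs: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Dense heatmap matrix with D' above the diagonal and r2 below (markers
    in the given order), unit diagonal — the numeric counterpart of the
    conventional two-statistic LD heatmap."""
    dp = ld_square(pairs, markers, "Dprime").to_numpy()
    r2 = ld_square(pairs, markers, "r2").to_numpy()
    out = np.tril(r2, k=-1) + np.triu(dp, k=1) + np.eye(len(markers))
    return pd.DataFrame(out, index=markers, columns=markers)


def concat_map_padded(gmap: GeneticMap, pad_to_cM: float = 250.0) -> pd.Series:
    """Global marker coordinate with chromosomes concatenated after padding
    each to a fixed length: global = chromosome_index * pad + within-chrom cM.
    Chromosomes follow genome order (1A, 1B, 1D, 2A, ...)."""
    max_len = max(gmap.pos[sl].max() for _, sl in gmap.chrom_slices())
    pad = pad_to_cM
    if max_len > pad_to_cM:
        warnings.warn(
            f"chromosome length {max_len:.1f} cM exceeds pad {pad_to_cM}; padding to the maximum",
            stacklevel=2,
        )
        pad = max_len
    out = np.empty(gmap.n_markers)
    for k, (_, sl) in enumerate(gmap.chrom_slices()):
        out[sl] = k * pad + gmap.pos[sl]
    return pd.Series(out, index=gmap.markers, name="global_cM")


@dataclass
class LDDecayCurve:
    """Raw LD-vs-distance scatter and its lowess smooth."""

    distance: np.ndarray
    statistic: np.ndarray
    smooth_x: np.ndarray | None
    smooth_y: np.ndarray | None
    smoothing_fraction: float

    def smoothed_at(self, d: float) -> float:
        """Smoothed statistic at distance d (linear interpolation)."""
        if self.smooth_x is None:
            raise ValueError("no smoothed curve (too few pairs)")
        return float(np.interp(d, self.smooth_x, self.smooth_y))


def ld_decay(
    pairs: pd.DataFrame,
    statistic: str = "r2",
    smoothing_fraction: float = 0.1,
    min_pairs: int = 10,
) -> LDDecayCurve:
    """LD decay with genetic distance: intra-chromosome defined pairs only,
    smoothed by lowess (tricube-weighted local linear regression, three
    robustifying iterations) with the given span fraction."""
    ok = pairs["defined"] & pairs["distance_cM"].notna()
    d = pairs.loc[ok, "distance_cM"].to_numpy(dtype=float)
    y = pairs.loc[ok, statistic].to_numpy(dtype=float)
    if len(d) < min_pairs:
        return LDDecayCurve(d, y, None, None, smoothing_fraction)
    sm = lowess(y, d, frac=smoothing_fraction, it=3, return_sorted=True)
    return LDDecayCurve(d, y, sm[:, 0], sm[:, 1], smoothing_fraction)
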