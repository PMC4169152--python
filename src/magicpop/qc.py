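"""Marker/line quality control and diversity statistics for genotype panels.

Implements the two filtering regimes used for array-genotyped wheat panels —
a variety-panel filter (codominant markers, maf >= 0.01, < 10% missing) and a
MAGIC-population filter (line call rate >= 75%, marker success rate > 0.91,
maf > 0.05, one of each perfectly correlated marker pair removed) — plus
expected heterozygosity summaries and panel-to-panel diversity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING, GeneticMap, GenotypeMatrix

__all__ = [
    "marker_stats",
    "filter_variety_panel",
    "filter_magic_panel",
    "expected_heterozygosity",
    "diversity_ratio",
    "DiversitySummary",
    "DiversityRatio",
    "QCReport",
]


def _allele1_freq(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker allele-1 frequency among non-missing calls (heterozygote
    contributes one copy of each allele) and the non-missing call count."""
    obs = calls != MISSING
    n_called = obs.sum(axis=0)
    dose = np.where(obs, calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, dose / (2.0 * n_called), np.nan)
    return p, n_called


def marker_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, minor allele frequency and polymorphism flag.

    maf is computed on non-missing calls only; an all-missing marker gets
    call_rate 0 and maf NaN (undefined).
    """
    if genotypes.n_lines < 1:
        raise ValueError("need at least one line")
    p, n_called = _allele1_freq(genotypes.calls)
    call_rate = n_called / genotypes.n_lines
    maf = np.minimum(p, 1.0 - p)
    poly = (n_called > 0) & (maf > 0)
    return pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "polymorphic": poly,
            "n_called": n_called,
        },
        index=pd.Index(genotypes.markers, name="marker"),
    )


def filter_variety_panel(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_max: float = 0.10,
) -> GenotypeMatrix:
    """Variety-panel marker filter: keep markers with maf >= maf_min and a
    missing fraction strictly below missing_max.  Lines are untouched."""
    stats = marker_stats(genotypes)
    # exact count ratio: 4/40 missing must compare equal to a 0.10 threshold
    missing_frac = (genotypes.n_lines - stats["n_called"].to_numpy()) / genotypes.n_lines
    maf = stats["maf"].to_numpy()
    keep = (~np.isnan(maf)) & (maf >= maf_min) & (missing_frac < missing_max)
    return genotypes.subset(markers=genotypes.markers[keep])


@dataclass
class QCReport:
    """Counts removed per MAGIC-filter rule."""

    lines_low_call_rate: int
    markers_low_success: int
    markers_low_maf: int
    markers_duplicate: int
    n_lines_kept: int
    n_markers_kept: int


def _map_order(markers: np.ndarray, gmap: GeneticMap | None) -> np.ndarray:
    """Indices of `markers` in map order; unmapped markers follow mapped ones,
    ordered lexicographically."""
    if gmap is None:
        return np.argsort(markers, kind="stable")
    rank = {m: i for i, m in enumerate(gmap.markers)}
    n_mapped = len(rank)
    keys = [(rank.get(m, n_mapped), m) for m in markers]
    return np.array(sorted(range(len(markers)), key=lambda i: keys[i]))


def _perfect_pairs(calls: np.ndarray) -> list[tuple[int, int]]:
    """Pairs of marker columns with identical non-missing call patterns over
    jointly non-missing lines (global 0<->2 allele flip allowed).  Requires at
    least two jointly observed lines.  Candidate pairs are pre-screened with a
    correlation matrix on mean-imputed dosages, then verified exactly."""
    n, m = calls.shape
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), mu, x)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    corr = (centered / safe).T @ (centered / safe)
    cand = np.argwhere(np.triu(np.abs(corr) > 0.999, k=1))
    out = []
    for i, j in cand:
        a, b = calls[:, i], calls[:, j]
        joint = (a != MISSING) & (b != MISSING)
        if joint.sum() < 2:
            continue
        aa, bb = a[joint], b[joint]
        if np.array_equal(aa, bb) or np.array_equal(aa, 2 - bb):
            out.append((int(i), int(j)))
    return out


def filter_magic_panel(
    genotypes: GenotypeMatrix,
    success_min: float = 0.91,
    maf_min: float = 0.05,
    line_success_min: float = 0.75,
    gmap: GeneticMap | None = None,
    return_report: bool = False,
):
    """MAGIC-population QC, applied in order:

    1. drop lines with call rate < line_success_min;
    2. drop markers with call rate <= success_min or maf <= maf_min
       (the boundary semantics follow the printed inequalities: markers are
       kept on success rate > 0.91 and maf > 0.05);
    3. from every pair of remaining markers with perfectly correlated calls
       (identical jointly non-missing patterns up to a global allele flip)
       drop the marker later in map order (unmapped after mapped).
    """
    obs = genotypes.calls != MISSING
    line_rate = obs.sum(axis=1) / genotypes.n_markers
    keep_lines = line_rate >= line_success_min
    g = genotypes.subset(lines=[l for l, k in zip(genotypes.lines, keep_lines) if k])

    stats = marker_stats(g)
    cr = stats["call_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    ok_success = cr > success_min
    ok_maf = (~np.isnan(maf)) & (maf > maf_min)
    g2 = g.subset(markers=g.markers[ok_success & ok_maf])

    order = _map_order(g2.markers, gmap)
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    drop = set()
    for i, j in _perfect_pairs(g2.calls):
        drop.add(i if rank[i] > rank[j] else j)
    keep = [k for k in range(g2.n_markers) if k not in drop]
    out = g2.subset(markers=g2.markers[keep])

    if not return_report:
        return out
    report = QCReport(
        lines_low_call_rate=int((~keep_lines).sum()),
        markers_low_success=int((~ok_success).sum()),
        markers_low_maf=int((ok_success & ~ok_maf).sum()),
        markers_duplicate=len(drop),
        n_lines_kept=out.n_lines,
        n_markers_kept=out.n_markers,
    )
    return out, report


@dataclass
class DiversitySummary:
    """Mean expected heterozygosity and segregating-marker count of a panel."""

    mean_he: float
    n_segregating: int
    n_markers: int
    n_markers_excluded: int  # all-missing within the subset

    def __str__(self) -> str:
        return (
            f"He = {self.mean_he:.3f} over {self.n_markers} markers "
            f"({self.n_segregating} segregating, {self.n_markers_excluded} excluded)"
        )


def expected_heterozygosity(
    genotypes: GenotypeMatrix,
    line_subset: list[str] | None = None,
) -> DiversitySummary:
    """Average expected heterozygosity under random mating, He = 2p(1-p) per
    marker with p estimated from allele counts in the line subset; markers
    all-missing within the subset are excluded from the mean and counted."""
    g = genotypes if line_subset is None else genotypes.subset(lines=line_subset)
    if g.n_lines == 0:
        raise ValueError("line subset is empty")
    p, n_called = _allele1_freq(g.calls)
    usable = n_called > 0
    he = 2.0 * p * (1.0 - p)
    segregating = int(((p > 0) & (p < 1) & usable).sum())
    return DiversitySummary(
        mean_he=float(he[usable].mean()) if usable.any() else float("nan"),
        n_segregating=segregating,
        n_markers=int(usable.sum()),
        n_markers_excluded=int((~usable).sum()),
    )


@dataclass
class DiversityRatio:
    """Subset-to-reference diversity comparison."""

    he_ratio: float
    segregating_fraction: float

    @property
    def he_pct(self) -> int:
        return int(round(100.0 * self.he_ratio))

    @property
    def segregating_pct(self) -> int:
        return int(round(100.0 * self.segregating_fraction))

    def __str__(self) -> str:
        return f"He ratio {self.he_pct}%, segregating fraction {self.segregating_pct}%"


def diversity_ratio(
    subset_summary: DiversitySummary,
    reference_summary: DiversitySummary,
) -> DiversityRatio:
    """Diversity of a panel relative to a reference: He ratio and the fraction
    of the reference's segregating markers also segregating in the subset."""
    if reference_summary.mean_he <= 0 or reference_summary.n_segregating <= 0:
        raise ValueError("reference panel has no diversity; ratio undefined")
    return DiversityRatio(
        he_ratio=subset_summary.mean_he / reference_summary.mean_he,
        segregating_fraction=subset_summary.n_segregating / reference_summary.n_segregating,
    )
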