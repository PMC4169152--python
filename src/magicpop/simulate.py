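"""Forward genetic simulation of MAGIC populations.

Generates fully inbred founder genomes over a multi-chromosome centiMorgan
map, runs meiosis (Haldane map function, no interference) through the funnel
crossing scheme and single seed descent, and returns recombinant inbred line
(RIL) genotypes together with the founder-of-origin mosaic.  Also attaches a
monogenic fully penetrant recessive trait and degrades genotype calls with
missingness and error, emulating the statistical structure of array-genotyped
MAGIC data.

Alleles are coded 0/1 per marker; diploid calls count copies of allele 1
(0, 1, 2) with -1 as the distinct missing state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CrossPlan, DesignError, Pedigree

__all__ = [
    "MISSING",
    "GeneticMap",
    "FounderPanel",
    "GenotypeMatrix",
    "FounderMosaic",
    "generate_map",
    "generate_founders",
    "simulate_gamete",
    "cross",
    "self_cross",
    "simulate_magic",
    "attach_recessive_trait",
    "degrade",
    "drop_double_dwarfs",
    "wheat_chromosome_labels",
]

MISSING = np.int8(-1)


def _chrom_sort_key(label: str):
    """Natural chromosome order: 1A, 1B, 1D, 2A, ..., 7D; numeric prefix first."""
    i = 0
    while i < len(label) and label[i].isdigit():
        i += 1
    num = int(label[:i]) if i else np.inf
    return (num, label[i:], label)


def wheat_chromosome_labels() -> list[str]:
    """The 21 hexaploid wheat chromosome labels, genome order 1A..7D."""
    return [f"{n}{g}" for n in range(1, 8) for g in "ABD"]


class GeneticMap:
    """Marker -> (chromosome, cM position); defines recombination distances.

    The table is stored sorted by (chromosome, position, marker); duplicate
    positions are allowed.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "cM"}
        if not required <= set(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        t = table.copy()
        if (t["cM"] < 0).any():
            raise ValueError("cM positions must be non-negative")
        t["_key"] = t["chrom"].map(_chrom_sort_key)
        t = t.sort_values(["_key", "cM", "marker"], kind="stable").drop(columns="_key")
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["cM"].to_numpy(dtype=float)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        out = []
        chroms = self.chrom
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out

    def recomb_fractions(self) -> list[tuple[slice, np.ndarray]]:
        """Per chromosome: Haldane recombination fraction between adjacent
        markers, r = (1 - exp(-2 d / 100)) / 2 for d in cM."""
        pos = self.pos
        out = []
        for _, sl in self.chrom_slices():
            d = np.diff(pos[sl])
            out.append((sl, 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))))
        return out

    def position_of(self, marker: str) -> tuple[str, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return row.iloc[0]["chrom"], float(row.iloc[0]["cM"])


def generate_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chromosome_length_cM: float = 150.0,
    seed: int = 0,
    chrom_labels: list[str] | None = None,
) -> GeneticMap:
    """Uniform-random marker positions on each chromosome, sorted within
    chromosome.  With 21 chromosomes the wheat genome labels 1A..7D are used."""
    if n_chromosomes < 1 or markers_per_chromosome < 1 or chromosome_length_cM <= 0:
        raise ValueError("map dimensions must be positive")
    if chrom_labels is None:
        chrom_labels = (
            wheat_chromosome_labels() if n_chromosomes == 21
            else [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
        )
    rng = np.random.default_rng(seed)
    rows = []
    for c in chrom_labels[:n_chromosomes]:
        pos = np.sort(rng.uniform(0.0, chromosome_length_cM, markers_per_chromosome))
        for j, p in enumerate(pos):
            rows.append((f"{c}_m{j:04d}", c, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM"]))


@dataclass
class FounderPanel:
    """Fully inbred founders: one haplotype per founder, alleles in {0, 1}."""

    founders: list[str]
    haplotypes: np.ndarray  # (n_founders, n_markers) uint8
    markers: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (len(self.founders), len(self.markers)):
            raise ValueError("haplotype matrix shape inconsistent with ids")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("founder alleles must be 0/1")

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def diploid(self, founder: str) -> np.ndarray:
        h = self.haplotypes[self.founders.index(founder)]
        return np.stack([h, h])


def generate_founders(
    gmap: GeneticMap,
    n_founders: int = 8,
    allele_freq_spec: dict[str, float] | None = None,
    private_allele_spec: dict[str, str] | None = None,
    seed: int = 0,
    founder_ids: list[str] | None = None,
) -> FounderPanel:
    """Homozygous founder haplotypes over the map's markers.

    By default the number of founders carrying allele 1 at a marker is drawn
    from the folded neutral frequency spectrum (weight 1/k + 1/(n-k) for
    k carriers), which reproduces the skew toward rare variants seen in
    variety panels.  `allele_freq_spec` pins designated markers to an exact
    allele-1 frequency (e.g. 1/8 -> exactly one carrier); `private_allele_spec`
    pins a marker's allele 1 to exactly one designated founder.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    founders = founder_ids or [chr(ord("A") + i) for i in range(n_founders)]
    if len(founders) != n_founders:
        raise ValueError("founder_ids length mismatch")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    marker_index = {mk: i for i, mk in enumerate(gmap.markers)}

    counts = np.arange(1, n_founders)
    weights = 1.0 / counts + 1.0 / (n_founders - counts)
    weights /= weights.sum()
    k = rng.choice(counts, size=m, p=weights)

    allele_freq_spec = allele_freq_spec or {}
    private_allele_spec = private_allele_spec or {}
    for mk, freq in allele_freq_spec.items():
        if mk not in marker_index:
            raise ValueError(f"allele_freq_spec marker {mk!r} not in map")
        k[marker_index[mk]] = int(round(freq * n_founders))
    for mk, fndr in private_allele_spec.items():
        if mk not in marker_index:
            raise ValueError(f"private_allele_spec marker {mk!r} not in map")
        if fndr not in founders:
            raise ValueError(f"private_allele_spec founder {fndr!r} unknown")
        if allele_freq_spec.get(mk, 1.0 / n_founders) == 0:
            raise ValueError(f"marker {mk!r} specified both private and monomorphic")
        k[marker_index[mk]] = 1

    hap = np.zeros((n_founders, m), dtype=np.uint8)
    order = np.argsort(rng.random((m, n_founders)), axis=1)  # random founder subsets
    for j in range(m):
        hap[order[j, : k[j]], j] = 1
    for mk, fndr in private_allele_spec.items():
        j = marker_index[mk]
        hap[:, j] = 0
        hap[founders.index(fndr), j] = 1
    return FounderPanel(founders=founders, haplotypes=hap, markers=gmap.markers.copy())


@dataclass
class GenotypeMatrix:
    """Lines x markers diploid calls: copies of allele 1 (0/1/2), -1 missing."""

    calls: np.ndarray  # (n_lines, n_markers) int8
    lines: list[str]
    markers: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.markers = np.asarray(self.markers)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("call matrix shape inconsistent with ids")
        if not np.isin(self.calls, [-1, 0, 1, 2]).all():
            raise ValueError("calls must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def marker_index(self, marker: str) -> int:
        idx = np.flatnonzero(self.markers == marker)
        if idx.size == 0:
            raise KeyError(f"marker {marker!r} not in genotype matrix")
        return int(idx[0])

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines)
        mi = np.arange(self.n_markers)
        if lines is not None:
            pos = {l: i for i, l in enumerate(self.lines)}
            li = np.array([pos[l] for l in lines], dtype=int)
        if markers is not None:
            pos = {m: i for i, m in enumerate(self.markers)}
            mi = np.array([pos[m] for m in markers], dtype=int)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(li, mi)],
            lines=[self.lines[i] for i in li],
            markers=self.markers[mi],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype("float"), index=self.lines, columns=self.markers)
        return df.mask(df < 0)


@dataclass
class FounderMosaic:
    """Founder-of-origin of each haplotype at each marker of each line."""

    origins: np.ndarray  # (n_lines, n_markers, 2) int8 founder indices
    founders: list[str]
    lines: list[str]
    markers: np.ndarray

    def founder_share(self) -> pd.Series:
        """Mean genome fraction descending from each founder (over lines,
        markers and haplotypes)."""
        n = self.origins.shape[0] * self.origins.shape[1] * 2
        counts = np.bincount(self.origins.ravel(), minlength=len(self.founders))
        return pd.Series(counts / n, index=self.founders, name="share")

    def per_line_share(self) -> pd.DataFrame:
        nl, nm, _ = self.origins.shape
        out = np.zeros((nl, len(self.founders)))
        for f in range(len(self.founders)):
            out[:, f] = (self.origins == f).sum(axis=(1, 2)) / (2 * nm)
        return pd.DataFrame(out, index=self.lines, columns=self.founders)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _meiosis_choice(gmap: GeneticMap, rng: np.random.Generator, k: int) -> np.ndarray:
    """(k, n_markers) matrix of 0/1 parental-haplotype choices for k gametes.

    Independent Bernoulli crossovers between adjacent markers (Haldane),
    independent chromosomes, random starting haplotype per chromosome.
    """
    out = np.empty((k, gmap.n_markers), dtype=np.uint8)
    for sl, r in gmap.recomb_fractions():
        n = sl.stop - sl.start
        start = rng.integers(0, 2, size=(k, 1), dtype=np.uint8)
        if n > 1:
            switch = (rng.random((k, n - 1)) < r).astype(np.uint8)
            cum = np.cumsum(switch, axis=1, dtype=np.int64)
            out[:, sl.start + 1: sl.stop] = (start + cum) % 2
        out[:, sl.start] = start[:, 0]
    return out


def _gametes(hap0, hap1, gmap, rng, orig0=None, orig1=None):
    """Batched meiosis: haplotype arrays (k, m) -> gametes (k, m), optionally
    recombining origin labels with the same crossover pattern."""
    choice = _meiosis_choice(gmap, rng, hap0.shape[0])
    gam = np.where(choice == 1, hap1, hap0)
    if orig0 is None:
        return gam, None
    return gam, np.where(choice == 1, orig1, orig0)


def simulate_gamete(parent: np.ndarray, gmap: GeneticMap, seed=0) -> np.ndarray:
    """One gamete from a diploid parent given as two haplotype rows (2, m)."""
    parent = np.asarray(parent)
    if parent.shape != (2, gmap.n_markers):
        raise ValueError("parent must be (2, n_markers) haplotypes aligned to the map")
    rng = _as_rng(seed)
    gam, _ = _gametes(parent[0][None, :], parent[1][None, :], gmap, rng)
    return gam[0]


def cross(parent1: np.ndarray, parent2: np.ndarray, gmap: GeneticMap, seed=0) -> np.ndarray:
    """Offspring diploid (2, m): one gamete from each parent."""
    rng = _as_rng(seed)
    return np.stack([simulate_gamete(parent1, gmap, rng), simulate_gamete(parent2, gmap, rng)])


def self_cross(line: np.ndarray, gmap: GeneticMap, seed=0) -> np.ndarray:
    """Selfed offspring: two independent gametes from the same diploid."""
    rng = _as_rng(seed)
    return cross(line, line, gmap, rng)


def simulate_magic(
    plan: CrossPlan,
    pedigree: Pedigree,
    founders: FounderPanel,
    gmap: GeneticMap,
    seed: int = 0,
    track_mosaic: bool = True,
) -> tuple[GenotypeMatrix, FounderMosaic | None]:
    """Run the funnel (two-way -> four-way -> eight-way crosses) and SSD
    selfing per the pedigree; return terminal RIL genotypes and, optionally,
    the founder-descent mosaic.

    Meiosis is batched across individuals per crossing stage, so the cost is
    a handful of vectorised draws per generation rather than per line.
    """
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    if not np.array_equal(founders.markers, gmap.markers):
        raise DesignError("founder panel markers do not match the map")
    missing_f = set(plan.founders) - set(founders.founders)
    if missing_f:
        raise DesignError(f"founder panel lacks plan founders {sorted(missing_f)}")
    fidx = {f: i for i, f in enumerate(founders.founders)}
    ew_by_id = {ew.id: ew for ew in plan.eightways}

    recs = pedigree.records
    f1_recs = recs[recs["generation"] == "F1"]
    families = f1_recs["family_id"].drop_duplicates().tolist()
    unknown = set(families) - set(ew_by_id)
    if unknown:
        raise DesignError(f"pedigree references unknown crosses: {sorted(unknown)[:3]}")

    def founder_hap(f):
        return founders.haplotypes[fidx[f]]

    def founder_orig(f):
        return np.full(m, fidx[f], dtype=np.int8)

    # Two-way F1s are genetically uniform (inbred x inbred): one diploid each.
    twoway_dip = {}
    for fam in families:
        for fw in ew_by_id[fam].fourway_pair:
            for tw in fw.f1_pair:
                if tw.id not in twoway_dip:
                    p, q = tw.parents
                    twoway_dip[tw.id] = (
                        founder_hap(p), founder_hap(q),
                        founder_orig(p), founder_orig(q),
                    )

    # One four-way plant per (family, side): cross the two two-way F1s.
    def batch_cross(parent_pairs):
        """parent_pairs: list of ((h0,h1,o0,o1) mother, (...) father) ->
        offspring hap0, hap1, orig0, orig1 arrays of shape (k, m)."""
        k = len(parent_pairs)
        h = [np.empty((k, m), np.uint8) for _ in range(4)]
        o = [np.empty((k, m), np.int8) for _ in range(4)]
        for i, (mo, fa) in enumerate(parent_pairs):
            h[0][i], h[1][i], o[0][i], o[1][i] = mo[0], mo[1], mo[2], mo[3]
            h[2][i], h[3][i], o[2][i], o[3][i] = fa[0], fa[1], fa[2], fa[3]
        g0, go0 = _gametes(h[0], h[1], gmap, rng, o[0], o[1])
        g1, go1 = _gametes(h[2], h[3], gmap, rng, o[2], o[3])
        return g0, g1, go0, go1

    fourway_pairs = []
    fourway_key = []
    for fam in families:
        for side, fw in enumerate(ew_by_id[fam].fourway_pair):
            a, b = fw.f1_pair
            fourway_pairs.append((twoway_dip[a.id], twoway_dip[b.id]))
            fourway_key.append((fam, side))
    fw_h0, fw_h1, fw_o0, fw_o1 = batch_cross(fourway_pairs)
    fw_plant = {key: i for i, key in enumerate(fourway_key)}

    # Eight-way F1 plants: cross the family's two four-way plants.
    f1_ids = f1_recs["line_id"].tolist()
    f1_fam = f1_recs["family_id"].tolist()
    k1 = len(f1_ids)
    idx_a = np.array([fw_plant[(fam, 0)] for fam in f1_fam])
    idx_b = np.array([fw_plant[(fam, 1)] for fam in f1_fam])
    g0, go0 = _gametes(fw_h0[idx_a], fw_h1[idx_a], gmap, rng, fw_o0[idx_a], fw_o1[idx_a])
    g1, go1 = _gametes(fw_h0[idx_b], fw_h1[idx_b], gmap, rng, fw_o0[idx_b], fw_o1[idx_b])
    plant_pos = {lid: i for i, lid in enumerate(f1_ids)}

    # SSD: advance every RIL chain one generation at a time, batched.
    ssd = pedigree.ssd_generations
    if ssd == 0:
        term_ids = f1_ids
        cur = (g0, g1, go0, go1)
    else:
        gen2 = recs[recs["generation"] == "F2"]
        parents = [plant_pos[p] for p in gen2["parent_id"]]
        chain_ids = gen2["line_id"].tolist()
        cur = (g0[parents], g1[parents], go0[parents], go1[parents])
        order = {lid: i for i, lid in enumerate(chain_ids)}
        for g in range(2, 2 + ssd):
            h0, h1, o0, o1 = cur
            a0, ao0 = _gametes(h0, h1, gmap, rng, o0, o1)
            a1, ao1 = _gametes(h0, h1, gmap, rng, o0, o1)
            cur = (a0, a1, ao0, ao1)
            if g < 1 + ssd:
                nxt = recs[recs["generation"] == f"F{g + 1}"]
                perm = [order[p] for p in nxt["parent_id"]]
                cur = tuple(arr[perm] for arr in cur)
                order = {lid: i for i, lid in enumerate(nxt["line_id"])}
        term_ids = recs.loc[recs["generation"] == f"F{1 + ssd}", "line_id"].tolist()
        perm = [order[lid] for lid in term_ids]
        cur = tuple(arr[perm] for arr in cur)

    h0, h1, o0, o1 = cur
    calls = (h0.astype(np.int8) + h1.astype(np.int8))
    geno = GenotypeMatrix(calls=calls, lines=term_ids, markers=gmap.markers.copy())
    mosaic = None
    if track_mosaic:
        mosaic = FounderMosaic(
            origins=np.stack([o0, o1], axis=2),
            founders=list(founders.founders),
            lines=term_ids,
            markers=gmap.markers.copy(),
        )
    return geno, mosaic


def attach_recessive_trait(
    genotypes: GenotypeMatrix,
    causal_marker: str,
    carrier_allele: int = 1,
) -> pd.Series:
    """Fully penetrant monogenic recessive phenotype: 1 iff homozygous for the
    designated allele, 0 otherwise, NaN where the genotype is missing."""
    j = genotypes.marker_index(causal_marker)
    calls = genotypes.calls[:, j]
    target = 2 if carrier_allele == 1 else 0
    pheno = np.where(calls == target, 1.0, 0.0)
    pheno[calls == MISSING] = np.nan
    present = calls[calls != MISSING]
    if present.size and (np.all(present == present[0])):
        warnings.warn(f"causal marker {causal_marker!r} is monomorphic", stacklevel=2)
    return pd.Series(pheno, index=genotypes.lines, name="phenotype")


def degrade(
    genotypes: GenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Independently set calls missing at `missing_rate`, then flip surviving
    calls to a uniformly random *other* state at `error_rate`."""
    if not (0 <= missing_rate <= 1 and 0 <= error_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = genotypes.calls.copy()
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if error_rate > 0:
        hit = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
        # other state = current + 1 or 2 (mod 3), uniformly
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls[hit] = (calls[hit] + shift[hit]) % 3
    return GenotypeMatrix(calls=calls, lines=list(genotypes.lines), markers=genotypes.markers.copy())


def drop_double_dwarfs(
    genotypes: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    dwarf_allele: int = 1,
) -> GenotypeMatrix:
    """Optional culling mirroring field practice: remove lines homozygous for
    the dwarfing allele at both designated height loci.  Off by default in
    every pipeline; provided as an explicit post-processing step."""
    target = 2 if dwarf_allele == 1 else 0
    ja, jb = genotypes.marker_index(locus_a), genotypes.marker_index(locus_b)
    keep = ~((genotypes.calls[:, ja] == target) & (genotypes.calls[:, jb] == target))
    return GenotypeMatrix(
        calls=genotypes.calls[keep],
        lines=[l for l, k in zip(genotypes.lines, keep) if k],
        markers=genotypes.markers.copy(),
    )
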