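"""Pedigree-aware single-marker association scan for MAGIC populations.

The model follows the strategy used for funnel-structured populations: line
phenotype means are regressed on marker dosage with random intercepts for the
pedigree strata — between funnels (eight-way families) and between outcrossed
plants within funnels.  Variance components are estimated once on the null
(no-marker) model by REML (statsmodels MixedLM); each marker is then tested
on GLS-whitened data with a 1-df likelihood-ratio statistic, which makes a
genome scan of thousands of markers a single vectorised pass.  If the
variance-component fit fails (or the strata carry no replication) the scan
falls back to strata as fixed effects with an F-test, flagged in the
metadata.

Also provides the Bonferroni threshold on the -log10 scale, peak support
intervals from map-adjacent flanking markers, diagnostic-marker concordance
tables, and rescans with the peak marker as a covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Pedigree
from .simulate import GeneticMap, GenotypeMatrix

__all__ = [
    "StrataDesign",
    "AssociationScan",
    "ScanResult",
    "bonferroni_threshold",
    "significant_markers",
    "support_interval",
    "SupportInterval",
    "concordance_table",
    "ConcordanceTable",
    "covariate_rescan",
]

_MIN_LINES = 30


def _chi2_1_logsf(x: np.ndarray) -> np.ndarray:
    """log sf of chi-square(1) via the exact identity sf(x) = 2 Phi(-sqrt(x));
    norm.logsf stays finite far beyond where chi2.logsf underflows."""
    return np.log(2.0) + stats.norm.logsf(np.sqrt(np.asarray(x, dtype=float)))


def _f_1_logsf(x: np.ndarray, d: int) -> np.ndarray:
    """log sf of F(1, d), with the leading-order incomplete-beta asymptote
    where scipy's logsf underflows to -inf."""
    from scipy.special import betaln

    x = np.asarray(x, dtype=float)
    v = stats.f.logsf(x, 1, d)
    bad = ~np.isfinite(v) & np.isfinite(x)
    if np.any(bad):
        a = d / 2.0
        z = d / (d + x[bad])
        v[bad] = a * np.log(z) - np.log(a) - betaln(a, 0.5)
    return v


@dataclass
class StrataDesign:
    """Per-line pedigree strata: funnel id and outcrossed-plant-within-funnel id."""

    table: pd.DataFrame  # index = line_id, columns funnel, f1_plant

    def __post_init__(self):
        need = {"funnel", "f1_plant"}
        if not need <= set(self.table.columns):
            raise ValueError(f"strata table needs columns {sorted(need)}")

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree) -> "StrataDesign":
        return cls(pedigree.strata())

    def aligned(self, lines: list[str]) -> pd.DataFrame:
        missing = [l for l in lines if l not in self.table.index]
        if missing:
            raise ValueError(f"{len(missing)} lines lack strata (e.g. {missing[:3]})")
        return self.table.loc[lines]


def _group_codes(values) -> np.ndarray:
    return pd.factorize(np.asarray(values))[0]


class AssociationScan:
    """Single-marker association model for a genotyped, phenotyped population.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        QC-passed diploid calls; missing dosages are mean-imputed per marker
        for testing.
    phenotype : pd.Series
        Line phenotype (binary traits are analysed on the linear scale, as for
        line means).  Lines with missing phenotype are dropped.
    strata : StrataDesign or None
        Funnel / plant-within-funnel assignment; None fits an unstructured
        (ordinary least squares) scan.
    covariate_markers : list of marker ids, optional
        Markers entered as fixed covariates; they are excluded from testing.
    gmap : GeneticMap, optional
        Annotates results with chromosome and cM.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotype: pd.Series,
        strata: StrataDesign | None = None,
        covariate_markers: list[str] | None = None,
        gmap: GeneticMap | None = None,
    ):
        lines = [l for l in genotypes.lines if l in phenotype.index and np.isfinite(phenotype[l])]
        if strata is not None:
            lines = [l for l in lines if l in strata.table.index]
        if len(lines) < _MIN_LINES:
            raise ValueError(f"need at least {_MIN_LINES} phenotyped lines, got {len(lines)}")
        self.genotypes = genotypes.subset(lines=lines)
        self.phenotype = phenotype.loc[lines].astype(float)
        self.strata = strata
        self.covariate_markers = list(covariate_markers or [])
        self.gmap = gmap
        self.lines = lines

    # -- variance components ------------------------------------------------

    def _estimate_vc(self, y, funnel, plant):
        """REML variance components (funnel, plant-within-funnel, residual)
        from the null model.  Returns (sigma2_funnel, sigma2_plant,
        sigma2_resid, note)."""
        import statsmodels.formula.api as smf

        funnel_sizes = np.bincount(_group_codes(funnel))
        plant_codes = _group_codes(plant)
        plant_sizes = np.bincount(plant_codes)
        if (funnel_sizes <= 1).all():
            return None, None, float(np.var(y, ddof=1)), "no funnel replication; OLS"
        df = pd.DataFrame({"y": y, "funnel": funnel, "f1_plant": plant})
        use_plant = (plant_sizes > 1).any() and len(plant_sizes) > len(funnel_sizes)
        kwargs = dict(groups="funnel", re_formula="1")
        if use_plant:
            kwargs["vc_formula"] = {"plant": "0 + C(f1_plant)"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ 1", df, **kwargs)
            res = model.fit(reml=True, method=["bfgs", "powell"])
        if not np.isfinite(res.scale) or res.scale <= 0:
            raise RuntimeError("variance-component fit did not converge")
        s2_f = float(res.cov_re.iloc[0, 0])
        s2_p = float(res.vcomp[0]) if use_plant else 0.0
        note = "lmm" if use_plant else "lmm (within-funnel stratum unreplicated, dropped)"
        return s2_f, s2_p, float(res.scale), note

    def _whiten(self, mats, funnel, plant, s2_f, s2_p, s2_e):
        """Left-multiply each matrix by L^-1 where V = L L' is the strata
        covariance, block-diagonal by funnel."""
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        funnel = np.asarray(funnel)
        plant = np.asarray(plant)
        order = np.argsort(funnel, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        out = [np.asarray(m, dtype=float)[order] for m in mats]
        fo, po = funnel[order], plant[order]
        start = 0
        n = len(funnel)
        for i in range(1, n + 1):
            if i == n or fo[i] != fo[start]:
                b = i - start
                v = np.full((b, b), s2_f) + np.diag(np.full(b, s2_e))
                if s2_p > 0:
                    same = (po[start:i, None] == po[None, start:i])
                    v += s2_p * same
                else:
                    pass
                L = np.linalg.cholesky(v)
                for m in out:
                    m[start:i] = solve_triangular(L, m[start:i], lower=True)
                start = i
        return [m[inv] for m in out]

    # -- fitting -------------------------------------------------------------

    def fit(self, method: str = "auto") -> "ScanResult":
        """Run the scan.

        method: 'auto' (mixed model, falling back to fixed strata on
        failure), 'lmm', 'fixed' (strata as fixed effects, F-test) or 'ols'
        (no strata; for calibration comparisons).
        """
        y = self.phenotype.to_numpy()
        n = len(y)
        test_markers = [m for m in self.genotypes.markers if m not in self.covariate_markers]
        dose = self.genotypes.dosage()
        col = {m: i for i, m in enumerate(self.genotypes.markers)}
        # mean-impute missing dosages per marker
        mu = np.nanmean(dose, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        filled = np.where(np.isnan(dose), mu[None, :], dose)
        G = filled[:, [col[m] for m in test_markers]]
        covs = filled[:, [col[m] for m in self.covariate_markers]] if self.covariate_markers else None

        info: dict = {
            "n_lines": n,
            "n_markers": len(test_markers),
            "covariates": list(self.covariate_markers),
        }
        flags = np.full(len(test_markers), "", dtype=object)

        use = method
        if method in ("auto", "lmm") and self.strata is None:
            use = "ols"
        strata_df = self.strata.aligned(self.lines) if self.strata is not None else None

        if use in ("auto", "lmm"):
            funnel = strata_df["funnel"].to_numpy()
            plant = strata_df["f1_plant"].to_numpy()
            try:
                s2_f, s2_p, s2_e, note = self._estimate_vc(y, funnel, plant)
                if s2_f is None:
                    use = "ols"
                    info["model"] = "ols (no strata replication)"
                else:
                    info.update(model=note, sigma2_funnel=s2_f, sigma2_plant=s2_p,
                                sigma2_resid=s2_e)
                    mats = [y[:, None], np.ones((n, 1)), G]
                    if covs is not None:
                        mats.insert(2, covs)
                    wh = self._whiten(mats, funnel, plant, s2_f, s2_p, s2_e)
                    yw = wh[0][:, 0]
                    Xw = np.hstack(wh[1:-1])
                    Gw = wh[-1]
                    table = self._lrt_pass(yw, Xw, Gw, n, flags)
                    return self._result(test_markers, table, flags, info)
            except Exception as exc:  # fit failure -> documented fallback
                if method == "lmm":
                    raise
                info["lmm_failure"] = str(exc)
                use = "fixed"

        if use == "fixed":
            funnel = strata_df["funnel"].to_numpy()
            plant = strata_df["f1_plant"].to_numpy()
            plant_codes = _group_codes(plant)
            group = plant_codes if (np.bincount(plant_codes) > 1).any() else _group_codes(funnel)
            k_groups = int(group.max()) + 1
            info["model"] = "fixed-strata F-test"
            # within-group demeaning absorbs funnel and plant intercepts
            def demean(a):
                a = np.asarray(a, dtype=float)
                sums = np.zeros((k_groups,) + a.shape[1:])
                np.add.at(sums, group, a)
                cnt = np.bincount(group, minlength=k_groups).astype(float)
                return a - (sums.T / cnt).T[group]

            yd = demean(y[:, None])[:, 0]
            Gd = demean(G)
            Xd = demean(covs) if covs is not None else None
            dof = n - k_groups - (covs.shape[1] if covs is not None else 0) - 1
            table = self._ftest_pass(yd, Xd, Gd, dof, flags)
            return self._result(test_markers, table, flags, info)

        # plain OLS
        info.setdefault("model", "ols")
        X = np.ones((n, 1))
        if covs is not None:
            X = np.hstack([X, covs])
        table = self._lrt_pass(y, X, G, n, flags)
        return self._result(test_markers, table, flags, info)

    @staticmethod
    def _residualize(y, X, G):
        q, _ = np.linalg.qr(X)
        return y - q @ (q.T @ y), G - q @ (q.T @ G), X.shape[1]

    def _lrt_pass(self, y, X, G, n, flags):
        ry, rG, _ = self._residualize(y, X, G)
        rss0 = float(ry @ ry)
        gg = (rG * rG).sum(axis=0)
        gy = rG.T @ ry
        tol = 1e-12 * max(rss0, 1.0)
        if rss0 <= 1e-12:
            flags[:] = "constant-phenotype"
            return np.zeros(len(gg)), np.zeros(len(gg))  # p = 1 everywhere
        ok = gg > tol
        beta = np.zeros(len(gg))
        logp = np.full(len(gg), np.nan)
        beta[ok] = gy[ok] / gg[ok]
        rss1 = np.clip(rss0 - gy[ok] ** 2 / gg[ok], 1e-300, None)
        lrt = n * np.log(rss0 / rss1)
        # log survival function keeps full resolution for extreme peaks
        logp[ok] = -_chi2_1_logsf(lrt) / np.log(10.0)
        flags[~ok] = "monomorphic"
        return beta, logp

    def _ftest_pass(self, y, X, G, dof, flags):
        if X is not None:
            ry, rG, _ = self._residualize(y, X, G)
        else:
            ry, rG = y, G
        rss0 = float(ry @ ry)
        gg = (rG * rG).sum(axis=0)
        gy = rG.T @ ry
        if rss0 <= 1e-12:
            flags[:] = "constant-phenotype"
            return np.zeros(len(gg)), np.zeros(len(gg))
        ok = gg > 1e-12 * max(rss0, 1.0)
        beta = np.zeros(len(gg))
        logp = np.full(len(gg), np.nan)
        beta[ok] = gy[ok] / gg[ok]
        rss1 = np.clip(rss0 - gy[ok] ** 2 / gg[ok], 1e-300, None)
        fstat = (rss0 - rss1) / (rss1 / max(dof, 1))
        logp[ok] = -_f_1_logsf(fstat, max(dof, 1)) / np.log(10.0)
        flags[~ok] = "monomorphic"
        return beta, logp

    def _result(self, markers, table, flags, info) -> "ScanResult":
        beta, logp = table
        chrom = [None] * len(markers)
        cM = [np.nan] * len(markers)
        if self.gmap is not None:
            lookup = dict(zip(self.gmap.markers, zip(self.gmap.chrom, self.gmap.pos)))
            for i, m in enumerate(markers):
                if m in lookup:
                    chrom[i], cM[i] = lookup[m]
        df = pd.DataFrame(
            {
                "marker": markers,
                "chrom": chrom,
                "cM": cM,
                "effect": beta,
                "minus_log10_p": logp,
                "flag": flags,
            }
        )
        return ScanResult(table=df, model_info=info)


@dataclass
class ScanResult:
    """Per-marker association statistics with scan metadata."""

    table: pd.DataFrame
    model_info: dict = field(default_factory=dict)

    def peak(self) -> str:
        """Marker with the largest -log10 p; ties broken by map order (table
        order follows the map when one was supplied)."""
        s = self.table["minus_log10_p"]
        if s.isna().all():
            raise ValueError("no defined tests in scan")
        return str(self.table.loc[s.idxmax(), "marker"])

    def significant(self, threshold: float) -> list[str]:
        return significant_markers(self, threshold)

    def summary(self, top: int = 10) -> str:
        info = self.model_info
        lines = [
            "Single-marker association scan",
            f"  model: {info.get('model', '?')}   lines: {info.get('n_lines')}   "
            f"markers: {info.get('n_markers')}",
        ]
        if "sigma2_funnel" in info:
            lines.append(
                f"  variance components: funnel {info['sigma2_funnel']:.4g}, "
                f"plant {info['sigma2_plant']:.4g}, residual {info['sigma2_resid']:.4g}"
            )
        if info.get("covariates"):
            lines.append(f"  fixed covariate markers: {', '.join(info['covariates'])}")
        shown = self.table.sort_values("minus_log10_p", ascending=False).head(top)
        lines.append(shown.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Multiple-testing threshold on the -log10 p scale: -log10(alpha / m)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def significant_markers(scan: ScanResult, threshold: float) -> list[str]:
    """Markers with -log10 p strictly above the threshold, strongest first."""
    t = scan.table
    hits = t[t["minus_log10_p"] > threshold].sort_values("minus_log10_p", ascending=False)
    return hits["marker"].tolist()


@dataclass
class SupportInterval:
    """QTL support interval spanned by the map-adjacent flanking markers."""

    left_cM: float | None
    right_cM: float | None
    width_cM: float
    chrom: str
    flag: str  # two-sided | one-sided | undefined

    def __str__(self) -> str:
        return f"{self.chrom}: [{self.left_cM}, {self.right_cM}] width {self.width_cM} cM ({self.flag})"


def support_interval(gmap: GeneticMap, peak_marker: str) -> SupportInterval:
    """Interval between the mapped markers immediately flanking the peak in
    map order; one-sided (flagged) when the peak is at a chromosome end."""
    chrom, pos = gmap.position_of(peak_marker)
    sel = gmap.table[gmap.table["chrom"] == chrom].reset_index(drop=True)
    idx = int(sel.index[sel["marker"] == peak_marker][0])
    left = float(sel.iloc[idx - 1]["cM"]) if idx > 0 else None
    right = float(sel.iloc[idx + 1]["cM"]) if idx < len(sel) - 1 else None
    if left is None and right is None:
        return SupportInterval(None, None, float("nan"), chrom, "undefined")
    if left is None or right is None:
        bound = pos
        lo = left if left is not None else bound
        hi = right if right is not None else bound
        return SupportInterval(left, right, hi - lo, chrom, "one-sided")
    return SupportInterval(left, right, right - left, chrom, "two-sided")


@dataclass
class ConcordanceTable:
    """Phenotype-class by genotype-class counts for a diagnostic marker."""

    counts: pd.DataFrame  # rows: observed phenotype class, cols: genotype class
    rule: dict
    discordant: int
    n_classified: int
    n_excluded: int

    @property
    def discordant_pct(self) -> float:
        return 100.0 * self.discordant / self.n_classified

    def __str__(self) -> str:
        return (
            f"{self.counts.to_string()}\n"
            f"discordant: {self.discordant} of {self.n_classified} "
            f"({self.discordant_pct:.1f}%), excluded: {self.n_excluded}"
        )


def concordance_table(
    calls,
    phenotype,
    rule: dict[int, int],
) -> ConcordanceTable:
    """Cross-tabulate observed phenotype against genotype classes at one
    marker and count lines discordant with the diagnostic rule.

    `rule` maps each genotype class (0/1/2 copies of allele 1) to a predicted
    phenotype (0/1).  Lines with a missing genotype or phenotype are excluded
    and counted separately.
    """
    calls = np.asarray(pd.Series(calls), dtype=float)
    phen = np.asarray(pd.Series(phenotype), dtype=float)
    if calls.shape != phen.shape:
        raise ValueError("calls and phenotype must align")
    ok = np.isfinite(calls) & (calls >= 0) & np.isfinite(phen)
    g, y = calls[ok].astype(int), phen[ok].astype(int)
    missing_rule = sorted(set(g) - set(rule))
    if missing_rule:
        raise ValueError(f"diagnostic rule lacks genotype classes {missing_rule}")
    counts = pd.DataFrame(
        0, index=pd.Index([0, 1], name="phenotype"), columns=pd.Index([0, 1, 2], name="genotype")
    )
    for gi, yi in zip(g, y):
        counts.loc[yi, gi] += 1
    predicted = np.array([rule[gi] for gi in g])
    discordant = int((predicted != y).sum())
    return ConcordanceTable(
        counts=counts,
        rule=dict(rule),
        discordant=discordant,
        n_classified=int(ok.sum()),
        n_excluded=int((~ok).sum()),
    )


def covariate_rescan(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    strata: StrataDesign | None,
    peak_marker: str,
    gmap: GeneticMap | None = None,
    method: str = "auto",
) -> ScanResult:
    """Rescan with the peak marker as a fixed covariate; the peak itself is
    excluded from testing."""
    genotypes.marker_index(peak_marker)  # raises if absent
    model = AssociationScan(
        genotypes,
        phenotype,
        strata=strata,
        covariate_markers=[peak_marker],
        gmap=gmap,
    )
    return model.fit(method=method)
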