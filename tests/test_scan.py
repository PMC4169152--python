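"""Association scan: thresholds, intervals, concordance, covariate rescans,
and calibration of the strata-aware model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicpop import scan as msc
from magicpop.simulate import GeneticMap, GenotypeMatrix


def test_bonferroni_threshold_values():
    assert round(msc.bonferroni_threshold(0.01, 8920), 2) == 5.95
    assert round(msc.bonferroni_threshold(0.01, 1621), 2) == 5.21
    assert round(msc.bonferroni_threshold(0.05, 1), 2) == 1.30
    # closed form to 1e-12 before rounding
    assert msc.bonferroni_threshold(0.01, 8920) == pytest.approx(
        np.log10(8920) - np.log10(0.01), abs=1e-12)
    with pytest.raises(ValueError):
        msc.bonferroni_threshold(1.5, 10)
    with pytest.raises(ValueError):
        msc.bonferroni_threshold(0.05, 0)


def test_significant_markers_filtering():
    table = pd.DataFrame({
        "marker": ["a", "b", "c", "d"],
        "chrom": "1A", "cM": [1.0, 2.0, 3.0, 4.0],
        "effect": 0.0,
        "minus_log10_p": [7.2, 3.0, np.nan, 9.1],
        "flag": ["", "", "monomorphic", ""],
    })
    res = msc.ScanResult(table=table)
    assert msc.significant_markers(res, 5.0) == ["d", "a"]  # descending
    assert msc.significant_markers(res, 99.0) == []
    assert res.peak() == "d"


def _map(rows):
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM"]))


def test_support_interval_flanking_markers():
    gmap = _map([
        ("left", "5A", 139.76), ("peak", "5A", 140.59),
        ("mid", "5A", 141.7), ("right", "5A", 147.26),
    ])
    # flanking = map-adjacent markers; for the paper-like layout the interval
    # is bounded by the immediate neighbours
    si = msc.support_interval(gmap, "peak")
    assert si.left_cM == pytest.approx(139.76) and si.right_cM == pytest.approx(141.7)
    si2 = msc.support_interval(_map([("l", "1A", 139.76), ("p", "1A", 140.59),
                                     ("r", "1A", 147.26)]), "p")
    assert si2.width_cM == pytest.approx(7.5)
    tight = msc.support_interval(_map([("l", "2B", 9.0), ("p", "2B", 10.0),
                                       ("r", "2B", 11.0)]), "p")
    assert tight.width_cM == pytest.approx(2.0)
    lone = msc.support_interval(_map([("p", "3D", 50.0)]), "p")
    assert lone.flag == "undefined" and np.isnan(lone.width_cM)
    edge = msc.support_interval(_map([("p", "4A", 0.0), ("r", "4A", 3.0)]), "p")
    assert edge.flag == "one-sided" and edge.width_cM == pytest.approx(3.0)


def test_concordance_printed_table():
    """Diagnostic-marker table: 625/3/15 absence and 8/2/57 presence by
    genotype class; homozygous-alt predicts presence."""
    calls = np.concatenate([
        np.repeat([0, 1, 2], [625, 3, 15]),
        np.repeat([0, 1, 2], [8, 2, 57]),
    ])
    phen = np.concatenate([np.zeros(643), np.ones(67)])
    t = msc.concordance_table(calls, phen, {0: 0, 1: 0, 2: 1})
    assert t.discordant == 25
    assert t.n_classified == 710
    assert round(t.discordant_pct, 1) == 3.5
    assert t.counts.loc[0].tolist() == [625, 3, 15]
    assert t.counts.loc[1].tolist() == [8, 2, 57]


def test_concordance_edge_cases():
    perfect = msc.concordance_table([0, 0, 2, 2], [0, 0, 1, 1], {0: 0, 1: 0, 2: 1})
    assert perfect.discordant == 0
    t = msc.concordance_table([0, 2, np.nan, -1, 0], [0, 1, 1, 0, np.nan],
                              {0: 0, 1: 0, 2: 1})
    assert t.n_classified == 2 and t.n_excluded == 3
    toy = msc.concordance_table([0, 0, 0, 2, 2, 2, 1, 1, 0, 2],
                                [0, 0, 1, 1, 1, 0, 0, 1, 0, 1],
                                {0: 0, 1: 0, 2: 1})
    assert toy.discordant == 3  # hand count: one 0->1, one 2->0, one 1->1


def test_scan_recovers_causal_locus(small_population):
    pop = small_population
    res = msc.AssociationScan(pop["genotypes"], pop["phenotype"],
                              strata=pop["strata"], gmap=pop["map"]).fit()
    assert res.peak() == pop["causal"]
    assert "lmm" in res.model_info["model"]
    thr = msc.bonferroni_threshold(0.01, res.model_info["n_markers"])
    assert pop["causal"] in msc.significant_markers(res, thr)
    logp = res.table["minus_log10_p"]
    assert (logp.dropna() >= 0).all() and np.isfinite(logp.dropna()).all()
    assert "lmm" in res.summary()


def test_scan_constant_phenotype_nonsignificant(small_population):
    pop = small_population
    const = pop["phenotype"] * 0.0
    res = msc.AssociationScan(pop["genotypes"], const, strata=pop["strata"]).fit()
    assert (res.table["minus_log10_p"] == 0.0).all()  # p = 1 everywhere
    assert (res.table["flag"] == "constant-phenotype").all()


def test_scan_requires_minimum_lines(small_population):
    pop = small_population
    tiny = pop["phenotype"].iloc[:10]
    with pytest.raises(ValueError, match="at least"):
        msc.AssociationScan(pop["genotypes"], tiny, strata=pop["strata"])


def test_covariate_rescan_removes_signal(small_population):
    pop = small_population
    res = msc.covariate_rescan(pop["genotypes"], pop["phenotype"], pop["strata"],
                               pop["causal"], gmap=pop["map"])
    assert pop["causal"] not in set(res.table["marker"])
    thr = msc.bonferroni_threshold(0.01, res.model_info["n_markers"])
    assert msc.significant_markers(res, thr) == []


def test_orthogonal_covariate_leaves_scan_unchanged(small_population):
    """Conditioning on a marker unlinked to the trait barely perturbs the
    scan: rank correlation of -log10 p > 0.95."""
    pop = small_population
    gmap = pop["map"]
    # covariate from the last chromosome, causal is on the third
    cov = gmap.markers[-5]
    base = msc.AssociationScan(pop["genotypes"], pop["phenotype"],
                               strata=pop["strata"], gmap=gmap).fit()
    resc = msc.covariate_rescan(pop["genotypes"], pop["phenotype"], pop["strata"],
                                cov, gmap=gmap)
    merged = base.table.merge(resc.table, on="marker", suffixes=("_0", "_1"))
    ok = merged[["minus_log10_p_0", "minus_log10_p_1"]].dropna()
    rho = stats.spearmanr(ok["minus_log10_p_0"], ok["minus_log10_p_1"]).statistic
    assert rho > 0.95


def test_strata_model_calibrated_under_funnel_confounding(full_plan):
    """With a pure funnel effect (no marker effect), the strata-aware scan
    holds its size while a naive no-strata scan inflates.  Large families
    (10 RILs each) make the confounding visible."""
    from magicpop import design as dz
    from magicpop import simulate as msim

    plan = full_plan
    fams = [ew.id for ew in plan.eightways[:40]]
    ped = dz.build_pedigree(plan, dz.allocate_rils(fams, 400), ssd_generations=6)
    gmap = msim.generate_map(3, 30, 120.0, seed=31)
    panel = msim.generate_founders(gmap, 8, seed=32)
    geno, _ = msim.simulate_magic(plan, ped, panel, gmap, seed=33, track_mosaic=False)
    strata = msc.StrataDesign.from_pedigree(ped)
    spaced = list(gmap.markers[::3])  # ~12 cM apart: near-independent tests
    sub = geno.subset(markers=spaced)
    strata_tab = strata.aligned(sub.lines)
    rng = np.random.default_rng(99)
    rejections = {"lmm": [], "ols": []}
    for rep in range(5):
        funnels = strata_tab["funnel"].unique()
        eff = pd.Series(rng.normal(0, 2.0, len(funnels)), index=funnels)
        y = pd.Series(
            eff[strata_tab["funnel"]].to_numpy() + rng.normal(0, 1.0, len(sub.lines)),
            index=sub.lines,
        )
        for method in ("lmm", "ols"):
            res = msc.AssociationScan(sub, y, strata=strata).fit(method=method)
            p = 10.0 ** (-res.table["minus_log10_p"].dropna())
            rejections[method].extend((p < 0.05).tolist())
    n = len(rejections["lmm"])
    ci = 2 * np.sqrt(0.05 * 0.95 / n)
    assert abs(np.mean(rejections["lmm"]) - 0.05) < ci + 0.02
    assert np.mean(rejections["ols"]) > 0.05 + ci + 0.02  # visibly inflated
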