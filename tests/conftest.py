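"""Shared fixtures: a desk-scale simulated MAGIC population reused across the
QC, LD and scan tests.  All randomness is seeded; fixtures are session-scoped
so the forward simulation runs once."""

import numpy as np
import pytest

from magicpop import design as dz
from magicpop import scan as msc
from magicpop import simulate as ms


@pytest.fixture(scope="session")
def full_plan():
    """Replicated eight-founder design: every four-way used exactly twice."""
    fourways = dz.enumerate_four_way(8)
    eightways = dz.enumerate_eight_way(fourways)
    return dz.select_replicated_eight_ways(eightways, per_fourway_usage=2, seed=1)


@pytest.fixture(scope="session")
def small_population(full_plan):
    """420 F7 RILs (2 per eight-way family), 5 chromosomes x 30 markers of
    120 cM, one marker private to founder H carrying a recessive trait."""
    alloc = dz.allocate_rils([ew.id for ew in full_plan.eightways], 420)
    ped = dz.build_pedigree(full_plan, alloc, ssd_generations=6)
    gmap = ms.generate_map(5, 30, 120.0, seed=11)
    causal = gmap.markers[75]  # mid third chromosome
    panel = ms.generate_founders(gmap, 8, private_allele_spec={causal: "H"}, seed=12)
    geno, mosaic = ms.simulate_magic(full_plan, ped, panel, gmap, seed=13)
    pheno = ms.attach_recessive_trait(geno, causal)
    return {
        "plan": full_plan,
        "pedigree": ped,
        "map": gmap,
        "founders": panel,
        "genotypes": geno,
        "mosaic": mosaic,
        "phenotype": pheno,
        "causal": causal,
        "strata": msc.StrataDesign.from_pedigree(ped),
    }
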