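"""Segregation expectations for a monogenic recessive trait under selfing.

Starting from a random-mated base at Hardy-Weinberg proportions (which the
replicated funnel approximates at the eight-way F1 stage), t generations of
selfing halve heterozygosity each generation and split the lost heterozygotes
equally between the homozygous classes.  The recessive phenotypic class
frequency is therefore

    f(q, t) = q^2 + q(1 - q)(1 - 2^-t)

for recessive allele frequency q, running from q^2 (t = 0) to q (fully
inbred).  Goodness of fit of observed two-class counts uses a Pearson
chi-square with 1 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SegregationModel",
    "SegregationObservation",
    "GofResult",
    "recessive_class_freq",
    "expected_ratio",
    "observed_ratio",
    "gof_chisq",
]


@dataclass(frozen=True)
class SegregationModel:
    """Recessive allele frequency q and number of selfing generations t."""

    q: float
    t: float  # integer >= 0; math.inf allowed for the fully inbred limit

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.t < 0 or (math.isfinite(self.t) and self.t != int(self.t)):
            raise ValueError("t must be a non-negative integer (or inf)")


@dataclass(frozen=True)
class SegregationObservation:
    """Observed dominant-class and recessive-class counts."""

    dominant: int
    recessive: int

    def __post_init__(self):
        if self.dominant < 0 or self.recessive < 0 or self.dominant + self.recessive == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return self.dominant + self.recessive


def recessive_class_freq(model: SegregationModel) -> float:
    """Expected recessive-phenotype frequency q^2 + q(1-q)(1 - 2^-t)."""
    q, t = model.q, model.t
    decay = 0.0 if math.isinf(t) else 2.0 ** (-t)
    return q * q + q * (1.0 - q) * (1.0 - decay)


def expected_ratio(model: SegregationModel) -> float:
    """Expected dominant:recessive ratio (1-f)/f; display rounded to 2 dp,
    the unrounded value is returned."""
    f = recessive_class_freq(model)
    if f <= 0.0 or f >= 1.0:
        raise ValueError("recessive class frequency outside (0, 1); ratio undefined")
    return (1.0 - f) / f


def observed_ratio(obs: SegregationObservation) -> float:
    """Observed dominant:recessive ratio."""
    if obs.recessive == 0:
        raise ZeroDivisionError("no recessive-class observations; ratio infinite")
    return obs.dominant / obs.recessive


@dataclass(frozen=True)
class GofResult:
    chisq: float
    p_value: float
    df: int
    expected_dominant: float
    expected_recessive: float
    low_expected_warning: bool

    def __str__(self) -> str:
        return f"chi-square({self.df}) = {self.chisq:.2f}, p = {self.p_value:.2f}"


def gof_chisq(obs: SegregationObservation, model: SegregationModel) -> GofResult:
    """Pearson chi-square (1 df) of observed counts against the model's
    expected two-class split."""
    f = recessive_class_freq(model)
    n = obs.total
    exp = (n * (1.0 - f), n * f)
    chisq, p = stats.chisquare([obs.dominant, obs.recessive], f_exp=exp)
    return GofResult(
        chisq=float(chisq),
        p_value=float(p),
        df=1,
        expected_dominant=exp[0],
        expected_recessive=exp[1],
        low_expected_warning=min(exp) < 5.0,
    )
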