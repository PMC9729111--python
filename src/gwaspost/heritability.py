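"""Liability-scale heritability explained by independent risk variants.

A binary disease with population risk K is modeled as a standard normal
liability exceeding the threshold t = Phi^-1(1 - K). A variant's
per-allele log-odds effect is mapped to the liability scale through the
density at the threshold,

    beta_liab = beta_logodds * K (1 - K) / phi(t),

the first-order equivalence between the logistic and probit-liability
models at risk K (no case-control ascertainment correction: effects are
assumed to come from population-scale or ascertainment-adjusted
log-odds). The liability variance of a variant with effect-allele
frequency p is then 2 p (1 - p) beta_liab^2, additive over conditionally
independent variants, and is reported as a percentage of an assumed twin
heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gwaspost.simulate import InputError


@dataclass(frozen=True)
class LiabilityModel:
    """Liability-threshold model parameters."""

    K: float = 0.0719
    h2_twin: float = 0.4

    def __post_init__(self):
        if not (0.0 < self.K < 1.0):
            raise InputError("K must lie in (0, 1)")
        if not (0.0 < self.h2_twin <= 1.0):
            raise InputError("h2_twin must lie in (0, 1]")

    @property
    def threshold(self) -> float:
        """Upper-K quantile of the standard normal."""
        return float(stats.norm.isf(self.K))

    @property
    def z_density(self) -> float:
        """Standard normal density at the threshold."""
        return float(stats.norm.pdf(self.threshold))


def liability_beta(beta: float, model: LiabilityModel) -> float:
    """Per-allele effect on the liability scale from a log-odds effect."""
    return beta * model.K * (1.0 - model.K) / model.z_density


def logodds_beta(beta_liab: float, model: LiabilityModel) -> float:
    """Inverse of :func:`liability_beta` (used by generators/oracles)."""
    return beta_liab * model.z_density / (model.K * (1.0 - model.K))


def variant_liability_variance(beta, eaf, model: LiabilityModel):
    """Liability variance contributed by one variant: 2p(1-p) beta_liab^2."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise InputError("eaf must lie in (0, 1)")
    b_l = beta * model.K * (1.0 - model.K) / model.z_density
    out = 2.0 * eaf * (1.0 - eaf) * b_l**2
    return float(out) if out.ndim == 0 else out


def percent_heritability_explained(betas, eafs, model: LiabilityModel) -> float:
    """Summed liability variance as a percentage of twin heritability.

    ``betas`` should be conditionally independent (joint) effects;
    marginal effects over-count in LD. A result above 100 is returned as
    computed, with a warning, since it signals model misspecification
    rather than a computational error.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size == 0:
        return 0.0
    total = float(np.sum(variant_liability_variance(betas, eafs, model)))
    pct = 100.0 * total / model.h2_twin
    if pct > 100.0:
        warnings.warn(
            f"explained heritability {pct:.1f}% exceeds 100%: "
            "check independence of the variant set or model parameters",
            stacklevel=2,
        )
    return pct
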