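"""Functionally informed fine-mapping.

Per-variant approximate Bayes factors are combined across regions under a
one-causal-variant-per-region model whose prior is tilted by a binary
tissue annotation. The annotation (enrichment) coefficient gamma is
estimated by maximizing the marginal likelihood across regions; regions
with a strong gain in evidence under the annotation model are selected and
fine-mapped to annotation-reweighted posterior probabilities and 95%
credible sets. All evidence arithmetic is in log space.

Region-level marginal likelihood ratio (vs. no causal variant anywhere):

    LR_r(g0, g) = (1 + sum_v exp(g0 + g a_v) ABF_v)
                  / (1 + sum_v exp(g0 + g a_v))

where g0 is a per-variant log prior odds intercept and a_v the annotation.
The denominator normalizes the configuration prior (null plus one-causal
configurations); with g = 0 the model reduces exactly to the null model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from gwaspost.simulate import InputError

DEFAULT_PRIOR_SD = 0.2  # effect-size prior sd on the log-odds scale (W = 0.04)


class NonIdentifiableError(ValueError):
    """Annotation carries no information (constant across variants)."""


@dataclass
class Region:
    """A fine-mapping region: variants with effects and annotations."""

    region_id: str
    chrom: str
    rsids: list
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    annotations: dict = field(default_factory=dict)  # tissue -> 0/1 array

    def __post_init__(self):
        if len(self.rsids) == 0:
            raise InputError(f"region {self.region_id} has no variants")
        for tissue, a in self.annotations.items():
            if len(a) != len(self.rsids):
                raise InputError(
                    f"annotation {tissue} length mismatch in {self.region_id}"
                )

    def has_gws(self, threshold: float = 5e-8) -> bool:
        return bool(np.min(self.p) <= threshold)


@dataclass
class EnrichmentFit:
    tissue: str
    gamma: float
    gamma_ci: tuple
    gamma0: float
    log_bf_null: np.ndarray      # per-region log marginal LR, gamma = 0
    log_bf_model: np.ndarray     # per-region log marginal LR at gamma-hat
    increment: np.ndarray        # model minus null, per region
    loglik_null: float
    loglik_model: float
    region_ids: list = field(default_factory=list)


@dataclass
class CredibleSet:
    region_id: str
    tissue: str | None
    rsids: list          # PPA-descending order
    ppa: np.ndarray      # same order
    cumulative: np.ndarray
    level: float
    size: int

    @property
    def members(self) -> list:
        return self.rsids[: self.size]


def log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor (association vs. null) for one variant.

    ABF = sqrt(V / (V + W)) * exp(z^2 W / (2 (V + W))) with V = se^2,
    W = prior_sd^2 and z = beta / se, evaluated in log space.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("se must be positive")
    if prior_sd <= 0:
        raise InputError("prior sd must be positive")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2 * (V + W))


def _region_loglr(labf: np.ndarray, a: np.ndarray, g0: float, g: float) -> float:
    prior = g0 + g * a
    num = special.logsumexp(np.concatenate([[0.0], prior + labf]))
    den = special.logsumexp(np.concatenate([[0.0], prior]))
    return float(num - den)


def _pad_regions(arrays: list) -> np.ndarray:
    """Stack ragged per-region vectors into a -inf padded matrix with a
    leading zero column for the null configuration."""
    n = len(arrays)
    width = max(len(a) for a in arrays)
    out = np.full((n, width + 1), -np.inf)
    out[:, 0] = 0.0
    for i, a in enumerate(arrays):
        out[i, 1 : len(a) + 1] = a
    return out


def _padded_loglr(
    labf_pad: np.ndarray, a_pad: np.ndarray, g0: float, g: float
) -> np.ndarray:
    # padding is -inf in labf_pad and 0 in a_pad, so padded entries stay -inf
    prior = g0 + g * a_pad
    prior[:, 0] = 0.0
    with np.errstate(invalid="ignore"):
        num = special.logsumexp(prior + labf_pad, axis=1)
    num[np.isnan(num)] = -np.inf
    mask = np.isfinite(labf_pad)
    mask[:, 0] = True
    den = special.logsumexp(np.where(mask, prior, -np.inf), axis=1)
    return num - den


def _total_loglik(regions_labf, regions_a, g0: float, g: float) -> float:
    return sum(
        _region_loglr(labf, a, g0, g)
        for labf, a in zip(regions_labf, regions_a)
    )


def fit_enrichment(
    regions: list[Region],
    tissue: str,
    prior_sd: float = DEFAULT_PRIOR_SD,
    ci_level: float = 0.95,
) -> EnrichmentFit:
    """Estimate the annotation enrichment coefficient for one tissue.

    Maximizes the product over regions of the marginal likelihood ratio
    (see module docstring) jointly over the intercept g0 and the
    annotation coefficient gamma; the null model fixes gamma = 0. The
    gamma CI comes from the profile likelihood at the chi-square(1)
    cutoff. Raises NonIdentifiableError when the annotation is constant
    across all variants.
    """
    labfs = [log_abf(r.beta, r.se, prior_sd) for r in regions]
    annots = []
    for r in regions:
        if tissue not in r.annotations:
            raise InputError(f"region {r.region_id} lacks annotation {tissue}")
        annots.append(np.asarray(r.annotations[tissue], dtype=float))
    flat = np.concatenate(annots)
    if np.all(flat == 0) or np.all(flat == 1):
        raise NonIdentifiableError(
            f"annotation {tissue} is constant; enrichment not identifiable"
        )

    labf_pad = _pad_regions(labfs)
    a_pad = _pad_regions(annots)
    a_pad[~np.isfinite(a_pad)] = 0.0  # padding neutral in the prior term

    def nll(theta):
        return -float(np.sum(_padded_loglr(labf_pad, a_pad, theta[0], theta[1])))

    def nll_null(theta):
        return -float(np.sum(_padded_loglr(labf_pad, a_pad, theta[0], 0.0)))

    # bounded search keeps a flat likelihood (weak data) from drifting to
    # arbitrary extremes; the bounds are far outside any plausible fold
    box = (-12.0, 12.0)
    res0 = optimize.minimize(
        nll_null, x0=[0.0], method="Nelder-Mead", bounds=[box]
    )
    res = optimize.minimize(
        nll, x0=[float(res0.x[0]), 0.0], method="Nelder-Mead", bounds=[box, box],
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000},
    )
    g0_null = float(res0.x[0])
    g0_hat, g_hat = float(res.x[0]), float(res.x[1])
    ll_model, ll_null = -float(res.fun), -float(res0.fun)

    # profile-likelihood CI for gamma
    cut = stats.chi2.ppf(ci_level, df=1) / 2.0

    def profile(g):
        r = optimize.minimize_scalar(
            lambda g0: -float(np.sum(_padded_loglr(labf_pad, a_pad, g0, g))),
            bounds=(g0_hat - 10, g0_hat + 10),
            method="bounded",
        )
        return -float(r.fun)

    def deficit(g):
        return ll_model - profile(g) - cut

    def side(direction: float) -> float:
        step, g = 0.5, g_hat
        while abs(g) < 20.0:
            g = g + direction * step
            if deficit(g) > 0:
                lo, hi = sorted([g - direction * step, g])
                return float(optimize.brentq(deficit, lo, hi, xtol=1e-4))
            step *= 1.6
        return direction * math.inf

    ci = (side(-1.0), side(+1.0))

    lbf_null = _padded_loglr(labf_pad, a_pad, g0_null, 0.0)
    lbf_model = _padded_loglr(labf_pad, a_pad, g0_hat, g_hat)
    return EnrichmentFit(
        tissue=tissue,
        gamma=g_hat,
        gamma_ci=ci,
        gamma0=g0_hat,
        log_bf_null=lbf_null,
        log_bf_model=lbf_model,
        increment=lbf_model - lbf_null,
        loglik_null=ll_null,
        loglik_model=ll_model,
        region_ids=[r.region_id for r in regions],
    )


def select_enriched_regions(
    regions: list[Region],
    fits: dict[str, EnrichmentFit],
    increment_sd: float = 3.0,
    gws_threshold: float = 5e-8,
    mode: str = "region_sd",
) -> pd.DataFrame:
    """Select strongly enriched regions and their best tissue.

    Default mode ("region_sd"): a region qualifies for a tissue when its
    log-BF increment exceeds mean + ``increment_sd`` * sd of that tissue's
    increments across all regions. Alternative mode ("gamma_sd"): a tissue
    qualifies globally when gamma-hat exceeds ``increment_sd`` times its
    profile-likelihood standard error, and a region qualifies with any
    positive increment in such a tissue. Either way the region must also
    contain a genome-wide significant variant; the selected tissue is the
    argmax increment (ties break by tissue order in ``fits``).
    """
    tissues = list(fits)
    rows = []
    thr = {}
    for t in tissues:
        inc = fits[t].increment
        if mode == "region_sd":
            thr[t] = float(np.mean(inc) + increment_sd * np.std(inc))
        elif mode == "gamma_sd":
            lo, hi = fits[t].gamma_ci
            se = (hi - lo) / (2 * 1.96) if np.isfinite(hi - lo) else math.inf
            thr[t] = 0.0 if abs(fits[t].gamma) > increment_sd * se else math.inf
        else:
            raise InputError(f"unknown selection mode {mode!r}")

    for i, region in enumerate(regions):
        incs = {t: float(fits[t].increment[i]) for t in tissues}
        qualifying = [t for t in tissues if incs[t] > thr[t]]
        selected = bool(qualifying) and region.has_gws(gws_threshold)
        best = max(tissues, key=lambda t: (incs[t], -tissues.index(t)))
        rows.append(
            {
                "REGION_ID": region.region_id,
                "SELECTED": selected,
                "TISSUE": best if selected else None,
                "INCREMENT": incs[best],
                "HAS_GWS": region.has_gws(gws_threshold),
            }
        )
    return pd.DataFrame(rows)


def reweighted_ppa(
    region: Region,
    gamma: float,
    tissue: str | None,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray:
    """Posterior probability of association under the one-causal model.

    PPA(v) = pi(v) ABF(v) / sum_u pi(u) ABF(u) with
    pi(v) proportional to exp(gamma * a(v)); gamma = 0 or a missing tissue
    gives the flat prior (PPA proportional to ABF). Normalization happens
    in log space so underflowing ABFs never produce 0/0.
    """
    labf = log_abf(region.beta, region.se, prior_sd)
    if tissue is None or gamma == 0.0:
        logw = labf
    else:
        a = np.asarray(region.annotations[tissue], dtype=float)
        logw = gamma * a + labf
    return np.exp(logw - special.logsumexp(logw))


def credible_set(
    ppa: np.ndarray,
    level: float = 0.95,
    region_id: str = "",
    rsids: list | None = None,
    tissue: str | None = None,
) -> CredibleSet:
    """Minimal PPA-ranked prefix with cumulative mass >= ``level``.

    Variants tied (to within 1e-12) with the boundary variant are all
    included. PPAs must sum to 1 within 1e-8.
    """
    if not (0.0 < level < 1.0):
        raise InputError("credible level must lie in (0, 1)")
    ppa = np.asarray(ppa, dtype=float)
    if abs(ppa.sum() - 1.0) > 1e-8:
        raise InputError(f"PPAs sum to {ppa.sum():.10f}, expected 1")
    if rsids is None:
        rsids = [f"v{i}" for i in range(len(ppa))]

    order = np.argsort(-ppa, kind="stable")
    ranked = ppa[order]
    cum = np.cumsum(ranked)
    size = int(np.searchsorted(cum, level - 1e-12) + 1)
    # If the prefix overshoots the level, the boundary variant's inclusion
    # over an equal-PPA variant would be arbitrary: include the whole tie.
    if cum[size - 1] > level + 1e-12:
        while size < len(ranked) and abs(ranked[size] - ranked[size - 1]) <= 1e-12:
            size += 1
    return CredibleSet(
        region_id=region_id,
        tissue=tissue,
        rsids=[rsids[i] for i in order],
        ppa=ranked,
        cumulative=cum,
        level=level,
        size=size,
    )


def build_regions(
    meta: pd.DataFrame,
    loci,
    annotations: dict[str, np.ndarray] | None = None,
    rsid_index: dict | None = None,
    window_bp: int = 500_000,
) -> list[Region]:
    """Expand clumped loci to +/- ``window_bp`` windows, merge overlaps and
    collect each window's variants from the meta table into Regions.

    ``annotations`` maps tissue -> per-variant binary vector aligned with
    ``rsid_index`` (rsid -> position in the vector).
    """
    windows: dict[str, list] = {}
    for locus in loci:
        windows.setdefault(locus.chrom, []).append(
            [locus.start - window_bp, locus.end + window_bp]
        )
    regions = []
    count = 0
    for chrom in sorted(windows):
        merged: list[list] = []
        for start, end in sorted(windows[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        for start, end in merged:
            sub = meta[
                (meta["CHR"].astype(str) == chrom)
                & (meta["POS"] >= start)
                & (meta["POS"] <= end)
            ]
            if len(sub) == 0:
                continue
            count += 1
            annot = {}
            if annotations is not None and rsid_index is not None:
                idx = [rsid_index[r] for r in sub["RSID"]]
                annot = {
                    t: np.asarray(vec)[idx] for t, vec in annotations.items()
                }
            regions.append(
                Region(
                    region_id=f"region{count:03d}",
                    chrom=chrom,
                    rsids=sub["RSID"].tolist(),
                    beta=sub["BETA"].to_numpy(float),
                    se=sub["SE"].to_numpy(float),
                    p=sub["P"].to_numpy(float),
                    annotations=annot,
                )
            )
    return regions
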