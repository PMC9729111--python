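"""Fixed-effect meta-analysis, locus definition and related summary operations.

Implements inverse-variance pooling with log-space p-values, allele
alignment across tables, contributing-study/case-count filters, 500-kb
transitive locus clumping, novelty annotation against previously reported
variants via an LD reference, Storey q-values, between-sex heterogeneity
tests and cross-ancestry effect/frequency correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from gwaspost.simulate import InputError, LDPanel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GWS_THRESHOLD = 5e-8
CLUMP_WINDOW_BP = 500_000
NOVELTY_R2 = 0.2


class AlignmentError(ValueError):
    """Allele sets cannot be reconciled between two records."""


@dataclass
class VariantAssociation:
    """One variant's summary statistics in one study or meta-analysis."""

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    non_effect_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n_cases: int = 0
    n_controls: int = 0
    info: float = 1.0

    def __post_init__(self):
        if self.se <= 0:
            raise InputError(f"{self.rsid}: se must be positive")
        if not (0.0 < self.eaf < 1.0):
            raise InputError(f"{self.rsid}: eaf must lie in (0, 1)")
        if not (0.0 < self.p <= 1.0):
            raise InputError(f"{self.rsid}: p must lie in (0, 1]")
        if self.effect_allele == self.non_effect_allele:
            raise InputError(f"{self.rsid}: alleles must differ")

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.non_effect_allele


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate for one variant."""

    beta: float
    se: float
    z: float
    p: float
    log10_p: float
    n_studies: int
    n_cases: int = 0


@dataclass
class Locus:
    """A clumped genomic region of genome-wide significant variants."""

    chrom: str
    start: int
    end: int
    sentinel: str
    sentinel_pos: int
    sentinel_p: float
    members: list = field(default_factory=list)
    novelty: str | None = None  # "new" | "known" | "unassessed"
    nearest_gene: str | None = None


def two_sided_p(z: float | np.ndarray) -> tuple:
    """Two-sided normal tail probability computed in log space.

    Returns (p, log10_p). p never collapses to exactly 0: for extreme |z|
    it saturates at the smallest subnormal float while log10_p stays exact.
    """
    z = np.abs(np.asarray(z, dtype=float))
    logp = stats.norm.logsf(z) + math.log(2.0)
    log10p = logp / math.log(10.0)
    p = np.maximum(np.exp(logp), 5e-324)
    if p.ndim == 0:
        return float(p), float(log10p)
    return p, log10p


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_alleles(
    a: VariantAssociation,
    b: VariantAssociation,
    palindromic_policy: str = "maf_drop",
    palindromic_maf: float = 0.4,
    allow_strand_flip: bool = True,
) -> tuple[VariantAssociation, VariantAssociation]:
    """Harmonize ``b`` onto the effect allele of ``a``.

    When b's alleles are swapped relative to a, its beta sign is flipped
    and its frequency complemented. Strand-complement matches are resolved
    when ``allow_strand_flip``. Palindromic (A/T, C/G) variants are
    ambiguous under strand uncertainty: under the default policy they are
    dropped (AlignmentError) when the minor allele frequency exceeds
    ``palindromic_maf``, otherwise aligned by frequency.
    """
    if (a.chrom, a.pos) != (b.chrom, b.pos):
        raise AlignmentError(f"{a.rsid}/{b.rsid}: different sites")

    if a.is_palindromic() or b.is_palindromic():
        if palindromic_policy == "drop":
            raise AlignmentError(f"{a.rsid}: palindromic variant dropped")
        if palindromic_policy == "maf_drop":
            maf = min(b.eaf, 1 - b.eaf)
            if maf > palindromic_maf:
                raise AlignmentError(
                    f"{a.rsid}: palindromic with MAF {maf:.3f} > "
                    f"{palindromic_maf} dropped"
                )
            # align by frequency: both tables should agree on which allele
            # is minor
            same_side = (a.eaf < 0.5) == (b.eaf < 0.5)
            if a.effect_allele in (b.effect_allele, _COMPLEMENT[b.effect_allele]):
                flipped = not same_side
            else:
                flipped = same_side
            return a, _flip(b, a) if flipped else _relabel(b, a)
        if palindromic_policy != "keep":
            raise InputError(f"unknown palindromic policy {palindromic_policy!r}")

    if b.effect_allele == a.effect_allele and b.non_effect_allele == a.non_effect_allele:
        return a, b
    if b.effect_allele == a.non_effect_allele and b.non_effect_allele == a.effect_allele:
        return a, _flip(b, a)
    if allow_strand_flip:
        bc_ea = _COMPLEMENT.get(b.effect_allele)
        bc_nea = _COMPLEMENT.get(b.non_effect_allele)
        if bc_ea == a.effect_allele and bc_nea == a.non_effect_allele:
            return a, _relabel(b, a)
        if bc_ea == a.non_effect_allele and bc_nea == a.effect_allele:
            return a, _flip(b, a)
    raise AlignmentError(
        f"{a.rsid}: incompatible alleles "
        f"{a.effect_allele}/{a.non_effect_allele} vs "
        f"{b.effect_allele}/{b.non_effect_allele}"
    )


def _relabel(b: VariantAssociation, a: VariantAssociation) -> VariantAssociation:
    out = VariantAssociation(**{**b.__dict__})
    out.effect_allele = a.effect_allele
    out.non_effect_allele = a.non_effect_allele
    return out


def _flip(b: VariantAssociation, a: VariantAssociation) -> VariantAssociation:
    out = _relabel(b, a)
    out.beta = -b.beta
    out.eaf = 1.0 - b.eaf
    return out


# ---------------------------------------------------------------------------
# Inverse-variance weighting
# ---------------------------------------------------------------------------

def ivw_meta(studies: Sequence[VariantAssociation]) -> MetaResult:
    """Fixed-effect inverse-variance weighted pooling of one variant.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2 and
    se = sum(w_i)^(-1/2). The two-sided p is computed in log space so it
    degrades gracefully for extreme Z scores.
    """
    if len(studies) == 0:
        raise InputError("ivw_meta needs at least one study")
    betas = np.array([s.beta for s in studies])
    ses = np.array([s.se for s in studies])
    if np.any(ses <= 0):
        raise InputError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p, log10p = two_sided_p(z)
    return MetaResult(
        beta=beta,
        se=se,
        z=float(z),
        p=p,
        log10_p=log10p,
        n_studies=len(studies),
        n_cases=int(sum(s.n_cases for s in studies)),
    )


def _align_tables(base: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align ``other`` onto ``base``'s effect alleles by chrom/pos.

    Vectorized strict/swapped matching; rows with incompatible alleles are
    dropped. Returns ``other`` re-expressed on base alleles, indexed like
    the merge of the two tables.
    """
    m = base.merge(other, on=["CHR", "POS"], suffixes=("", "_o"))
    same = (m["EA"] == m["EA_o"]) & (m["NEA"] == m["NEA_o"])
    swap = (m["EA"] == m["NEA_o"]) & (m["NEA"] == m["EA_o"])
    m = m[same | swap].copy()
    flip = (m["EA"] == m["NEA_o"]).to_numpy()
    m.loc[flip, "BETA_o"] *= -1.0
    m.loc[flip, "EAF_o"] = 1.0 - m.loc[flip, "EAF_o"]
    return m


def ivw_meta_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyze per-study summary tables variant-by-variant.

    Variants are keyed by CHR:POS; effect alleles are aligned to the first
    table that carries each variant. Output columns: CHR, POS, RSID, EA,
    NEA, EAF (weight-averaged), BETA, SE, Z, P, LOG10_P, N_STUDIES,
    N_CASES, N_CONTROLS.
    """
    if not tables:
        raise InputError("no study tables supplied")
    acc: dict = {}
    for df in tables:
        for row in df.itertuples(index=False):
            key = (row.CHR, row.POS)
            rec = acc.get(key)
            if rec is None:
                acc[key] = {
                    "CHR": row.CHR, "POS": row.POS, "RSID": row.RSID,
                    "EA": row.EA, "NEA": row.NEA,
                    "w": [], "wb": [], "weaf": [],
                    "n_cases": 0, "n_controls": 0, "n_studies": 0,
                }
                rec = acc[key]
            beta, eaf = row.BETA, row.EAF
            if row.EA == rec["NEA"] and row.NEA == rec["EA"]:
                beta, eaf = -beta, 1.0 - eaf
            elif not (row.EA == rec["EA"] and row.NEA == rec["NEA"]):
                continue  # incompatible alleles: skip this study's record
            w = 1.0 / row.SE**2
            rec["w"].append(w)
            rec["wb"].append(w * beta)
            rec["weaf"].append(w * eaf)
            rec["n_cases"] += int(row.N_CASES)
            rec["n_controls"] += int(row.N_CONTROLS)
            rec["n_studies"] += 1

    rows = []
    for rec in acc.values():
        sw = sum(rec["w"])
        beta = sum(rec["wb"]) / sw
        se = sw**-0.5
        z = beta / se
        p, log10p = two_sided_p(z)
        rows.append(
            {
                "CHR": rec["CHR"], "POS": rec["POS"], "RSID": rec["RSID"],
                "EA": rec["EA"], "NEA": rec["NEA"],
                "EAF": sum(rec["weaf"]) / sw,
                "BETA": beta, "SE": se, "Z": z, "P": p, "LOG10_P": log10p,
                "N_STUDIES": rec["n_studies"],
                "N_CASES": rec["n_cases"], "N_CONTROLS": rec["n_controls"],
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["CHR", "POS"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Filters, clumping, novelty
# ---------------------------------------------------------------------------

def filter_variants(
    meta: pd.DataFrame, min_studies: int = 2, min_cases: int = 30_000
) -> pd.DataFrame:
    """Drop variants in fewer than ``min_studies`` studies or with fewer
    than ``min_cases`` total cases."""
    keep = (meta["N_STUDIES"] >= min_studies) & (meta["N_CASES"] >= min_cases)
    return meta[keep].reset_index(drop=True)


def clump_loci(
    significant: pd.DataFrame, window_bp: int = CLUMP_WINDOW_BP
) -> list[Locus]:
    """Single-linkage clumping of significant variants into loci.

    Any two variants within ``window_bp`` on the same chromosome share a
    locus (transitively). The sentinel is the minimum-p member; ties break
    to the lowest position.
    """
    loci: list[Locus] = []
    if len(significant) == 0:
        return loci
    df = significant.sort_values(["CHR", "POS"], kind="stable")
    for chrom, sub in df.groupby("CHR", sort=True):
        pos = sub["POS"].to_numpy()
        breaks = np.where(np.diff(pos) > window_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            grp = sub.iloc[s : e + 1]
            best = grp.sort_values(["P", "POS"], kind="stable").iloc[0]
            loci.append(
                Locus(
                    chrom=str(chrom),
                    start=int(grp["POS"].min()),
                    end=int(grp["POS"].max()),
                    sentinel=str(best["RSID"]),
                    sentinel_pos=int(best["POS"]),
                    sentinel_p=float(best["P"]),
                    members=grp["RSID"].tolist(),
                )
            )
    return loci


def annotate_novelty(
    locus: Locus,
    known: pd.DataFrame,
    panel: LDPanel,
    r2_threshold: float = NOVELTY_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> Locus:
    """Flag a locus as known or new against previously reported variants.

    Known if a reported variant lies inside the locus region, or if the
    sentinel has r^2 >= ``r2_threshold`` with a reported variant in the LD
    panel (r^2 exactly at the threshold counts as known, since "new" is
    strictly below it). If the r^2 check is needed but the sentinel is not
    in the panel, the locus is flagged "unassessed" rather than silently
    "new". ``known`` has columns RSID, CHR, POS.
    """
    near = known[
        (known["CHR"].astype(str) == locus.chrom)
        & (known["POS"] >= locus.start - window_bp)
        & (known["POS"] <= locus.end + window_bp)
    ]
    inside = near[(near["POS"] >= locus.start) & (near["POS"] <= locus.end)]
    if len(inside) > 0:
        locus.novelty = "known"
        return locus
    candidates = [r for r in near["RSID"] if r in panel]
    if not candidates:
        locus.novelty = "new"
        return locus
    if locus.sentinel not in panel:
        locus.novelty = "unassessed"
        return locus
    max_r2 = max(panel.r2(locus.sentinel, r) for r in candidates)
    locus.novelty = "known" if max_r2 >= r2_threshold - 1e-12 else "new"
    return locus


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    threshold: float  # largest p with q <= target


def qvalue_fdr(
    pvalues: Iterable[float],
    target: float = 0.01,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> QValueResult:
    """Storey q-values with a smoothed pi0 estimate.

    pi0 is estimated on the grid ``lambdas`` (default 0.05..0.95) by a
    cubic smoothing spline evaluated at the largest lambda, clipped to
    (0, 1]. Forcing ``pi0=1`` reproduces Benjamini-Hochberg step-up
    values exactly. The reported threshold is the largest p-value whose
    q-value is at or below ``target`` (0 if none qualifies).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InputError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size

    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        counts = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        if m < 100 or np.allclose(counts, counts[0]):
            pi0 = float(min(1.0, counts.mean()))
        else:
            spline = UnivariateSpline(lambdas, counts, k=3)
            pi0 = float(spline(lambdas[-1]))
        pi0 = float(min(1.0, max(pi0, 1.0 / m)))

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked

    passing = ranked[q_ranked <= target]
    threshold = float(passing.max()) if passing.size else 0.0
    return QValueResult(qvalues=q, pi0=pi0, threshold=threshold)


# ---------------------------------------------------------------------------
# Sex heterogeneity
# ---------------------------------------------------------------------------

def sex_heterogeneity(
    beta_m: float, se_m: float, beta_f: float, se_f: float
) -> tuple[float, float]:
    """Between-sex heterogeneity Z and two-sided p for one variant."""
    if se_m <= 0 or se_f <= 0:
        raise InputError("standard errors must be positive")
    z = (beta_m - beta_f) / math.sqrt(se_m**2 + se_f**2)
    p, _ = two_sided_p(z)
    return float(z), float(p)


def flag_sex_heterogeneity(
    beta_m, se_m, p_m, beta_f, se_f, p_f,
    gws: float = GWS_THRESHOLD,
    het_p: float = 0.01,
) -> pd.DataFrame:
    """Vectorized screen: genome-wide significant in either stratum and
    heterogeneity p at or below ``het_p``."""
    beta_m, se_m = np.asarray(beta_m, float), np.asarray(se_m, float)
    beta_f, se_f = np.asarray(beta_f, float), np.asarray(se_f, float)
    if np.any(se_m <= 0) or np.any(se_f <= 0):
        raise InputError("standard errors must be positive")
    z = (beta_m - beta_f) / np.sqrt(se_m**2 + se_f**2)
    p, _ = two_sided_p(z)
    p = np.atleast_1d(p)
    flagged = (
        (np.minimum(np.asarray(p_m, float), np.asarray(p_f, float)) <= gws)
        & (p <= het_p)
    )
    return pd.DataFrame({"HET_Z": np.atleast_1d(z), "HET_P": p, "FLAG": flagged})


# ---------------------------------------------------------------------------
# Cross-ancestry comparison
# ---------------------------------------------------------------------------

@dataclass
class CrossAncestryResult:
    r_beta: float
    r_eaf: float
    n: int
    r_beta_no_outliers: float | None = None
    n_excluded: int = 0


def cross_ancestry_compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    sentinels: Sequence[str],
    exclude: Sequence[str] = (),
) -> CrossAncestryResult:
    """Pearson correlations of allele-aligned betas and frequencies at
    shared sentinel variants, optionally recomputed after excluding
    caller-specified outliers."""
    a = table_a[table_a["RSID"].isin(sentinels)]
    b = table_b[["CHR", "POS", "EA", "NEA", "EAF", "BETA"]]
    m = _align_tables(a, b)
    if len(m) < 3:
        raise InputError(
            f"only {len(m)} overlapping sentinel variants; need at least 3"
        )
    r_beta = float(stats.pearsonr(m["BETA"], m["BETA_o"]).statistic)
    r_eaf = float(stats.pearsonr(m["EAF"], m["EAF_o"]).statistic)
    r_excl = None
    n_excl = 0
    if len(exclude) > 0:
        kept = m[~m["RSID"].isin(exclude)]
        n_excl = len(m) - len(kept)
        if len(kept) >= 3:
            r_excl = float(stats.pearsonr(kept["BETA"], kept["BETA_o"]).statistic)
    return CrossAncestryResult(
        r_beta=r_beta, r_eaf=r_eaf, n=len(m),
        r_beta_no_outliers=r_excl, n_excluded=n_excl,
    )
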