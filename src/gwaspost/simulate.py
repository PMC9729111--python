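"""Synthetic input generator for the post-GWAS pipeline.

Every downstream module consumes inputs produced here, so the generator
implements the exact statistical structure the analyses assume:

* block-diagonal AR(1) LD with allele frequencies on [0.01, 0.5];
* per-study case-control summary statistics whose marginal effects are the
  LD projection of sparse joint (causal) effects, with correlated noise at
  the scale implied by the effective sample size;
* binary annotation tracks enriched (on the odds scale) around causal
  variants in one target tissue;
* a second ancestry whose causal effects correlate with the first at a
  configured level;
* locus x gene x predictor evidence matrices generated under a
  "one true causal gene per locus" model with per-predictor
  sensitivity/specificity;
* a prospective cohort with dosages, covariates and time-to-event outcomes
  driven by the polygenic score.

All randomness flows from one seed through named sub-streams, so calling
operations in a different order cannot change any single output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Fixed predictor order for evidence matrices (column order is part of the
# file contract).
PREDICTORS = (
    "clinvar_monogenic",
    "drug_or_mr",
    "pops_top2",
    "eqtl_highld",
    "mouse_ko",
    "protein_altering_highld",
    "rare_variant_assoc",
    "nearest_gene",
)

# Named sub-streams: each operation draws from rng(seed, stream) so module
# call order does not perturb results.
_STREAMS = {
    "panel": 11,
    "truth": 13,
    "stats": 17,
    "stats_eas": 19,
    "annotations": 23,
    "evidence": 29,
    "cohort": 31,
}

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


class InputError(ValueError):
    """Invalid user-supplied configuration or data."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one synthetic dataset.

    The seed fully determines every generated artifact.
    """

    seed: int = 0
    n_variants: int = 1000
    n_blocks: int = 50
    block_rho: float = 0.5
    n_causal: int = 20
    causal_beta_sd: float = 0.05
    n_studies: int = 3
    per_study_cases: int = 30000
    per_study_controls: int = 90000
    baseline_risk: float = 0.0719
    annotation_enrichment: float = 5.0
    annotation_coverage: float = 0.10
    n_tissues: int = 10
    cross_ancestry_r: float = 0.6
    predictor_sensitivity: tuple = (0.8,) * 8
    predictor_specificity: tuple = (0.95,) * 8
    cohort_n: int = 20000
    cohort_loghr_per_sd: float = float(np.log(1.6))
    followup_years: float = 5.0

    def __post_init__(self):
        if self.n_variants <= 0:
            raise InputError("n_variants must be positive")
        if self.n_blocks < 1:
            raise InputError("n_blocks must be >= 1")
        if not (0.0 <= self.block_rho < 1.0):
            raise InputError("block_rho must lie in [0, 1)")
        if not (0 <= self.n_causal <= self.n_variants):
            raise InputError("n_causal must lie in [0, n_variants]")
        if not (0.0 < self.baseline_risk < 1.0):
            raise InputError("baseline_risk must lie in (0, 1)")
        if self.annotation_enrichment < 1.0:
            raise InputError("annotation_enrichment fold must be >= 1")
        if not (0.0 <= self.annotation_coverage < 1.0):
            raise InputError("annotation_coverage must lie in [0, 1)")
        if not (-1.0 <= self.cross_ancestry_r <= 1.0):
            raise InputError("cross_ancestry_r must lie in [-1, 1]")
        for name in ("predictor_sensitivity", "predictor_specificity"):
            vec = getattr(self, name)
            if len(vec) != len(PREDICTORS):
                raise InputError(f"{name} must have {len(PREDICTORS)} entries")
            if any(not (0.0 <= v <= 1.0) for v in vec):
                raise InputError(f"{name} entries must be probabilities")

    @property
    def tissues(self) -> tuple:
        return tuple(f"tissue{i + 1:02d}" for i in range(self.n_tissues))

    @property
    def enriched_tissue(self) -> str:
        return self.tissues[0]


@dataclass
class LDPanel:
    """Variant set with a block-diagonal correlation matrix.

    Serves both clumping/novelty r-squared queries and conditional analysis.
    ``variants`` has columns RSID, CHR, POS, EA, NEA, EAF in matrix order.
    """

    variants: pd.DataFrame
    R: np.ndarray
    blocks: np.ndarray  # block index per variant

    def __post_init__(self):
        self._index = {r: i for i, r in enumerate(self.variants["RSID"])}

    @property
    def rsids(self) -> np.ndarray:
        return self.variants["RSID"].to_numpy()

    @property
    def eaf(self) -> np.ndarray:
        return self.variants["EAF"].to_numpy()

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def loc(self, rsid: str) -> int:
        return self._index[rsid]

    def r(self, a: str, b: str) -> float:
        return float(self.R[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def submatrix(self, rsids: Sequence[str]) -> np.ndarray:
        idx = [self._index[r] for r in rsids]
        return self.R[np.ix_(idx, idx)]


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the data, never inside the data files."""

    causal_rsids: list = field(default_factory=list)
    beta_joint: dict = field(default_factory=dict)       # rsid -> liability/log-odds beta (primary ancestry)
    beta_joint_alt: dict = field(default_factory=dict)   # rsid -> beta in the second ancestry
    enrichment_log_fold: dict = field(default_factory=dict)  # tissue -> log fold
    causal_gene: dict = field(default_factory=dict)      # locus id -> gene
    cross_ancestry_r: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    base = n_variants // n_blocks
    sizes = np.full(n_blocks, base, dtype=int)
    sizes[: n_variants - base * n_blocks] += 1
    return sizes[sizes > 0]


def ar1_matrix(size: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: corr(i, j) = rho ** |i - j|."""
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_panel(config: SimulationConfig) -> LDPanel:
    """Generate a block-diagonal AR(1) LD panel with random frequencies.

    Blocks are placed 2 Mb apart on one chromosome with 5 kb spacing within
    a block, so 500-kb clumping keeps distinct blocks in distinct loci.
    """
    rng = _rng(config.seed, "panel")
    sizes = _block_sizes(config.n_variants, config.n_blocks)
    n = int(sizes.sum())

    R = np.zeros((n, n))
    blocks = np.zeros(n, dtype=int)
    pos = np.zeros(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes):
        sl = slice(start, start + size)
        R[sl, sl] = ar1_matrix(size, config.block_rho)
        blocks[sl] = b
        pos[sl] = b * 2_000_000 + 10_001 + 5_000 * np.arange(size)
        start += size

    eaf = rng.uniform(0.01, 0.5, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    nea = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    variants = pd.DataFrame(
        {
            "RSID": [f"rs{i + 1:07d}" for i in range(n)],
            "CHR": "1",
            "POS": pos,
            "EA": ea,
            "NEA": nea,
            "EAF": eaf,
        }
    )
    return LDPanel(variants=variants, R=R, blocks=blocks)


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def simulate_truth(panel: LDPanel, config: SimulationConfig) -> TruthRecord:
    """Draw causal variants and their joint effects in both ancestries.

    Effects in the second ancestry share the configured marginal
    distribution and correlate with the primary-ancestry effects at
    ``cross_ancestry_r``.
    """
    rng = _rng(config.seed, "truth")
    causal = rng.choice(panel.rsids, size=config.n_causal, replace=False)
    causal = sorted(causal, key=panel.loc)
    beta = rng.normal(0.0, config.causal_beta_sd, size=len(causal))
    r = config.cross_ancestry_r
    beta_alt = r * beta + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(
        0.0, config.causal_beta_sd, size=len(causal)
    )
    log_fold = {t: 0.0 for t in config.tissues}
    log_fold[config.enriched_tissue] = float(np.log(config.annotation_enrichment))
    return TruthRecord(
        causal_rsids=list(causal),
        beta_joint={v: float(b) for v, b in zip(causal, beta)},
        beta_joint_alt={v: float(b) for v, b in zip(causal, beta_alt)},
        enrichment_log_fold=log_fold,
        cross_ancestry_r=r,
    )


def joint_beta_vector(panel: LDPanel, betas: Mapping[str, float]) -> np.ndarray:
    b = np.zeros(len(panel.rsids))
    for rsid, beta in betas.items():
        if rsid not in panel:
            raise InputError(f"truth variant {rsid} absent from panel")
        b[panel.loc(rsid)] = beta
    return b


def marginal_effects(panel: LDPanel, b_joint: np.ndarray) -> np.ndarray:
    """LD-projected marginal effects on the per-allele scale.

    b_marg = S^-1 R S b_joint with S = diag(sqrt(2p(1-p))); this is the
    expectation of per-allele least-squares marginal effects when the
    individual-level model has joint effects b_joint, and reduces to
    R b_joint at equal allele frequencies.
    """
    s = np.sqrt(2 * panel.eaf * (1 - panel.eaf))
    b_marg = np.zeros_like(b_joint)
    for blk in np.unique(panel.blocks):
        m = panel.blocks == blk
        Rb = panel.R[np.ix_(m, m)]
        b_marg[m] = (Rb @ (s[m] * b_joint[m])) / s[m]
    return b_marg


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Standard case-control effective size 4 / (1/n_cases + 1/n_controls)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _log10p_from_z(z: np.ndarray) -> np.ndarray:
    return (stats.norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)


def _p_from_z(z: np.ndarray) -> np.ndarray:
    logp = stats.norm.logsf(np.abs(z)) + np.log(2.0)
    p = np.exp(logp)
    return np.maximum(p, 5e-324)


def simulate_summary_stats(
    panel: LDPanel,
    truth: TruthRecord,
    config: SimulationConfig,
    ancestry: str = "primary",
) -> list[pd.DataFrame]:
    """Per-study case-control summary-statistic tables.

    Marginal effects are the LD projection of the joint truth effects;
    estimation noise has covariance se_i se_j r_ij, i.e. sigma^2 R / N_eff
    on the standardized scale. Effect alleles are randomized per study so
    downstream alignment code is exercised.
    """
    if ancestry == "primary":
        betas, stream = truth.beta_joint, "stats"
    elif ancestry in ("alt", "secondary"):
        betas, stream = truth.beta_joint_alt, "stats_eas"
    else:
        raise InputError(f"unknown ancestry {ancestry!r}")

    rng = _rng(config.seed, stream)
    b_joint = joint_beta_vector(panel, betas)
    b_marg = marginal_effects(panel, b_joint)

    eaf = panel.eaf
    s2 = 2 * eaf * (1 - eaf)
    chols = {
        blk: np.linalg.cholesky(
            panel.R[np.ix_(panel.blocks == blk, panel.blocks == blk)]
            + 1e-12 * np.eye(int((panel.blocks == blk).sum()))
        )
        for blk in np.unique(panel.blocks)
    }

    cases = np.atleast_1d(config.per_study_cases)
    controls = np.atleast_1d(config.per_study_controls)
    tables = []
    for i in range(config.n_studies):
        ncas = int(cases[i % len(cases)])
        ncon = int(controls[i % len(controls)])
        neff = effective_sample_size(ncas, ncon)
        se = 2.0 / np.sqrt(neff * s2)

        eps = np.empty(len(eaf))
        for blk, L in chols.items():
            m = panel.blocks == blk
            eps[m] = L @ rng.standard_normal(int(m.sum()))
        beta_hat = b_marg + se * eps
        z = beta_hat / se

        eaf_obs = np.clip(
            eaf + rng.normal(0, np.sqrt(eaf * (1 - eaf) / (2 * (ncas + ncon)))),
            1e-3,
            1 - 1e-3,
        )
        info = rng.uniform(0.9, 1.0, size=len(eaf))

        df = pd.DataFrame(
            {
                "CHR": panel.variants["CHR"],
                "POS": panel.variants["POS"],
                "RSID": panel.variants["RSID"],
                "EA": panel.variants["EA"],
                "NEA": panel.variants["NEA"],
                "EAF": eaf_obs,
                "BETA": beta_hat,
                "SE": se,
                "P": _p_from_z(z),
                "N_CASES": ncas,
                "N_CONTROLS": ncon,
                "INFO": info,
            }
        )
        flip = rng.random(len(df)) < 0.5
        df.loc[flip, ["EA", "NEA"]] = df.loc[flip, ["NEA", "EA"]].to_numpy()
        df.loc[flip, "BETA"] *= -1.0
        df.loc[flip, "EAF"] = 1.0 - df.loc[flip, "EAF"]
        tables.append(df)
    return tables


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def simulate_annotations(
    panel: LDPanel, truth: TruthRecord, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Binary per-tissue annotation vectors aligned to the panel.

    In the enriched tissue the odds of annotation at causal variants equal
    ``annotation_enrichment`` times the odds at non-causal variants, in
    expectation; the other tissues annotate at background coverage
    everywhere.
    """
    if config.annotation_enrichment < 1.0:
        raise InputError("annotation enrichment fold must be >= 1")
    rng = _rng(config.seed, "annotations")
    cov = config.annotation_coverage
    fold = config.annotation_enrichment
    causal_mask = np.isin(panel.rsids, truth.causal_rsids)

    if cov == 0.0:
        return {t: np.zeros(len(panel.rsids), dtype=int) for t in config.tissues}

    odds = cov / (1 - cov)
    p_causal = (fold * odds) / (1 + fold * odds)

    tracks = {}
    for tissue in config.tissues:
        p = np.full(len(panel.rsids), cov)
        if tissue == config.enriched_tissue:
            p[causal_mask] = p_causal
        tracks[tissue] = (rng.random(len(p)) < p).astype(int)
    return tracks


# ---------------------------------------------------------------------------
# Evidence matrices
# ---------------------------------------------------------------------------

def simulate_evidence_matrix(
    sentinels: Mapping[str, int] | int,
    truth: TruthRecord,
    config: SimulationConfig,
    min_genes: int = 3,
    max_genes: int = 8,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Locus x candidate-gene x 8-predictor binary evidence matrix.

    ``sentinels`` maps locus id to sentinel position (an int builds that
    many synthetic loci). Exactly one true causal gene is drawn per locus
    and written into ``truth.causal_gene``. For every stochastic predictor
    p, P(evidence | true gene) = sensitivity_p and
    P(evidence | other gene) = 1 - specificity_p, independently. The
    nearest-gene predictor is deterministic from the simulated coordinates.
    """
    rng = _rng(config.seed, "evidence")
    if isinstance(sentinels, int):
        sentinels = {
            f"locus{i + 1:03d}": 1_000_000 + 2_000_000 * i for i in range(sentinels)
        }
    if min_genes < 1:
        raise InputError("each locus needs at least one candidate gene")

    sens = np.asarray(config.predictor_sensitivity)
    spec = np.asarray(config.predictor_specificity)
    rows = []
    for locus, spos in sentinels.items():
        n_genes = int(rng.integers(min_genes, max_genes + 1))
        if n_genes == 0:
            raise InputError(f"locus {locus} has zero candidate genes")
        tss = spos + rng.integers(-window_bp, window_bp + 1, size=n_genes)
        genes = [f"{locus.upper()}_G{k + 1}" for k in range(n_genes)]
        dist = np.abs(tss - spos)
        nearest = int(np.argmin(dist))
        true_idx = int(rng.integers(0, n_genes))
        truth.causal_gene[locus] = genes[true_idx]

        for g in range(n_genes):
            row = {
                "LOCUS_ID": locus,
                "GENE": genes[g],
                "DISTANCE_BP": int(dist[g]),
            }
            for k, pred in enumerate(PREDICTORS):
                if pred == "nearest_gene":
                    row[pred] = int(g == nearest)
                elif g == true_idx:
                    row[pred] = int(rng.random() < sens[k])
                else:
                    row[pred] = int(rng.random() < 1 - spec[k])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Dosage + phenotype table for polygenic-score evaluation.

    ``data`` holds one row per individual: IID, EVENT, TIME, AGE, SEX,
    PC1..PC5 and one ``DS_<rsid>`` dosage column per model variant (dosage
    counts the allele in ``variant_meta.ALLELE``).
    """

    data: pd.DataFrame
    variant_meta: pd.DataFrame  # RSID, ALLELE, EAF

    @property
    def dosages(self) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c.startswith("DS_")]
        out = self.data[cols].copy()
        out.columns = [c[3:] for c in cols]
        return out


def simulate_cohort(
    panel: LDPanel,
    weights: pd.DataFrame,
    config: SimulationConfig,
) -> CohortTable:
    """Prospective cohort with events driven by the polygenic score.

    ``weights`` is a PRS weight table (RSID, EA, WEIGHT) whose variants
    must all be present in the panel. Event times are exponential with a
    per-individual rate lambda0 * exp(b * score_sd) where b is
    ``cohort_loghr_per_sd`` and lambda0 is set so the baseline cumulative
    risk over follow-up equals ``baseline_risk``; events are times within
    the follow-up window, so a proportional-hazards fit is exactly
    calibrated against the generator.
    """
    if config.cohort_n <= 0:
        raise InputError("cohort_n must be positive (empty cohort)")
    missing = [r for r in weights["RSID"] if r not in panel]
    if missing:
        raise InputError(f"weight variants absent from panel: {missing[:5]}")

    rng = _rng(config.seed, "cohort")
    n = config.cohort_n
    rsids = weights["RSID"].tolist()
    idx = [panel.loc(r) for r in rsids]
    eaf = panel.eaf[idx]
    panel_ea = panel.variants["EA"].to_numpy()[idx]
    panel_nea = panel.variants["NEA"].to_numpy()[idx]

    dos = rng.binomial(2, eaf, size=(n, len(rsids))).astype(float)

    # align weights to the panel counted allele
    w = weights["WEIGHT"].to_numpy().astype(float).copy()
    wea = weights["EA"].to_numpy()
    flip = wea == panel_nea
    bad = ~flip & (wea != panel_ea)
    if bad.any():
        raise InputError("weight effect alleles incompatible with panel")
    w[flip] *= -1.0

    raw = dos @ w
    sd = raw.std()
    x = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)

    K, years = config.baseline_risk, config.followup_years
    lam0 = -np.log(1 - K) / years
    lam = lam0 * np.exp(config.cohort_loghr_per_sd * x)
    t = rng.exponential(1.0 / lam)
    event = (t <= years).astype(int)
    time = np.minimum(t, years)

    data = pd.DataFrame(
        {
            "IID": [f"id{i + 1:06d}" for i in range(n)],
            "EVENT": event,
            "TIME": time,
            "AGE": rng.normal(60, 8, size=n).round(1),
            "SEX": rng.integers(0, 2, size=n),
        }
    )
    for k in range(1, 6):
        data[f"PC{k}"] = rng.normal(0, 1, size=n)
    for j, rsid in enumerate(rsids):
        data[f"DS_{rsid}"] = dos[:, j]

    meta = pd.DataFrame({"RSID": rsids, "ALLELE": panel_ea, "EAF": eaf})
    return CohortTable(data=data, variant_meta=meta)
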