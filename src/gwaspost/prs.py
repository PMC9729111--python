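"""Polygenic score computation, stratification and survival association.

Scores are weighted dosage sums after allele alignment; standardization is
within the scored cohort. Stratification reports per-decile event rates
and extreme-decile comparisons; the survival association is a thin wrapper
around a proportional-hazards fit (lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from gwaspost.simulate import CohortTable, InputError

DEFAULT_COVARIATES = ("AGE", "SEX", "PC1", "PC2", "PC3", "PC4", "PC5")


@dataclass
class PRSModel:
    """Variant weights keyed by effect allele (RSID, EA, WEIGHT)."""

    weights: pd.DataFrame

    def __post_init__(self):
        w = self.weights
        for col in ("RSID", "EA", "WEIGHT"):
            if col not in w.columns:
                raise InputError(f"weight table missing column {col}")
        if w["RSID"].duplicated().any():
            raise InputError("duplicate variant ids in weight table")
        if not np.isfinite(w["WEIGHT"].to_numpy(float)).all():
            raise InputError("weights must be finite")


def score(
    cohort: CohortTable,
    model: PRSModel,
    missing: str = "impute",
) -> pd.DataFrame:
    """Per-individual raw, standardized and percentile scores.

    Model weights are aligned to the cohort's counted alleles (sign flip
    when the weight's effect allele is the other allele). Model variants
    absent from the cohort are mean-imputed at dosage 2*EAF of the cohort
    (``missing="impute"``, the default) or dropped (``missing="drop"``).
    """
    meta = cohort.variant_meta.set_index("RSID")
    dosages = cohort.dosages
    raw = np.zeros(len(dosages))
    n_used = 0
    for row in model.weights.itertuples(index=False):
        if row.RSID not in meta.index:
            if missing == "drop":
                continue
            raise InputError(f"variant {row.RSID} absent from cohort")
        counted = meta.loc[row.RSID, "ALLELE"]
        w = float(row.WEIGHT)
        if row.EA != counted:
            w = -w  # dosage counts the other allele: 2 - d contributes w*d' = -w*d + 2w
            raw += 2.0 * float(row.WEIGHT)
        if row.RSID in dosages.columns:
            d = dosages[row.RSID].to_numpy(float)
        else:
            d = np.full(len(dosages), 2.0 * float(meta.loc[row.RSID, "EAF"]))
        raw += w * d
        n_used += 1
    if n_used == 0:
        raise InputError("no overlap between model variants and cohort")

    sd = raw.std()
    if sd == 0:
        std = np.zeros_like(raw)
    else:
        std = (raw - raw.mean()) / sd
    pct = pd.Series(raw).rank(method="average", pct=True).to_numpy()
    return pd.DataFrame(
        {"IID": cohort.data["IID"].to_numpy(), "RAW": raw, "STD": std, "PERCENTILE": pct}
    )


@dataclass
class DecileResult:
    rates: np.ndarray               # event rate per decile, 1..10
    counts: np.ndarray
    top_vs_bottom: float
    top_vs_middle: float
    bottom_vs_middle: float
    infinite: bool = False


def decile_stratify(scores: np.ndarray, events: np.ndarray) -> DecileResult:
    """Event rates by score decile and extreme-decile comparisons.

    Deciles partition individuals by stable score rank, so assignment is
    invariant to monotone transforms of the score. Ratios against a
    zero-event reference stratum are reported infinite with a flag.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events)
    n = len(scores)
    if n < 10:
        raise InputError("need at least 10 individuals for deciles")
    order = np.argsort(scores, kind="stable")
    decile = np.empty(n, dtype=int)
    decile[order] = (np.arange(n) * 10) // n  # 0..9, near-equal sizes

    rates = np.array([events[decile == d].mean() for d in range(10)])
    counts = np.array([(decile == d).sum() for d in range(10)])
    middle = events[(decile > 0) & (decile < 9)].mean()

    def ratio(a, b):
        return float(a / b) if b > 0 else float("inf")

    result = DecileResult(
        rates=rates,
        counts=counts,
        top_vs_bottom=ratio(rates[9], rates[0]),
        top_vs_middle=ratio(rates[9], middle),
        bottom_vs_middle=ratio(rates[0], middle),
    )
    result.infinite = not np.isfinite(
        [result.top_vs_bottom, result.top_vs_middle, result.bottom_vs_middle]
    ).all()
    return result


@dataclass
class AssociationResult:
    hr_per_sd: float
    ci: tuple
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool
    covariates: tuple


def score_association(
    cohort: CohortTable,
    std_scores: np.ndarray,
    covariates: tuple = DEFAULT_COVARIATES,
) -> AssociationResult:
    """Hazard ratio per 1 s.d. of the score from a Cox model.

    Adjusts for the declared covariates; non-convergence is flagged in the
    result rather than silently defaulted.
    """
    std_scores = np.asarray(std_scores, dtype=float)
    if std_scores.std() == 0:
        raise InputError("score has no variance")
    cols = [c for c in covariates if c in cohort.data.columns]
    df = cohort.data[["TIME", "EVENT", *cols]].copy()
    df["PRS_STD"] = std_scores
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="TIME", event_col="EVENT")
        converged = True
    except ConvergenceError:
        return AssociationResult(
            hr_per_sd=float("nan"), ci=(float("nan"), float("nan")),
            log_hr=float("nan"), se=float("nan"), p=float("nan"),
            n=len(df), n_events=int(df["EVENT"].sum()),
            converged=False, covariates=tuple(cols),
        )
    log_hr = float(fitter.params_["PRS_STD"])
    se = float(fitter.standard_errors_["PRS_STD"])
    return AssociationResult(
        hr_per_sd=float(np.exp(log_hr)),
        ci=(float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))),
        log_hr=log_hr,
        se=se,
        p=float(fitter.summary.loc["PRS_STD", "p"]),
        n=len(df),
        n_events=int(df["EVENT"].sum()),
        converged=converged,
        covariates=tuple(cols),
    )
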