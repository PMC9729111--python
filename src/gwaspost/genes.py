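"""Consensus causal-gene prioritization from eight binary predictors.

At every locus the candidate gene with the highest unweighted sum of
predictor evidence is nominated; loci tier at >= 2 (prioritized) and >= 3
(strong) concordant predictors. Ties are reported, never silently broken.
Summary statistics: per-predictor agreement with the consensus nominee,
per-pair concordance, and accuracy against a positive-control truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gwaspost.simulate import PREDICTORS, InputError

TIER_PRIORITIZED = 2
TIER_STRONG = 3


@dataclass
class PrioritizationResult:
    locus_id: str
    nominees: list            # all argmax genes (length > 1 only on ties)
    n_concordant: int
    tier: str                 # "none" | "prioritized" | "strong"
    tie: bool

    @property
    def nominee(self) -> str | None:
        """Unique nominee, or None when tied or no evidence."""
        return self.nominees[0] if len(self.nominees) == 1 else None


def _tier(n: int) -> str:
    if n >= TIER_STRONG:
        return "strong"
    if n >= TIER_PRIORITIZED:
        return "prioritized"
    return "none"


def prioritize_locus(matrix: pd.DataFrame) -> PrioritizationResult:
    """Nominate the causal gene for one locus.

    ``matrix`` holds that locus's rows of the evidence matrix (one row per
    candidate gene, the eight predictor columns binary). The nominee is the
    argmax of per-gene evidence sums; a zero maximum nominates nothing.
    Output is invariant to gene row order and predictor column order.
    """
    if len(matrix) == 0:
        raise InputError("locus has no candidate genes")
    locus_id = str(matrix["LOCUS_ID"].iloc[0])
    sums = matrix[list(PREDICTORS)].sum(axis=1).to_numpy()
    best = int(sums.max())
    if best == 0:
        return PrioritizationResult(locus_id, [], 0, "none", False)
    genes = sorted(matrix.loc[sums == best, "GENE"].tolist())
    return PrioritizationResult(
        locus_id=locus_id,
        nominees=genes,
        n_concordant=best,
        tier=_tier(best),
        tie=len(genes) > 1,
    )


def prioritize_all(matrix: pd.DataFrame) -> list[PrioritizationResult]:
    return [
        prioritize_locus(sub)
        for _, sub in matrix.groupby("LOCUS_ID", sort=True)
    ]


def _fires(matrix: pd.DataFrame, predictor: str) -> pd.Series:
    """Per locus: does the predictor provide evidence for >= 1 gene?"""
    return matrix.groupby("LOCUS_ID", sort=True)[predictor].max() > 0


def _marks_nominee(
    matrix: pd.DataFrame, results: Sequence[PrioritizationResult], predictor: str
) -> dict:
    marks = {}
    by_locus = {r.locus_id: r for r in results}
    for locus, sub in matrix.groupby("LOCUS_ID", sort=True):
        r = by_locus.get(str(locus))
        if r is None or r.nominee is None:
            marks[str(locus)] = False
            continue
        row = sub[sub["GENE"] == r.nominee]
        marks[str(locus)] = bool(row[predictor].iloc[0] == 1)
    return marks


def agreement(
    results: Sequence[PrioritizationResult],
    matrix: pd.DataFrame,
    predictor: str,
    include_ties: bool = False,
) -> tuple[float | None, int, int]:
    """Proportion of loci where the predictor marks the consensus nominee.

    Denominator: loci where the predictor provides evidence for at least
    one gene; tied loci (no unique nominee) are excluded unless
    ``include_ties`` (then a tied locus counts as a miss). Returns
    (rate or None, numerator, denominator); None when the predictor never
    fires.
    """
    if predictor not in PREDICTORS:
        raise InputError(f"unknown predictor {predictor!r}")
    fires = _fires(matrix, predictor)
    marks = _marks_nominee(matrix, results, predictor)
    num = den = 0
    for r in results:
        if not fires.get(r.locus_id, False):
            continue
        if r.tie and not include_ties:
            continue
        if r.nominee is None and not include_ties:
            continue
        den += 1
        num += int(marks[r.locus_id])
    if den == 0:
        return None, 0, 0
    return num / den, num, den


def concordance(
    results: Sequence[PrioritizationResult],
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    include_ties: bool = False,
) -> tuple[float | None, int, int]:
    """Proportion of loci where both predictors mark the consensus nominee,
    among loci where both provide evidence for >= 1 gene. Symmetric in the
    pair."""
    p, q = pair
    for name in (p, q):
        if name not in PREDICTORS:
            raise InputError(f"unknown predictor {name!r}")
    fires_p, fires_q = _fires(matrix, p), _fires(matrix, q)
    marks_p = _marks_nominee(matrix, results, p)
    marks_q = _marks_nominee(matrix, results, q)
    num = den = 0
    for r in results:
        if not (fires_p.get(r.locus_id, False) and fires_q.get(r.locus_id, False)):
            continue
        if (r.tie or r.nominee is None) and not include_ties:
            continue
        den += 1
        num += int(marks_p[r.locus_id] and marks_q[r.locus_id])
    if den == 0:
        return None, 0, 0
    return num / den, num, den


@dataclass
class ControlEvaluation:
    fraction_correct: float
    n_correct: int
    n_valid: int
    n_invalid: int
    correct_with_tie: int
    median_concordant_correct: float
    predictor_accuracy: dict = field(default_factory=dict)
    # per predictor: {"rate": float|None, "num": int, "den": int,
    #                 "rate_all": float, "den_all": int}


def evaluate_positive_controls(
    results: Sequence[PrioritizationResult],
    matrix: pd.DataFrame,
    truth: Mapping[str, str],
) -> ControlEvaluation:
    """Evaluate nominations against a positive-control truth set.

    ``truth`` maps locus id -> established causal gene. Loci whose truth
    gene is absent from the candidate list are flagged invalid and
    excluded. A tied locus counts as correct (with a flag) when the truth
    gene is among the tied nominees. Per-predictor accuracy is reported
    against two denominators: loci where the predictor fires, and all
    valid control loci.
    """
    by_locus = {r.locus_id: r for r in results}
    genes_at = matrix.groupby("LOCUS_ID", sort=True)["GENE"].apply(set)

    valid = {}
    n_invalid = 0
    for locus, gene in truth.items():
        if locus not in genes_at.index or gene not in genes_at[locus]:
            n_invalid += 1
            continue
        valid[locus] = gene

    n_correct = 0
    correct_with_tie = 0
    concordant_correct = []
    for locus, gene in valid.items():
        r = by_locus.get(locus)
        if r is None:
            continue
        if r.nominee == gene:
            n_correct += 1
            concordant_correct.append(r.n_concordant)
        elif r.tie and gene in r.nominees:
            n_correct += 1
            correct_with_tie += 1
            concordant_correct.append(r.n_concordant)

    accuracy = {}
    for pred in PREDICTORS:
        num = den_fire = 0
        for locus, gene in valid.items():
            sub = matrix[matrix["LOCUS_ID"] == locus]
            fires = bool(sub[pred].max() > 0)
            hit = bool(sub.loc[sub["GENE"] == gene, pred].iloc[0] == 1)
            if fires:
                den_fire += 1
                num += int(hit)
        accuracy[pred] = {
            "rate": (num / den_fire) if den_fire else None,
            "num": num,
            "den": den_fire,
            "rate_all": (num / len(valid)) if valid else None,
            "den_all": len(valid),
        }

    n_valid = len(valid)
    return ControlEvaluation(
        fraction_correct=(n_correct / n_valid) if n_valid else float("nan"),
        n_correct=n_correct,
        n_valid=n_valid,
        n_invalid=n_invalid,
        correct_with_tie=correct_with_tie,
        median_concordant_correct=(
            float(np.median(concordant_correct)) if concordant_correct else float("nan")
        ),
        predictor_accuracy=accuracy,
    )


RISK_FACTOR_GROUPS = ("lipids", "blood_pressure", "hyperglycemia", "adiposity")


def classify_risk_factor_consistency(
    trait_associations: Mapping[str, Sequence[tuple[float, bool]]],
) -> str:
    """Classify a risk allele's phenome-scan profile.

    ``trait_associations`` maps each risk-factor group (lipids, blood
    pressure, hyperglycemia, adiposity) to (direction, significant) pairs
    for traits in that group, with direction the signed association of the
    disease risk-increasing allele. Returns "risk-factor-consistent" when
    any group has a significant positive association, "non-risk-factor"
    otherwise, and "unassessed" with no trait data at all.
    """
    seen = False
    for group, assocs in trait_associations.items():
        if group not in RISK_FACTOR_GROUPS:
            raise InputError(f"unknown risk-factor group {group!r}")
        for direction, significant in assocs:
            seen = True
            if significant and direction > 0:
                return "risk-factor-consistent"
    return "non-risk-factor" if seen else "unassessed"
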