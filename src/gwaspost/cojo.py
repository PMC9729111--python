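"""Approximate conditional/joint analysis from summary statistics.

Reconstructs the sufficient statistics of a multiple regression from
marginal GWAS effects plus an external LD reference, then runs a greedy
stepwise selection with a backward check, mirroring the summary-statistic
approximation used by GCTA-COJO at desk scale.

Model: with per-allele dosages, X'X is approximated by
C_jk = sqrt(N_j N_k) s_j s_k r_jk where s_j^2 = 2 p_j (1 - p_j) comes from
the LD reference and r_jk from its correlation matrix, and
X_j'y = N_j s_j^2 b_j from the marginal effect b_j. Joint estimates solve
C b_joint = X'y; with identity LD the joint effects equal the marginal
ones exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gwaspost.meta import two_sided_p
from gwaspost.simulate import InputError, LDPanel, effective_sample_size

DEFAULT_COLLINEARITY_R2 = 0.9


class CollinearityError(ValueError):
    """The requested variant subset is (numerically) collinear."""


@dataclass
class JointModel:
    """Selected conditionally independent signals and their joint effects."""

    rsids: list = field(default_factory=list)
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    se: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: np.ndarray = field(default_factory=lambda: np.empty(0))
    log10_p: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold: float = 5e-8
    sigma2: float = float("nan")

    def __len__(self) -> int:
        return len(self.rsids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "RSID": self.rsids,
                "BETA_JOINT": self.beta,
                "SE_JOINT": self.se,
                "P_JOINT": self.p,
                "LOG10_P_JOINT": self.log10_p,
            }
        )


def _neff(table: pd.DataFrame) -> np.ndarray:
    if "N_EFF" in table.columns:
        return table["N_EFF"].to_numpy(float)
    return np.array(
        [
            effective_sample_size(c, k)
            for c, k in zip(table["N_CASES"], table["N_CONTROLS"])
        ],
        dtype=float,
    )


def _phenotypic_variance(
    beta: np.ndarray, se: np.ndarray, s2: np.ndarray, neff: np.ndarray
) -> float:
    # median of the per-variant implied var(y): robust to outlier SEs
    return float(np.median(s2 * (neff * se**2 + beta**2)))


def joint_effects(
    table: pd.DataFrame,
    panel: LDPanel,
    rsids: list[str],
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    freq_source: str = "panel",
) -> JointModel:
    """Joint (multiple-regression) effects of a variant subset.

    ``table`` is a meta-analysis table carrying RSID, BETA, SE, EAF and
    case/control counts (or N_EFF). Frequencies used for the diagonal
    scaling come from the LD reference by default (``freq_source="table"``
    switches to the summary table). Raises CollinearityError, naming the
    offending pair, when any pair in the subset exceeds the r^2 cutoff or
    the normal-equation matrix is singular.
    """
    missing = [r for r in rsids if r not in panel]
    if missing:
        raise InputError(f"variants absent from LD panel: {missing[:5]}")
    in_table = set(table["RSID"])
    absent = [r for r in rsids if r not in in_table]
    if absent:
        raise InputError(f"variants absent from summary table: {absent[:5]}")
    sub = table.set_index("RSID").loc[rsids]

    # align table betas to the panel's allele coding (the LD correlations
    # are expressed on panel effect alleles)
    sign = np.ones(len(rsids))
    if "EA" in sub.columns and "NEA" in sub.columns:
        pvars = panel.variants.iloc[[panel.loc(r) for r in rsids]]
        t_ea, t_nea = sub["EA"].to_numpy(), sub["NEA"].to_numpy()
        p_ea, p_nea = pvars["EA"].to_numpy(), pvars["NEA"].to_numpy()
        swapped = (t_ea == p_nea) & (t_nea == p_ea)
        same = (t_ea == p_ea) & (t_nea == p_nea)
        if not np.all(same | swapped):
            bad = [r for r, ok in zip(rsids, same | swapped) if not ok]
            raise InputError(f"alleles incompatible with panel: {bad[:5]}")
        sign[swapped] = -1.0

    R = panel.submatrix(rsids)
    k = len(rsids)
    for i in range(k):
        for j in range(i + 1, k):
            if R[i, j] ** 2 > collinearity_r2:
                raise CollinearityError(
                    f"{rsids[i]} and {rsids[j]} have r^2 "
                    f"{R[i, j] ** 2:.3f} > {collinearity_r2}"
                )

    if freq_source == "panel":
        p = np.array([panel.eaf[panel.loc(r)] for r in rsids])
    else:
        p = sub["EAF"].to_numpy(float)
        p = np.where(sign < 0, 1.0 - p, p)
    s = np.sqrt(2 * p * (1 - p))
    beta = sign * sub["BETA"].to_numpy(float)
    se = sub["SE"].to_numpy(float)
    neff = _neff(sub.reset_index())
    sigma2 = _phenotypic_variance(beta, se, s**2, neff)

    sqn = np.sqrt(neff)
    C = (sqn[:, None] * sqn[None, :]) * (s[:, None] * s[None, :]) * R
    xty = neff * s**2 * beta
    try:
        b_joint = np.linalg.solve(C, xty)
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise CollinearityError(f"singular LD submatrix for {rsids}") from err
    se_joint = np.sqrt(np.maximum(sigma2 * np.diag(Cinv), 1e-300))
    z = b_joint / se_joint
    pvals, log10p = two_sided_p(z)
    return JointModel(
        rsids=list(rsids),
        beta=b_joint,
        se=se_joint,
        p=np.atleast_1d(pvals),
        log10_p=np.atleast_1d(log10p),
        sigma2=sigma2,
    )


def stepwise_select(
    table: pd.DataFrame,
    panel: LDPanel,
    p_threshold: float = 5e-8,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    max_signals: int = 100,
) -> JointModel:
    """Greedy forward selection with backward elimination.

    Seeds with the smallest-p variant; at each step the candidate with the
    smallest joint p (fit together with the current selection) enters if it
    passes ``p_threshold``; after every entry, selected variants whose
    joint p rose above the threshold are dropped. Candidates with r^2 above
    the collinearity cutoff against any selected variant are excluded.
    Returns an empty model when no variant reaches the threshold.
    """
    table = table[table["RSID"].isin(panel.rsids)].reset_index(drop=True)
    if len(table) == 0 or float(table["P"].min()) > p_threshold:
        return JointModel(threshold=p_threshold)

    if table["CHR"].nunique() > 1:
        raise InputError("stepwise_select expects a single chromosome")

    seed = table.sort_values(["P", "POS"], kind="stable").iloc[0]
    selected = [str(seed["RSID"])]
    model = joint_effects(table, panel, selected, collinearity_r2)
    dropped: set = set()  # backward-eliminated variants never re-enter

    while len(selected) < max_signals:
        candidates = [
            r for r in table["RSID"] if r not in selected and r not in dropped
        ]
        best: tuple | None = None
        for cand in candidates:
            if any(panel.r2(cand, s) > collinearity_r2 for s in selected):
                continue
            try:
                trial = joint_effects(
                    table, panel, selected + [cand], collinearity_r2
                )
            except CollinearityError:
                continue
            cand_log10p = float(trial.log10_p[-1])
            if best is None or cand_log10p < best[0]:
                best = (cand_log10p, cand, trial)
        if best is None or best[0] > np.log10(p_threshold):
            break
        selected.append(best[1])
        model = best[2]

        # backward check: drop signals whose joint p rose above threshold
        while len(selected) > 1:
            worst = int(np.argmax(model.log10_p))
            if model.log10_p[worst] <= np.log10(p_threshold):
                break
            dropped.add(selected[worst])
            del selected[worst]
            model = joint_effects(table, panel, selected, collinearity_r2)

    model.threshold = p_threshold
    return model
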