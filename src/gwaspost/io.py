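"""Readers and writers for the toolkit's plain-text formats.

Summary statistics, evidence matrices, weights and cohorts are
tab-delimited with 1-based positions; annotation tracks are BED (0-based,
half-open), converted on read. LD panels are a variant-index TSV plus a
dense correlation-matrix TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gwaspost.simulate import CohortTable, LDPanel

_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = {"CHR", "POS", "RSID", "EA", "NEA", "EAF", "BETA", "SE", "P"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


write_summary_stats = write_tsv


def write_bed(panel: LDPanel, track: np.ndarray, path, name: str = "annot") -> None:
    """Serialize a per-variant binary track as BED intervals (0-based,
    half-open) around annotated variant positions."""
    rows = panel.variants.loc[np.asarray(track, dtype=bool), ["CHR", "POS"]]
    with open(path, "w") as fh:
        for chrom, pos in rows.itertuples(index=False):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\n")


def read_bed_annotation(path, panel: LDPanel) -> np.ndarray:
    """Binary per-variant vector: 1 when the variant position falls inside
    any BED interval (BED start is 0-based inclusive, end exclusive)."""
    track = np.zeros(len(panel.variants), dtype=int)
    intervals: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    for i, (chrom, pos) in enumerate(
        panel.variants[["CHR", "POS"]].itertuples(index=False)
    ):
        zero_based = pos - 1
        for start, end in intervals.get(str(chrom), []):
            if start <= zero_based < end:
                track[i] = 1
                break
    return track


def write_ld_panel(panel: LDPanel, prefix) -> None:
    prefix = Path(prefix)
    variants = panel.variants.copy()
    variants["BLOCK"] = panel.blocks
    write_tsv(variants, prefix.with_suffix(".vars.tsv"))
    np.savetxt(prefix.with_suffix(".ld.tsv"), panel.R, delimiter="\t", fmt="%.8g")


def read_ld_panel(prefix) -> LDPanel:
    prefix = Path(prefix)
    variants = pd.read_csv(prefix.with_suffix(".vars.tsv"), sep="\t", dtype={"CHR": str})
    R = np.loadtxt(prefix.with_suffix(".ld.tsv"), delimiter="\t", ndmin=2)
    blocks = variants.pop("BLOCK").to_numpy()
    return LDPanel(variants=variants, R=R, blocks=blocks)


def read_evidence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: CohortTable, prefix) -> None:
    prefix = Path(prefix)
    write_tsv(cohort.data, prefix.with_suffix(".pheno.tsv"))
    write_tsv(cohort.variant_meta, prefix.with_suffix(".variants.tsv"))


def read_cohort(prefix) -> CohortTable:
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_suffix(".pheno.tsv"), sep="\t")
    meta = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t")
    return CohortTable(data=data, variant_meta=meta)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
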