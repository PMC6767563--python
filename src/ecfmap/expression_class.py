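"""Promoter-dependence classification from WT vs mutant induction time courses.

Targets of an ECF sigma factor fall into three classes: a single promoter
completely dependent on the factor (Class I), a single promoter partially
dependent (Class II), or multiple promoters of which at least one is
(partially) dependent (Class III).  The classes are operationalised here
with explicit numeric thresholds on per-gene-median-normalised log2
expression: a gene counts as induced when its wild-type induction (max rise
over the time course relative to t = 0) reaches ``induction_min_log2``;
dependence is complete when the mutant's induction stays below
``full_dependence_max_mutant_log2``, absent when the mutant induces as
strongly as the wild type (within ``epsilon``), and partial otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TIME_GRID = (0, 30, 60, 90)
STRAINS = ("WT", "dsigE")

REPORT_COLUMNS = ["gene_id", "n_promoters", "wt_induction", "mut_induction",
                  "dependence", "promoter_class"]


@dataclass(frozen=True)
class ClassThresholds:
    """Numeric boundaries for the qualitative dependence scheme.

    ``induction_min_log2`` (default 1.0, i.e. twofold) is the minimum
    wild-type induction for a gene to be classified at all;
    ``full_dependence_max_mutant_log2`` bounds the residual mutant induction
    compatible with complete dependence; ``epsilon`` is the margin below the
    wild-type induction at which the mutant is considered fully induced
    (no dependence).
    """

    induction_min_log2: float = 1.0
    full_dependence_max_mutant_log2: float = 0.5
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.induction_min_log2 <= self.full_dependence_max_mutant_log2:
            raise ValueError(
                "induction_min_log2 must exceed full_dependence_max_mutant_log2")


@dataclass
class TargetClassification:
    gene_id: str
    n_promoters: int
    wt_induction: float
    mut_induction: float
    dependence: str       # complete | partial | none
    promoter_class: str   # I | II | III | unclassified


def condition_columns(strain: str, times: Sequence[int] = TIME_GRID) -> list[str]:
    return [f"{strain}_{t}" for t in times]


def normalize_per_gene_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's own median (log2 scale); idempotent."""
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return matrix.sub(matrix.median(axis=1), axis=0)


def induction(series: Mapping[int, float] | pd.Series) -> float:
    """Max rise over the time course relative to t = 0 (log2 fold)."""
    s = pd.Series(dict(series)) if not isinstance(series, pd.Series) else series
    if 0 not in s.index:
        raise ValueError("time 0 missing from the series")
    later = s[s.index != 0]
    if later.empty:
        raise ValueError("need at least one time point after t = 0")
    return float((later - s[0]).max())


def classify_target(gene_id: str, n_promoters: int,
                    wt_series: Mapping[int, float] | pd.Series,
                    mut_series: Mapping[int, float] | pd.Series,
                    thr: ClassThresholds = ClassThresholds()) -> TargetClassification:
    """Assign the promoter class of one gene from its two induction series."""
    if n_promoters < 1:
        raise ValueError("n_promoters must be >= 1")
    wt_ind = induction(wt_series)
    mut_ind = induction(mut_series)
    if wt_ind < thr.induction_min_log2:
        dependence = "none"
        promoter_class = "unclassified"
    else:
        if mut_ind <= thr.full_dependence_max_mutant_log2:
            dependence = "complete"
        elif mut_ind >= wt_ind - thr.epsilon:
            dependence = "none"
        else:
            dependence = "partial"
        if n_promoters == 1 and dependence == "complete":
            promoter_class = "I"
        elif n_promoters == 1 and dependence == "partial":
            promoter_class = "II"
        elif n_promoters > 1 and dependence in ("partial", "complete"):
            promoter_class = "III"
        else:
            promoter_class = "unclassified"
    return TargetClassification(gene_id, n_promoters, wt_ind, mut_ind,
                                dependence, promoter_class)


def classify_matrix(matrix: pd.DataFrame, n_promoters: Mapping[str, int],
                    thr: ClassThresholds = ClassThresholds(),
                    normalize: bool = True) -> list[TargetClassification]:
    """Classify every gene of a genes x conditions matrix.

    Column names follow ``WT_0 ... dsigE_90``.  Genes missing from
    ``n_promoters`` are assumed to have a single promoter.
    """
    if normalize:
        matrix = normalize_per_gene_median(matrix)
    wt_cols = condition_columns("WT")
    mut_cols = condition_columns("dsigE")
    missing = [c for c in wt_cols + mut_cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix lacks columns {missing}")
    out = []
    for gene_id, row in matrix.iterrows():
        wt = pd.Series(row[wt_cols].to_numpy(dtype=float), index=list(TIME_GRID))
        mut = pd.Series(row[mut_cols].to_numpy(dtype=float), index=list(TIME_GRID))
        out.append(classify_target(str(gene_id), int(n_promoters.get(gene_id, 1)),
                                   wt, mut, thr))
    return out


def dependence_report(classifications: Iterable[TargetClassification],
                      path: str | Path | None = None) -> pd.DataFrame:
    """One row per gene; written as TSV when ``path`` is given."""
    df = pd.DataFrame([{
        "gene_id": c.gene_id, "n_promoters": c.n_promoters,
        "wt_induction": round(c.wt_induction, 6),
        "mut_induction": round(c.mut_induction, 6),
        "dependence": c.dependence, "promoter_class": c.promoter_class,
    } for c in classifications], columns=REPORT_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_promoter_counts(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["n_promoters"].astype(int)))
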