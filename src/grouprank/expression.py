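"""Expression-matrix loading and differential-expression testing.

Differential expression uses a per-gene two-sample Student t-test (equal
variance by default; Welch behind a flag) with Bonferroni correction across
all tested genes.  Expression values are assumed to be on log2 scale, the
convention of curated microarray matrices, so the per-gene "log2 ratio
(cancer/control)" is simply the case-mean minus the control-mean; a linear
mode computes ``log2(mean case / mean control)`` instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


class ExpressionError(ValueError):
    """Raised for malformed expression or label inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with a binary case/control label per sample."""

    values: pd.DataFrame          # index: gene symbols, columns: sample IDs
    labels: pd.Series             # sample ID -> "case" | "control"

    def __post_init__(self) -> None:
        labels = self.labels.reindex(self.values.columns)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise ExpressionError(f"samples missing from labels: {missing}")
        bad = set(labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ExpressionError(
                f"unknown class labels {sorted(bad)}; expected "
                f"'{CASE}'/'{CONTROL}'"
            )
        if (labels == CASE).sum() < 2 or (labels == CONTROL).sum() < 2:
            raise ExpressionError("need >= 2 samples in each class")
        if self.values.index.duplicated().any():
            raise ExpressionError("duplicate gene symbols (collapse on load)")
        self.labels = labels

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == CASE]

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == CONTROL]

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.labels)


@dataclass
class DEResult:
    """Per-gene t statistics, p-values and log2 ratios, plus the DE flag.

    ``table`` columns: ``t``, ``p``, ``p_bonferroni``, ``log2_ratio``,
    ``is_de``; index is the gene symbol.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def log2_ratio_of(self, gene: str) -> float:
        return float(self.table.at[gene, "log2_ratio"])


def load_expression(matrix_path, labels_path) -> ExpressionMatrix:
    """Load a TSV expression matrix plus a two-column sample->label map.

    The matrix has a gene-symbol first column and a sample-ID header row.
    The matrix is restricted to samples present in the label file; duplicate
    gene rows are collapsed by their mean so symbols stay unique for network
    matching.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    lab = pd.read_csv(labels_path, sep="\t", header=None, comment="#",
                      names=["sample", "label"], dtype=str)
    labels = pd.Series(lab["label"].values, index=lab["sample"].values)

    known = [c for c in values.columns if c in labels.index]
    missing = [c for c in values.columns if c not in labels.index]
    if missing:
        logger.warning("dropping %d unlabeled samples: %s",
                       len(missing), missing)
    if not known:
        raise ExpressionError("no labeled samples found in matrix")
    values = values[known]

    n_before = len(values)
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).mean()
        logger.info("collapsed %d duplicate gene rows by mean",
                    n_before - len(values))
    logger.info("loaded expression matrix: %d genes x %d samples",
                *values.shape)
    return ExpressionMatrix(values=values, labels=labels.loc[known])


def de_test(
    expr: ExpressionMatrix, alpha: float = 0.05,
    equal_var: bool = True, linear: bool = False,
) -> DEResult:
    """Per-gene Student t-test with Bonferroni correction.

    A gene with zero variance in both classes has an undefined t statistic;
    it is assigned p = 1 (never DE) with a warning.  The Bonferroni
    multiplier is the number of genes tested, and the DE flag is
    ``corrected p < alpha`` (strict).
    """
    case = expr.case_values.to_numpy(dtype=float)
    ctrl = expr.control_values.to_numpy(dtype=float)
    m = case.shape[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)

    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both classes: t undefined, "
            "p set to 1", int(degenerate.sum()),
        )
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    p_bonf = np.minimum(1.0, p * m)
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "p_bonferroni": p_bonf,
            "log2_ratio": log2_ratio(expr, linear=linear).to_numpy(),
            "is_de": p_bonf < alpha,
        },
        index=expr.values.index,
    )
    logger.info("DE test: %d / %d genes pass Bonferroni p < %g",
                int(table["is_de"].sum()), m, alpha)
    return DEResult(table=table, alpha=alpha)


def log2_ratio(expr: ExpressionMatrix, linear: bool = False) -> pd.Series:
    """Per-gene log2 case/control ratio.

    With log2-scale data (default) this is the difference of class means;
    in linear mode it is ``log2(mean case / mean control)``.
    """
    case_mean = expr.case_values.mean(axis=1)
    ctrl_mean = expr.control_values.mean(axis=1)
    if not linear:
        return case_mean - ctrl_mean
    if (case_mean <= 0).any() or (ctrl_mean <= 0).any():
        raise ExpressionError(
            "linear mode requires strictly positive class means"
        )
    return np.log2(case_mean / ctrl_mean)
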