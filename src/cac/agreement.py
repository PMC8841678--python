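"""Multi-reader agreement statistics for measurements and response calls.

For continuous diameter measurements: per-lesion coefficient of variation
(CV), the fraction of lesions with good agreement (CV below a cut-off),
the pairwise Pearson correlation matrix with its per-reader
"correlation with others" summary, and the intraclass correlation
coefficient from the two-way ANOVA decomposition.  For categorical
response calls: Fleiss' kappa with raw percent agreement, and the
fraction of evaluations where a quorum of readers voted the same
category.

Rows (lesions or evaluations) with any missing value are excluded from
every statistic (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORY_ORDER = ("CR", "PR", "SD", "PD")


@dataclass
class RatingsTable:
    """Rows x readers table of measurements (mm) or categories."""

    values: pd.DataFrame  # index: lesion/evaluation ids; columns: reader ids

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 readers are required")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        row_col: str = "lesion_id",
        reader_col: str = "reader_id",
        value_col: str = "value",
    ) -> "RatingsTable":
        wide = df.pivot_table(
            index=row_col, columns=reader_col, values=value_col, aggfunc="first"
        )
        return cls(values=wide)

    def complete(self) -> pd.DataFrame:
        return self.values.dropna(axis=0, how="any")

    @property
    def n_readers(self) -> int:
        return self.values.shape[1]


# --- coefficient of variation ----------------------------------------------

def cv_per_row(values) -> float:
    """Sample CV of repeated measurements: SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean)


def table_cv(table: RatingsTable) -> pd.Series:
    """Per-lesion CV over readers, on complete cases."""
    data = table.complete()
    return data.apply(lambda row: cv_per_row(row.to_numpy()), axis=1)


def good_agreement_fraction(table: RatingsTable, threshold: float = 0.20) -> float:
    """Fraction of lesions whose reader CV is strictly below ``threshold``."""
    cvs = table_cv(table)
    if len(cvs) == 0:
        raise ValueError("no complete rows")
    return float((cvs < threshold).mean())


# --- Pearson correlation ----------------------------------------------------

def summarize_correlation_matrix(matrix: pd.DataFrame) -> dict:
    """Per-reader mean correlation with the other readers, and the grand
    mean with its sample SD over readers.

    This per-reader-mean convention is the one used in multi-reader
    correlation tables that report a "correlation with others" row and a
    single mean +/- SD summary.
    """
    mat = matrix.to_numpy(dtype=float)
    k = mat.shape[0]
    off = mat[~np.eye(k, dtype=bool)].reshape(k, k - 1)
    per_reader = off.mean(axis=1)
    return {
        "per_reader_mean": pd.Series(per_reader, index=matrix.index),
        "grand_mean": float(per_reader.mean()),
        "sd": float(per_reader.std(ddof=1)),
    }


def pearson_matrix(table: RatingsTable) -> dict:
    """Reader-pairwise Pearson matrix plus the per-reader summary.

    A reader with constant measurements has undefined correlations; the
    error names the offending reader.
    """
    data = table.complete()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    for reader in data.columns:
        if data[reader].nunique() <= 1:
            raise ValueError(f"reader {reader!r} is constant; correlation undefined")
    matrix = data.corr(method="pearson")
    return {"matrix": matrix, **summarize_correlation_matrix(matrix)}


# --- intraclass correlation -------------------------------------------------

def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way crossed layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc_two_way_mixed(
    table: RatingsTable,
    variant: str = "icc3",
    on_degenerate: str = "zero",
) -> dict:
    """Single-measure ICC from the two-way ANOVA decomposition.

    ``"icc3"`` is the two-way mixed, consistency form
    ``(MS_rows - MS_err) / (MS_rows + (k-1) MS_err)``; ``"icc2"`` the
    two-way random absolute-agreement form, which additionally charges the
    reader (column) variance.  Returns the coefficient and its
    conventional qualitative band (excellent above 0.75).  A table with no
    between-row variance has no reliability to estimate; per
    ``on_degenerate`` this returns 0 or raises.
    """
    data = table.complete().to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 rows and 2 readers")
    ms_rows, ms_cols, ms_err = _anova_mean_squares(data)
    if ms_rows <= 1e-15 and ms_err <= 1e-15:
        if on_degenerate == "raise":
            raise ValueError("degenerate ANOVA: no variance anywhere")
        return {"icc": 0.0, "band": _icc_band(0.0), "degenerate": True}
    if variant == "icc3":
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    elif variant == "icc2":
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
    else:
        raise ValueError("variant must be 'icc3' or 'icc2'")
    return {"icc": float(icc), "band": _icc_band(float(icc)), "degenerate": False}


def _icc_band(icc: float) -> str:
    if icc > 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


# --- Fleiss' kappa ----------------------------------------------------------

def _category_counts(
    table: np.ndarray, categories: tuple[str, ...]
) -> np.ndarray:
    counts = np.zeros((table.shape[0], len(categories)), dtype=float)
    for j, cat in enumerate(categories):
        counts[:, j] = (table == cat).sum(axis=1)
    if not np.all(counts.sum(axis=1) == table.shape[1]):
        raise ValueError(f"table contains categories outside {categories}")
    return counts


def fleiss_kappa(
    table: RatingsTable | pd.DataFrame | np.ndarray,
    categories: tuple[str, ...] = CATEGORY_ORDER,
) -> dict:
    """Fleiss' kappa and raw percent agreement over categorical calls.

    Percent agreement is the mean over evaluations of the fraction of
    concordant reader pairs; kappa corrects it for chance.  Both are
    reported since summaries of rater studies quote either.  When every
    call is the same category, chance agreement is 1 and kappa is
    undefined: the result flags ``degenerate`` and carries ``nan``.
    """
    if isinstance(table, RatingsTable):
        data = table.complete().to_numpy()
    elif isinstance(table, pd.DataFrame):
        data = table.dropna(axis=0, how="any").to_numpy()
    else:
        data = np.asarray(table)
    n, k = data.shape
    if k < 2 or n < 1:
        raise ValueError("need at least 2 readers and 1 evaluation")
    counts = _category_counts(data, categories)
    p_i = (counts * (counts - 1)).sum(axis=1) / (k * (k - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n * k)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-15:
        return {
            "kappa": float("nan"),
            "percent_agreement": p_bar,
            "degenerate": True,
        }
    return {
        "kappa": float((p_bar - p_e) / (1.0 - p_e)),
        "percent_agreement": p_bar,
        "degenerate": False,
    }


def vote_agreement(
    table: RatingsTable | pd.DataFrame | np.ndarray,
    quorum: float = 0.8,
) -> float:
    """Fraction of evaluations where the modal category reaches the quorum.

    With 5 readers, quorum 0.8 requires at least 4 concordant calls and
    quorum 1.0 unanimity.
    """
    if isinstance(table, RatingsTable):
        data = table.complete().to_numpy()
    elif isinstance(table, pd.DataFrame):
        data = table.dropna(axis=0, how="any").to_numpy()
    else:
        data = np.asarray(table)
    n, k = data.shape
    need = quorum * k - 1e-9
    hits = 0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        if counts.max() >= need:
            hits += 1
    return hits / n


# --- thin group-comparison utilities ---------------------------------------

def wilcoxon_rank_sum(x, y) -> dict:
    stat, p = sps.ranksums(x, y)
    return {"statistic": float(stat), "p_value": float(p)}


def chi_square(contingency: np.ndarray) -> dict:
    res = sps.chi2_contingency(np.asarray(contingency))
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def t_test(x, y) -> dict:
    stat, p = sps.ttest_ind(x, y)
    return {"statistic": float(stat), "p_value": float(p)}
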