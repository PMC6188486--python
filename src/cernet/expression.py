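"""Expression matrices, normalization, and differential-expression filters.

The analysis starts from per-class count tables (mRNA, miRNA, circRNA) for a
two-group design.  Features with counts below 2 in every sample are
removed, counts are library-size normalized (CPM, or TPM when feature
lengths are known), and features are called differentially expressed when
the fold change exceeds 2 (|log2FC| > 1, strict) and the p-value passes 0.05.

The canonical route supplies precomputed (log2FC, p) tables from a dedicated
DE engine; a built-in Welch t-test on log2(CPM + 1) is provided as a simple
two-group stand-in so fully synthetic runs are self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEThresholds",
    "normalize",
    "filter_low_counts",
    "test_de",
    "filter_de",
    "read_counts",
    "read_de_table",
]

PSEUDO_CPM = 1.0  # pseudo-count on the CPM scale for fold-change stability


@dataclass
class ExpressionMatrix:
    """Feature-by-sample value table with group labels.

    ``values``: DataFrame, index = feature ids, columns = sample ids.
    ``groups``: mapping sample id -> "case" | "control".
    ``feature_class``: the RNA class of every feature (mRNA/miRNA/circRNA),
    either one string for the whole matrix or a per-feature Series.
    ``unit``: "counts", "CPM" or "TPM".
    """

    values: pd.DataFrame
    groups: dict[str, str]
    feature_class: str | pd.Series = "mRNA"
    unit: str = "counts"
    lengths: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if set(self.groups.values()) - {"case", "control"}:
            raise ValueError("group labels must be 'case' or 'control'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if isinstance(self.feature_class, pd.Series) and not self.feature_class.index.equals(
            self.values.index
        ):
            raise ValueError("feature_class index must match feature ids")

    def class_of(self, feature_id: str) -> str:
        if isinstance(self.feature_class, str):
            return self.feature_class
        return self.feature_class.loc[feature_id]

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(counts_path, sample_sheet_path, feature_class: str = "mRNA") -> ExpressionMatrix:
    """Read a counts TSV (feature_id + one column per sample) and a sample
    sheet TSV (sample_id, group)."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"]))
    return ExpressionMatrix(values=values, groups=groups, feature_class=feature_class)


def normalize(matrix: ExpressionMatrix, mode: str = "CPM", lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Library-size normalization: every sample column rescales to 1e6.

    TPM first divides each count by the feature length (a per-feature rate),
    then rescales; it therefore needs positive lengths for all features.
    """
    if matrix.unit != "counts":
        raise ValueError(f"normalize expects counts, got unit={matrix.unit!r}")
    if mode not in {"CPM", "TPM"}:
        raise ValueError("mode must be 'CPM' or 'TPM'")
    vals = matrix.values.astype(float)
    if mode == "TPM":
        lengths = lengths if lengths is not None else matrix.lengths
        if lengths is None:
            raise ValueError("TPM normalization requires feature lengths")
        lengths = lengths.reindex(vals.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("TPM requires a positive length for every feature")
        vals = vals.div(lengths, axis=0)
    libsize = vals.sum(axis=0)
    zero = libsize[libsize == 0].index.tolist()
    if zero:
        raise ValueError(f"zero library size in sample(s): {zero}")
    out = vals.div(libsize, axis=1) * 1e6
    return replace(matrix, values=out, unit=mode)


def filter_low_counts(matrix: ExpressionMatrix, min_count: int = 2) -> ExpressionMatrix:
    """Remove features whose count is below ``min_count`` in every sample."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if matrix.unit != "counts":
        raise ValueError("low-count filtering applies to raw counts")
    keep = (matrix.values >= min_count).any(axis=1)
    removed = matrix.values.index[~keep].tolist()
    if removed:
        logger.info("low-count filter removed %d features", len(removed))
    fc = matrix.feature_class
    if isinstance(fc, pd.Series):
        fc = fc[keep]
    lengths = matrix.lengths[keep] if matrix.lengths is not None else None
    return replace(matrix, values=matrix.values[keep], feature_class=fc, lengths=lengths)


def _welch_log_cpm(case: np.ndarray, ctrl: np.ndarray) -> float:
    res = stats.ttest_ind(case, ctrl, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):
        # zero variance in both groups: identical means are a perfect null,
        # different constant levels a certain difference
        return 1.0 if np.isclose(case.mean(), ctrl.mean()) else 0.0
    return p


def test_de(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Two-group differential-expression scores for every feature.

    log2FC = log2((mean case CPM + 1) / (mean control CPM + 1)); p from a
    Welch t-test on log2(CPM + 1).  This is a simple stand-in for a
    dedicated count-model DE engine — precomputed tables are the first-class
    input (see :func:`read_de_table`).  Returns a DataFrame with columns
    feature_id, feature_class, log2fc, p_value, status (all NS).
    """
    cpm = matrix if matrix.unit == "CPM" else normalize(matrix, "CPM")
    case_cols = matrix.samples("case")
    ctrl_cols = matrix.samples("control")
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            "built-in test needs >= 2 samples per group; supply a precomputed "
            "DE table instead (read_de_table)"
        )
    case = cpm.values[case_cols].to_numpy(float)
    ctrl = cpm.values[ctrl_cols].to_numpy(float)
    log2fc = np.log2(case.mean(axis=1) + PSEUDO_CPM) - np.log2(
        ctrl.mean(axis=1) + PSEUDO_CPM
    )
    log_case = np.log2(case + 1.0)
    log_ctrl = np.log2(ctrl + 1.0)
    pvals = np.array(
        [_welch_log_cpm(log_case[i], log_ctrl[i]) for i in range(len(log2fc))]
    )
    fc = matrix.feature_class
    classes = fc if isinstance(fc, str) else fc.to_numpy()
    return pd.DataFrame(
        {
            "feature_id": cpm.values.index,
            "feature_class": classes,
            "log2fc": log2fc,
            "p_value": pvals,
            "status": "NS",
        }
    ).reset_index(drop=True)


def read_de_table(path) -> pd.DataFrame:
    """Load a precomputed DE table TSV (feature_id, feature_class, log2fc,
    p_value) — the canonical input when a dedicated DE engine was run."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    required = {"feature_id", "feature_class", "log2fc", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE table columns: {sorted(missing)}")
    df["status"] = "NS"
    return df


@dataclass(frozen=True)
class DEThresholds:
    """Fold change > 2 means |log2FC| strictly greater than 1; the p cut is
    inclusive (<= 0.05) by default, with ``p_strict`` for the strict variant."""

    min_abs_log2fc: float = 1.0
    max_p: float = 0.05
    p_strict: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0:
            raise ValueError("min_abs_log2fc must be positive")
        if not 0 < self.max_p < 1:
            raise ValueError("max_p must be in (0, 1)")

    def p_passes(self, p) -> bool:
        return p < self.max_p if self.p_strict else p <= self.max_p


def filter_de(
    records: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Annotate DE status and return (up ids, down ids, annotated table).

    UP iff log2FC > threshold (strict) and the p-value passes; DOWN iff
    log2FC < -threshold; everything else NS.  Idempotent on its own output.
    """
    df = records.copy()
    if df["log2fc"].isna().any() or np.isinf(df["log2fc"]).any():
        raise ValueError("log2fc must be finite")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValueError("p_value must lie in [0, 1]")
    p_ok = df["p_value"].map(thresholds.p_passes)
    up = p_ok & (df["log2fc"] > thresholds.min_abs_log2fc)
    down = p_ok & (df["log2fc"] < -thresholds.min_abs_log2fc)
    df["status"] = np.where(up, "UP", np.where(down, "DOWN", "NS"))
    return (
        set(df.loc[up, "feature_id"]),
        set(df.loc[down, "feature_id"]),
        df,
    )
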