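"""Reproducibility, flux and differential-abundance statistics.

Operates on the protein x sample matrices produced by
:mod:`prmflux.quantify` (and on peptide ratio tables for QC). Definitions
follow the assay conventions:

* CV% = 100 * sample sd / mean, computed on the linear scale; technical CVs
  are computed within each biological sample and averaged across samples.
* autophagy flux of a protein in a condition = mean abundance with lysosomal
  inhibition (+BafA1) / mean abundance without (-BafA1); significance from a
  two-sided unpaired t-test between the arms.
* differential abundance across treatments via one-way ANOVA on log2 values,
  retaining proteins with p strictly below alpha (default 0.01).
* peptide-correlation QC: pairwise Pearson correlation of log2 ratios of
  peptides from the same protein.
* hierarchical clustering of the z-scored matrix (Euclidean distance,
  complete linkage) for heatmap ordering.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.special import gammaln

from .quantify import ProteinQuantMatrix

__all__ = [
    "cv",
    "c4_correction",
    "CVReport",
    "technical_cv_report",
    "biological_cv_report",
    "FluxResult",
    "flux",
    "anova_filter",
    "CorrelationQC",
    "peptide_correlation_qc",
    "ClusterResult",
    "cluster_matrix",
]


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean.

    Requires at least two finite values; returns NaN (undefined) when the
    mean is not positive. The sd uses the n-1 denominator.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("cv requires at least 2 finite values")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def c4_correction(n: int) -> float:
    """Unbiasing constant c4(n) for the sample standard deviation.

    For normal data E[s] = c4(n) * sigma; with triplicates c4 ~= 0.886, so an
    average of raw triplicate CVs underestimates the underlying CV by ~11%.
    Dividing by c4 removes that small-sample bias.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))


@dataclass
class CVReport:
    """Per-entity CV% values with a summary.

    ``table`` has one row per entity (protein or peptide) with its average
    CV%; ``summary`` holds mean/median/min/max over entities.
    """

    level: str  # "protein" | "peptide"
    scope: str  # "technical" | "biological"
    table: pd.DataFrame
    summary: dict[str, float] = field(default_factory=dict)
    bias_corrected: bool = True

    def __post_init__(self) -> None:
        vals = self.table["cv_percent"].dropna()
        if len(vals) and not self.summary:
            self.summary = {
                "mean": float(vals.mean()),
                "median": float(vals.median()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(len(vals)),
            }


def _grouped_cv(
    values: pd.DataFrame, groups: list[list[str]], bias_correction: bool
) -> pd.Series:
    """Average CV% per row over replicate groups with >= 2 measured values."""
    out = {}
    for entity in values.index:
        cvs = []
        for cols in groups:
            vals = values.loc[entity, cols].astype(float).dropna()
            if len(vals) < 2 or vals.mean() <= 0:
                continue
            c = 100.0 * vals.std(ddof=1) / vals.mean()
            if bias_correction:
                c /= c4_correction(len(vals))
            cvs.append(c)
        out[entity] = float(np.mean(cvs)) if cvs else float("nan")
    return pd.Series(out, name="cv_percent")


def technical_cv_report(
    matrix: ProteinQuantMatrix, *, bias_correction: bool = True
) -> CVReport:
    """Protein-level technical CVs: within each biological sample, averaged.

    Technical replicates of one (condition, bafa1, bio_rep) group measure the
    same material, so their spread is pure LC-MS noise. Per protein, the CV%
    is computed within each group (>= 2 measured replicates required) and
    averaged across groups. ``bias_correction`` (default on) divides each CV
    by the c4 constant so the report estimates the underlying technical CV
    without the small-n downward bias of the sd estimator.
    """
    design = matrix.design
    if "tech_rep" not in design.columns:
        raise ValueError("technical CVs need a run-level matrix with tech_rep")
    groups = [
        [s for s in grp.index if s in matrix.values.columns]
        for _, grp in design.groupby(["condition", "bafa1", "bio_rep"], sort=True)
    ]
    measured = matrix.values.where(matrix.status == "measured")
    table = _grouped_cv(measured, groups, bias_correction).to_frame()
    return CVReport("protein", "technical", table, bias_corrected=bias_correction)


def biological_cv_report(
    matrix: ProteinQuantMatrix, *, bias_correction: bool = True
) -> CVReport:
    """Protein-level CVs across biological replicates within each condition."""
    design = matrix.design
    if "tech_rep" in design.columns:
        raise ValueError("biological CVs operate on a technical-averaged matrix")
    groups = [
        [s for s in grp.index if s in matrix.values.columns]
        for _, grp in design.groupby(["condition", "bafa1"], sort=True)
    ]
    measured = matrix.values.where(matrix.status == "measured")
    table = _grouped_cv(measured, groups, bias_correction).to_frame()
    return CVReport("protein", "biological", table, bias_corrected=bias_correction)


@dataclass
class FluxResult:
    """Autophagy flux of one protein in one condition."""

    protein: str
    condition: str
    flux: float
    p_value: float
    n_plus: int
    n_minus: int


def _ttest_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Unpaired two-sided t-test p-value with degenerate-case handling."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b).pvalue)


def flux(
    matrix: ProteinQuantMatrix, condition: str
) -> tuple[list[FluxResult], list[dict]]:
    """Flux per protein: mean(+BafA1) / mean(-BafA1) within ``condition``.

    Uses measured and imputed cells. Proteins with an empty arm are skipped;
    the second return value lists them with a reason. The p-value is a
    two-sided unpaired t-test between the two arms' replicate values (a
    zero-variance tie reports p = 1.0).
    """
    design = matrix.design
    plus_cols = [
        s for s in design.index[(design["condition"] == condition) & design["bafa1"]]
        if s in matrix.values.columns
    ]
    minus_cols = [
        s for s in design.index[(design["condition"] == condition) & ~design["bafa1"].astype(bool)]
        if s in matrix.values.columns
    ]
    if not plus_cols or not minus_cols:
        raise ValueError(f"condition {condition!r} lacks a +/-BafA1 arm")
    usable = matrix.values.where(matrix.status != "missing")
    results: list[FluxResult] = []
    skipped: list[dict] = []
    for protein in usable.index:
        a = usable.loc[protein, plus_cols].astype(float).dropna().to_numpy()
        b = usable.loc[protein, minus_cols].astype(float).dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            skipped.append(
                {"protein": protein, "condition": condition, "reason": "missing_arm"}
            )
            continue
        if b.mean() <= 0:
            skipped.append(
                {"protein": protein, "condition": condition,
                 "reason": "nonpositive_reference_mean"}
            )
            continue
        p = _ttest_two_sided(a, b) if a.size >= 2 and b.size >= 2 else float("nan")
        results.append(
            FluxResult(
                protein=str(protein), condition=condition,
                flux=float(a.mean() / b.mean()), p_value=p,
                n_plus=int(a.size), n_minus=int(b.size),
            )
        )
    return results, skipped


def anova_filter(
    matrix: ProteinQuantMatrix,
    alpha: float = 0.01,
    *,
    use_log2: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """One-way ANOVA across treatment groups; retain p < alpha (strict).

    Treatment groups are the (condition, bafa1) combinations of the design.
    Values (measured or imputed) are log2-transformed by default, since
    heavy-normalized abundances are ratio-scale. Proteins without >= 2 groups
    of >= 2 replicates are excluded with reason ``"insufficient_replication"``.
    Returns the retained protein list and a table with p-values and reasons.
    """
    design = matrix.design
    group_cols = [
        [s for s in grp.index if s in matrix.values.columns]
        for _, grp in design.groupby(["condition", "bafa1"], sort=True)
    ]
    usable = matrix.values.where(matrix.status != "missing")
    rows = []
    retained: list[str] = []
    for protein in usable.index:
        arrays = []
        for cols in group_cols:
            vals = usable.loc[protein, cols].astype(float).dropna().to_numpy()
            if vals.size >= 2:
                arrays.append(np.log2(vals) if use_log2 else vals)
        if len(arrays) < 2:
            rows.append({"protein": protein, "p_value": np.nan,
                         "retained": False, "reason": "insufficient_replication"})
            continue
        grand = np.concatenate(arrays)
        if np.ptp(grand) == 0:
            p = 1.0  # identical everywhere: no evidence of any difference
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(sps.f_oneway(*arrays).pvalue)
            if not np.isfinite(p):
                # zero within-group variance with differing means
                means = [a.mean() for a in arrays]
                p = 0.0 if np.ptp(means) > 0 else 1.0
        keep = p < alpha
        rows.append({"protein": protein, "p_value": p, "retained": keep,
                     "reason": None})
        if keep:
            retained.append(str(protein))
    return retained, pd.DataFrame(rows)


@dataclass
class CorrelationQC:
    """Pairwise peptide correlations per protein."""

    pairs: pd.DataFrame  # protein, peptide_a, peptide_b, n_samples, r
    median_r: float
    low_pairs: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)


def peptide_correlation_qc(
    peptides: pd.DataFrame,
    *,
    min_shared: int = 3,
    low_threshold: float = 0.5,
) -> CorrelationQC:
    """Pearson correlation of log2 peptide ratios within each protein.

    Peptides carrying a sub-stoichiometric modification, an interference or
    mostly-noise signal decorrelate from their siblings; pairs with
    r < ``low_threshold`` are listed for review. Pairs need >= ``min_shared``
    samples with finite ratios in both peptides; constant vectors are
    skipped with a reason.
    """
    valid = peptides[peptides["valid"] & np.isfinite(peptides["ratio"])]
    rows, skipped = [], []
    for protein, grp in valid.groupby("protein", sort=True):
        wide = grp.pivot_table(index="sample", columns="peptide", values="ratio")
        if wide.shape[1] < 2:
            continue
        for pa, pb in itertools.combinations(sorted(wide.columns), 2):
            pair = wide[[pa, pb]].dropna()
            if len(pair) < min_shared:
                skipped.append({"protein": protein, "pair": (pa, pb),
                                "reason": "lt_min_shared"})
                continue
            x = np.log2(pair[pa].to_numpy())
            y = np.log2(pair[pb].to_numpy())
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped.append({"protein": protein, "pair": (pa, pb),
                                "reason": "constant_vector"})
                continue
            r = float(sps.pearsonr(x, y).statistic)
            rows.append({"protein": protein, "peptide_a": pa, "peptide_b": pb,
                         "n_samples": len(pair), "r": r})
    pairs = pd.DataFrame(rows, columns=["protein", "peptide_a", "peptide_b",
                                        "n_samples", "r"])
    median_r = float(pairs["r"].median()) if len(pairs) else float("nan")
    low = pairs[pairs["r"] < low_threshold].reset_index(drop=True)
    return CorrelationQC(pairs=pairs, median_r=median_r, low_pairs=low,
                         skipped=skipped)


@dataclass
class ClusterResult:
    """Hierarchical clustering of the z-scored protein matrix."""

    zscores: pd.DataFrame  # ordered rows x ordered columns
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    excluded_rows: list[str] = field(default_factory=list)


def cluster_matrix(
    values: pd.DataFrame | ProteinQuantMatrix,
    *,
    zscore: bool = True,
    method: str = "complete",
    metric: str = "euclidean",
    cluster_columns: bool = True,
) -> ClusterResult:
    """Agglomerative clustering for heatmap ordering.

    Rows are z-scored (mean 0, sd 1 with the n-1 denominator) so clustering
    reflects abundance *profiles*, not magnitudes; zero-variance rows cannot
    be z-scored and are excluded with a warning. Complete linkage on
    Euclidean distances, deterministic ordering (scipy's leaf order; ties
    resolved by input order).

    Requires a complete matrix (run after imputation).
    """
    if isinstance(values, ProteinQuantMatrix):
        if (values.status == "missing").any().any():
            raise ValueError("matrix contains missing cells; impute first")
        values = values.values
    if values.isna().any().any():
        raise ValueError("matrix contains NaN cells; impute first")
    X = values.astype(float)
    if zscore:
        sd = X.std(axis=1, ddof=1)
        excluded = list(X.index[(sd == 0) | sd.isna()])
        if excluded:
            warnings.warn(f"zero-variance rows excluded from clustering: {excluded}")
            X = X.drop(index=excluded)
            sd = sd.drop(index=excluded)
        X = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        excluded = []
    if len(X) < 2:
        raise ValueError("need at least 2 rows to cluster")
    row_linkage = sch.linkage(X.to_numpy(), method=method, metric=metric)
    row_order = [X.index[i] for i in sch.leaves_list(row_linkage)]
    col_linkage = None
    col_order = list(X.columns)
    if cluster_columns and X.shape[1] >= 2:
        col_linkage = sch.linkage(X.to_numpy().T, method=method, metric=metric)
        col_order = [X.columns[i] for i in sch.leaves_list(col_linkage)]
    ordered = X.loc[row_order, col_order]
    return ClusterResult(
        zscores=ordered, row_linkage=row_linkage, col_linkage=col_linkage,
        row_order=[str(r) for r in row_order], col_order=[str(c) for c in col_order],
        excluded_rows=[str(r) for r in excluded],
    )
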