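"""Albumin-referenced relative quantitation and trimester kinetics.

Label-free LC-MS spectral counts are expressed relative to the albumin
channel of the same serum sample (albumin is assumed pregnancy-invariant),
then summarised per trimester and classified into the four trajectory
categories used for pregnancy-related-protein screening:

* category 1 -- relative amount more than doubled over the first-trimester
  base level, or was undetectable at baseline and later reached >= 1;
  ``1a`` peaks in the second trimester, ``1b`` in the third;
* category 2 -- relative amount dropped below half the base level, or from
  a detectable baseline to undetectable; ``2a`` bottoms in the second
  trimester, ``2b`` in the third;
* ``unchanged`` otherwise.

"Undetectable" means exactly zero after normalisation (hard zeros are what
spectral counting produces below the detection limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "UndefinedClassificationError",
    "SpectralCountTable",
    "AbundanceTable",
    "TrajectoryCategory",
    "PCAResult",
    "normalize_to_reference",
    "classify_trajectory",
    "trimester_ttest",
    "trimester_summary",
    "pca_projection",
]

TRIMESTERS = (1, 2, 3)


class ConfigurationError(ValueError):
    """Invalid table/reference configuration (e.g. missing albumin row)."""


class UndefinedClassificationError(ValueError):
    """Trajectory classification requested with no usable trimester means."""


def _check_design(values: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ConfigurationError(f"samples absent from design table: {missing}")
    if "trimester" not in design.columns:
        raise ConfigurationError("design table needs a 'trimester' column")
    bad = set(design.loc[list(values.columns), "trimester"]) - set(TRIMESTERS)
    if bad:
        raise ConfigurationError(f"trimester values outside 1-3: {sorted(bad)}")


@dataclass
class SpectralCountTable:
    """Protein x sample spectral counts plus the study design.

    ``counts`` is indexed by protein identifier with one column per sample;
    ``design`` is indexed by sample with at least a ``trimester`` column
    (``subject`` and ``species`` columns are carried through when present).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    names: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_design(self.counts, self.design)
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ConfigurationError("spectral counts must be nonnegative")


@dataclass
class AbundanceTable:
    """Reference-scaled relative amounts (same shape as the count table).

    The reference row equals ``scale`` in every valid sample.  Samples in
    which the reference protein was itself undetected cannot be normalised
    and are listed in ``invalid_samples`` (their cells are NaN).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    reference_id: str
    scale: float
    invalid_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_design(self.values, self.design)

    def valid_values(self) -> pd.DataFrame:
        return self.values.drop(columns=self.invalid_samples)


def normalize_to_reference(
    table: SpectralCountTable, reference_id: str, scale: float = 100.0
) -> AbundanceTable:
    """Express every count relative to the reference (albumin) channel.

    cell = scale * count / reference_count, per sample.  A sample whose
    reference count is zero is flagged invalid rather than dropped.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    if reference_id not in table.counts.index:
        raise ConfigurationError(f"reference protein {reference_id!r} not in table")
    ref = table.counts.loc[reference_id].astype(float)
    invalid = [s for s in table.counts.columns if ref[s] <= 0]
    if invalid:
        warnings.warn(
            f"reference count is zero in samples {invalid}; flagged invalid",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = scale * table.counts.astype(float).div(ref, axis=1)
    values[invalid] = np.nan
    return AbundanceTable(
        values=values,
        design=table.design,
        reference_id=reference_id,
        scale=float(scale),
        invalid_samples=invalid,
    )


@dataclass(frozen=True)
class TrajectoryCategory:
    """Trajectory label plus a human-readable trace of the clause that fired."""

    label: str  # one of {"1a", "1b", "2a", "2b", "unchanged"}
    trace: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def classify_trajectory(mean1, mean2, mean3) -> TrajectoryCategory:
    """Classify a (mean1, mean2, mean3) trimester trajectory.

    Pure function of the three means; the increase clause (category 1) is
    tested before the decrease clause (category 2), mirroring the order the
    rules are stated in.  A missing mean (``None``/NaN, e.g. a trimester
    with no samples) is simply excluded; mean1 and at least one later mean
    must be present.
    """
    means = {1: mean1, 2: mean2, 3: mean3}
    present = {t: float(v) for t, v in means.items() if not _missing(v)}
    if any(v < 0 for v in present.values()):
        raise ValueError("trimester means must be nonnegative")
    later = {t: v for t, v in present.items() if t > 1}
    if 1 not in present or not later:
        raise UndefinedClassificationError(
            "need the first-trimester mean and at least one later mean"
        )
    m1 = present[1]
    max_later = max(later.values())
    min_later = min(later.values())

    # Category 1: increase.
    if (m1 > 0 and max_later / m1 > 2.0) or (m1 == 0 and max_later >= 1.0):
        clause = (
            f"max(later)/mean1={max_later / m1:.3g}>2"
            if m1 > 0
            else f"mean1=0 and max(later)={max_later:.3g}>=1"
        )
        if 2 in present and present[2] == max(present.values()):
            return TrajectoryCategory("1a", f"category1 ({clause}); peak at 2nd -> 1a")
        return TrajectoryCategory("1b", f"category1 ({clause}); peak at 3rd -> 1b")

    # Category 2: decrease (only defined from a detectable baseline).
    if m1 > 0 and (min_later / m1 < 0.5 or min_later == 0):
        clause = f"min(later)/mean1={min_later / m1:.3g}<0.5"
        if 2 in present and present[2] == min(present.values()):
            return TrajectoryCategory("2a", f"category2 ({clause}); minimum at 2nd -> 2a")
        return TrajectoryCategory("2b", f"category2 ({clause}); minimum at 3rd -> 2b")

    return TrajectoryCategory("unchanged", "neither clause fired -> unchanged")


def trimester_ttest(samples_a, samples_b, variant: str = "welch") -> float:
    """Two-sample two-tailed t-test between two trimester sample groups.

    ``variant`` selects Welch (default) or the equal-variance (Student)
    statistic.  Returns NaN (with a warning) for groups of fewer than two
    values or fully degenerate data (both groups constant and equal), where
    the statistic is undefined.
    """
    if variant not in ("welch", "equal-variance"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(list(samples_a), dtype=float)
    b = np.asarray(list(samples_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        warnings.warn("t-test needs >=2 values per group; p absent", stacklevel=2)
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("degenerate t-test (both groups constant); p absent", stacklevel=2)
            return float("nan")
        return 0.0  # constant but different groups: infinitely separated
    res = stats.ttest_ind(a, b, equal_var=(variant == "equal-variance"))
    return float(res.pvalue)


def trimester_summary(
    table: AbundanceTable, ttest_variant: str = "welch", classify: bool = True
) -> pd.DataFrame:
    """Per-protein trimester means, fold ratios, t-tests and categories.

    Means are arithmetic means over the samples available in each trimester
    (missing cells, e.g. a premature birth, reduce ``n_t``, they are not
    zeros).  Ratios are computed from the full-precision means and also
    reported rounded to two decimals, the table print format; they are only
    defined for a detectable baseline (mean1 > 0), otherwise NaN with the
    undetectable-baseline flag set.
    """
    values = table.valid_values()
    tri_of = table.design["trimester"]
    groups = {t: [s for s in values.columns if tri_of[s] == t] for t in TRIMESTERS}
    rows = []
    for protein, row in values.iterrows():
        rec: dict[str, object] = {"protein": protein}
        means: dict[int, float] = {}
        obs: dict[int, np.ndarray] = {}
        for t in TRIMESTERS:
            x = row[groups[t]].dropna().to_numpy(dtype=float)
            obs[t] = x
            rec[f"n{t}"] = len(x)
            means[t] = float(x.mean()) if len(x) else float("nan")
            rec[f"mean{t}"] = means[t]
        m1 = means[1]
        baseline_undetectable = m1 == 0
        rec["baseline_undetectable"] = baseline_undetectable
        for t in (2, 3):
            ratio = means[t] / m1 if m1 > 0 and not np.isnan(means[t]) else float("nan")
            rec[f"ratio{t}1"] = ratio
            rec[f"ratio{t}1_2dp"] = round(ratio, 2) if not np.isnan(ratio) else float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec["p21"] = trimester_ttest(obs[1], obs[2], ttest_variant) if min(len(obs[1]), len(obs[2])) >= 2 else float("nan")
            rec["p31"] = trimester_ttest(obs[1], obs[3], ttest_variant) if min(len(obs[1]), len(obs[3])) >= 2 else float("nan")
        if classify:
            cat = classify_trajectory(means[1], means[2], means[3])
            rec["category"] = cat.label
            rec["rule_trace"] = cat.trace
        rows.append(rec)
    return pd.DataFrame(rows).set_index("protein")


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (proteins x components) and
    the explained-variance fraction of each retained component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scaling: str


def pca_projection(
    table: AbundanceTable, scaling: str = "unit-variance", n_components: int | None = None
) -> PCAResult:
    """PCA of samples over protein variables (chemometrics orientation).

    Columns (proteins) are mean-centred and, with the default
    ``unit-variance`` scaling, divided by their standard deviation, which is
    the default of the PCA tool this mirrors; constant proteins carry no
    information and are left at zero.  Scores are the projections of the
    samples on the eigenvectors of the processed matrix, ordered by
    explained variance; at most ``min(n_samples - 1, n_proteins)``
    components are retained.
    """
    if scaling not in ("unit-variance", "center-only"):
        raise ValueError(f"unknown scaling {scaling!r}")
    values = table.valid_values()
    X = values.T.to_numpy(dtype=float)  # samples x proteins
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 proteins")
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if not np.any(sd > 0):
        raise ValueError("constant matrix: no principal components exist")
    if scaling == "unit-variance":
        Xc = np.where(sd > 0, Xc / np.where(sd > 0, sd, 1.0), 0.0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p)
    if n_components is not None:
        k = min(k, int(n_components))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: the largest-magnitude loading of each PC is positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=values.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=comp),
        explained_variance_ratio=evr,
        scaling=scaling,
    )
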