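"""Two-sample statistics, permutation FDR, and the splicing-discordance caller.

The differential branch mirrors a classical label-free workflow: per protein
group, a two-sided equal-variance (pooled) Student's t-test between cohorts
on normalized log2 areas, a significance filter of p < ``p_de`` combined with
a fold change of at least ``fc_de``, and a permutation-based FDR estimate
obtained by recomputing all test p-values under random cohort-label
permutations.

The isoform branch contrasts, within each multi-isoform family, the
``SHARED_ISOFORMS`` (common) group — which tracks total protein abundance —
against each ``ISOFORM_SPECIFIC`` group.  A family is called
``SPLICING_DISCORDANT`` when a specific group shifts strongly and
significantly (p < ``p_iso``) *relative to* the common group while the common
group itself does not pass the abundance filter: the proteomic signature of
an isoform-usage change rather than a whole-protein change.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .digest import IsoformCatalog
from .errors import (
    DegenerateVarianceError,
    DesignError,
    InsufficientDataError,
)
from .io_formats import AnalysisThresholds, SampleDesign
from .isoform_mapping import MULTI_FAMILY, PeptideClass
from .normalization import NormalizedMatrix

__all__ = [
    "students_t",
    "permutation_fdr",
    "differential_abundance",
    "call_isoform_discordance",
    "pca_qc",
    "compare_proportions",
    "PCAResult",
    "ProportionComparison",
]


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------

def students_t(values_a, values_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test.

    Degenerate limits: both groups constant with equal means gives
    ``(0.0, 1.0)``; both constant with different means has no defined t and
    raises :class:`DegenerateVarianceError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if var_a == 0.0 and var_b == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "both groups have zero variance with unequal means"
        )
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / df
    t = diff / math.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _group_moments(filled: np.ndarray, mask: np.ndarray, cols: np.ndarray):
    """Count, mean and sample variance per feature over ``cols`` (nan-aware)."""
    sub = filled[:, cols]
    obs = mask[:, cols]
    n = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sub.sum(axis=1) / n
        ss = (sub**2).sum(axis=1)
        var = (ss - n * mean**2) / (n - 1)
    return n, mean, np.clip(var, 0.0, None)


def _t_pvalues(
    filled: np.ndarray,
    mask: np.ndarray,
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    min_obs: int,
):
    """Vectorised pooled t-test over all features.

    Returns (t, p, n_a, n_b, mean_a, mean_b); p is NaN where a feature has
    fewer than ``min_obs`` observations in either group; features constant
    across both groups get t = 0, p = 1.
    """
    n_a, mean_a, var_a = _group_moments(filled, mask, cols_a)
    n_b, mean_b, var_b = _group_moments(filled, mask, cols_b)
    valid = (n_a >= min_obs) & (n_b >= min_obs)
    df = n_a + n_b - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    diff = mean_a - mean_b
    degenerate = valid & (pooled == 0.0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff == 0.0), 0.0, t)
        t = np.where(degenerate & (diff != 0.0), np.inf * np.sign(diff), t)
    p = np.full(t.shape, np.nan)
    with np.errstate(invalid="ignore"):
        p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    p[degenerate & (diff == 0.0)] = 1.0
    p[degenerate & (diff != 0.0)] = 0.0
    return t, p, n_a, n_b, mean_a, mean_b


# ---------------------------------------------------------------------------
# permutation-based FDR
# ---------------------------------------------------------------------------

def _label_splits(n: int, n_a: int, n_perm: int, seed: int) -> list[np.ndarray]:
    """Cohort-A column index sets for each permutation.

    When the number of distinct label splits is at most ``n_perm``, all
    splits are enumerated exhaustively; otherwise ``n_perm`` splits are
    sampled with a seeded generator.
    """
    total = math.comb(n, n_a)
    if total <= n_perm:
        return [np.asarray(c, dtype=int) for c in itertools.combinations(range(n), n_a)]
    rng = np.random.default_rng(seed)
    return [rng.permutation(n)[:n_a] for _ in range(n_perm)]


def permutation_fdr(
    matrix: NormalizedMatrix | pd.DataFrame,
    design: SampleDesign,
    thresholds: AnalysisThresholds,
) -> pd.Series:
    """Permutation-based FDR (q-value) per protein group.

    For each group's observed p, q is the mean number of permutation-null
    p-values at or below it per permutation, divided by the observed number
    of p-values at or below it, clipped to [0, 1] and made monotone
    nondecreasing in p.  Cohort labels are permuted; exhaustive enumeration
    replaces sampling whenever feasible.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if len(design.samples_a) < 2 or len(design.samples_b) < 2:
        raise DesignError("each cohort needs at least 2 samples")
    values = values[design.samples]
    X = values.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    filled = np.where(mask, X, 0.0)
    samples = list(values.columns)
    cols_a = np.asarray([samples.index(s) for s in design.samples_a])
    cols_b = np.asarray([samples.index(s) for s in design.samples_b])
    min_obs = thresholds.min_obs_per_group

    _, p_obs, *_ = _t_pvalues(filled, mask, cols_a, cols_b, min_obs)
    observed = ~np.isnan(p_obs)
    q = np.full(p_obs.shape, np.nan)
    if observed.sum() == 0:
        return pd.Series(q, index=values.index, name="q")

    n = len(samples)
    splits = _label_splits(n, len(cols_a), thresholds.permutations, thresholds.seed)
    n_perm = len(splits)
    all_cols = np.arange(n)
    null_ps: list[np.ndarray] = []
    for cols in splits:
        comp = np.setdiff1d(all_cols, cols, assume_unique=True)
        _, p_null, *_ = _t_pvalues(filled, mask, cols, comp, min_obs)
        null_ps.append(p_null[~np.isnan(p_null)])
    null_flat = np.sort(np.concatenate(null_ps))

    p_t = p_obs[observed]
    obs_sorted = np.sort(p_t)
    n_null_le = np.searchsorted(null_flat, p_t, side="right") / n_perm
    n_obs_le = np.searchsorted(obs_sorted, p_t, side="right")
    q_t = np.clip(n_null_le / n_obs_le, 0.0, 1.0)

    order = np.argsort(p_t, kind="stable")
    q_t[order] = np.maximum.accumulate(q_t[order])
    q[observed] = q_t
    return pd.Series(q, index=values.index, name="q")


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "group_id",
    "accessions",
    "family",
    "pclass",
    "n_peptides",
    "n_A",
    "n_B",
    "mean_A",
    "mean_B",
    "log2fc",
    "fold",
    "direction",
    "t_stat",
    "p",
    "q",
    "testable",
    "significant",
]


def differential_abundance(
    matrix: NormalizedMatrix,
    design: SampleDesign,
    thresholds: AnalysisThresholds,
    *,
    compute_q: bool = True,
) -> pd.DataFrame:
    """Per-group two-sample statistics with the p/fold significance filter.

    Returns one record per group sorted by p (untestable groups last with
    NaN statistics).  ``significant`` is ``p < p_de`` and ``fold >= fc_de``;
    fold is ``2**|log2fc|`` with a direction label relative to cohort B.
    """
    values = matrix.values[design.samples]
    X = values.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    filled = np.where(mask, X, 0.0)
    samples = list(values.columns)
    cols_a = np.asarray([samples.index(s) for s in design.samples_a])
    cols_b = np.asarray([samples.index(s) for s in design.samples_b])
    min_obs = thresholds.min_obs_per_group

    t, p, n_a, n_b, mean_a, mean_b = _t_pvalues(filled, mask, cols_a, cols_b, min_obs)
    log2fc = mean_b - mean_a
    fold = np.power(2.0, np.abs(log2fc))
    testable = ~np.isnan(p)
    if compute_q:
        q = permutation_fdr(matrix, design, thresholds).to_numpy()
    else:
        q = np.full(p.shape, np.nan)

    with np.errstate(invalid="ignore"):
        significant = testable & (p < thresholds.p_de) & (fold >= thresholds.fc_de)
    direction = np.where(
        ~testable, "", np.where(log2fc > 0, "higher_in_B", np.where(log2fc < 0, "lower_in_B", "none"))
    )
    records = pd.DataFrame(
        {
            "group_id": values.index,
            "accessions": matrix.meta["accessions"].to_numpy(),
            "family": matrix.meta["family"].to_numpy(),
            "pclass": matrix.meta["pclass"].to_numpy(),
            "n_peptides": matrix.meta["n_peptides"].to_numpy(),
            "n_A": n_a,
            "n_B": n_b,
            "mean_A": np.where(testable, mean_a, np.nan),
            "mean_B": np.where(testable, mean_b, np.nan),
            "log2fc": np.where(testable, log2fc, np.nan),
            "fold": np.where(testable, fold, np.nan),
            "direction": direction,
            "t_stat": np.where(testable, t, np.nan),
            "p": p,
            "q": q,
            "testable": testable,
            "significant": significant,
        },
        columns=RESULT_COLUMNS,
    )
    return records.sort_values(
        ["p", "group_id"], na_position="last", kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# isoform discordance
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "family",
    "verdict",
    "reason",
    "n_specific_groups",
    "n_specific_testable",
    "common_group_id",
    "common_log2fc",
    "common_fold",
    "common_p",
    "common_q",
    "top_specific_group_id",
    "specific_log2fc",
    "specific_fold",
    "specific_p",
    "specific_q",
    "delta_log2fc",
]


def _passes_abundance(rec, thresholds: AnalysisThresholds) -> bool:
    return bool(rec.p < thresholds.p_de and rec.fold >= thresholds.fc_de)


def call_isoform_discordance(
    records: pd.DataFrame,
    catalog: IsoformCatalog,
    thresholds: AnalysisThresholds,
) -> pd.DataFrame:
    """Per-family isoform-discordance verdicts from INCLUDE_SHARED records.

    ``SPLICING_DISCORDANT``: some testable isoform-specific group has
    p < ``p_iso`` and its log2 fold change diverges from the common group's
    by at least log2(``fc_de``), while the common (all-isoform) group is
    testable but does not itself pass the abundance filter.
    ``ABUNDANCE_CONCORDANT``: common and some specific group both pass the
    abundance filter in the same direction.  Everything else is
    ``UNTESTABLE`` with a reason.
    """
    calls: list[dict] = []
    fam_records = records[records["family"] != MULTI_FAMILY]
    log2_fc_de = math.log2(thresholds.fc_de)
    for family, sub in fam_records.groupby("family", sort=True):
        if len(catalog.isoforms(family)) < 2:
            continue
        common = sub[sub["pclass"] == PeptideClass.SHARED_ISOFORMS.value]
        specific = sub[sub["pclass"] == PeptideClass.ISOFORM_SPECIFIC.value]
        call: dict = {
            "family": family,
            "n_specific_groups": len(specific),
            "n_specific_testable": int(specific["testable"].sum()),
        }
        common_rec = None
        if len(common) == 1 and bool(common.iloc[0]["testable"]):
            common_rec = common.iloc[0]
        testable_spec = specific[specific["testable"].astype(bool)]

        if common_rec is not None:
            call.update(
                common_group_id=common_rec["group_id"],
                common_log2fc=common_rec["log2fc"],
                common_fold=common_rec["fold"],
                common_p=common_rec["p"],
                common_q=common_rec["q"],
            )
        if common_rec is None or len(testable_spec) == 0:
            call["verdict"] = "UNTESTABLE"
            call["reason"] = (
                "no_testable_common_group" if common_rec is None else "no_testable_specific_group"
            )
            calls.append(call)
            continue

        delta = (testable_spec["log2fc"] - common_rec["log2fc"]).abs()
        discordant = testable_spec[
            (testable_spec["p"] < thresholds.p_iso) & (delta >= log2_fc_de)
        ]
        common_passes = _passes_abundance(common_rec, thresholds)
        if len(discordant) > 0 and not common_passes:
            top = discordant.loc[discordant["p"].idxmin()]
            call["verdict"] = "SPLICING_DISCORDANT"
            call["reason"] = "specific_shift_without_common_shift"
        else:
            concordant = testable_spec[
                testable_spec.apply(lambda r: _passes_abundance(r, thresholds), axis=1)
                & (np.sign(testable_spec["log2fc"]) == np.sign(common_rec["log2fc"]))
            ]
            if common_passes and len(concordant) > 0:
                top = concordant.loc[concordant["p"].idxmin()]
                call["verdict"] = "ABUNDANCE_CONCORDANT"
                call["reason"] = "common_and_specific_shift_together"
            else:
                top = testable_spec.loc[testable_spec["p"].idxmin()]
                call["verdict"] = "UNTESTABLE"
                call["reason"] = "no_signal"
        call.update(
            top_specific_group_id=top["group_id"],
            specific_log2fc=top["log2fc"],
            specific_fold=top["fold"],
            specific_p=top["p"],
            specific_q=top["q"],
            delta_log2fc=abs(top["log2fc"] - common_rec["log2fc"]),
        )
        calls.append(call)
    return pd.DataFrame(calls, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# PCA quality control
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample scores, explained-variance fractions and a PC1 cohort-separation
    score (difference of cohort means on PC1 in units of pooled SD)."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    separation: float


def pca_qc(
    matrix: NormalizedMatrix,
    design: SampleDesign,
    *,
    n_components: int = 2,
    missing: str = "drop",
) -> PCAResult:
    """Centered PCA of samples over complete features (default) or mean-filled.

    Complete features are groups observed in every sample; ``missing="mean"``
    instead fills each group's missing cells with the group mean.
    """
    from sklearn.decomposition import PCA

    values = matrix.values[design.samples]
    if missing == "drop":
        complete = values.dropna(axis=0, how="any")
    elif missing == "mean":
        complete = values.apply(lambda r: r.fillna(r.mean()), axis=1).dropna(how="any")
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    if len(complete) < 2:
        raise InsufficientDataError(
            f"only {len(complete)} complete feature(s); need at least 2"
        )
    data = complete.to_numpy(dtype=float).T  # samples x features
    if np.allclose(data.var(axis=0).sum(), 0.0):
        raise InsufficientDataError("zero variance across all features")
    k = min(n_components, data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)
    score_df = pd.DataFrame(
        scores, index=design.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    score_df.insert(0, "cohort", [design.cohort_of(s) for s in design.samples])

    pc1_a = score_df.loc[design.samples_a, "PC1"].to_numpy()
    pc1_b = score_df.loc[design.samples_b, "PC1"].to_numpy()
    df = pc1_a.size + pc1_b.size - 2
    pooled = (
        (pc1_a.size - 1) * pc1_a.var(ddof=1) + (pc1_b.size - 1) * pc1_b.var(ddof=1)
    ) / df
    diff = abs(pc1_a.mean() - pc1_b.mean())
    if pooled == 0.0:
        separation = math.inf if diff > 0 else 0.0
    else:
        separation = diff / math.sqrt(pooled)
    return PCAResult(score_df, pca.explained_variance_ratio_, float(separation))


# ---------------------------------------------------------------------------
# pooled proportion comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionComparison:
    """Comparison of two pooled count proportions via a 2x2 chi-square test."""

    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    diff: float
    chi2: float
    p: float

    @property
    def pct1(self) -> int:
        """First proportion as a display percentage (nearest integer)."""
        return round(self.p1 * 100)

    @property
    def pct2(self) -> int:
        return round(self.p2 * 100)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ProportionComparison:
    """Pooled proportions with a 1-df chi-square test (no continuity correction)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p1 = k1 / n1
    p2 = k2 / n2
    if p1 == p2:
        chi2, p = 0.0, 1.0
    else:
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        res = stats.chi2_contingency(table, correction=False)
        chi2, p = float(res.statistic), float(res.pvalue)
    return ProportionComparison(k1, n1, k2, n2, p1, p2, p1 - p2, chi2, p)
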