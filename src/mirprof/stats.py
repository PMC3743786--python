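"""Expression quantification and screening statistics.

Three pieces of the analysis live here:

* comparative-Ct (delta-delta-Ct) relative quantification of qPCR data,
  normalized to a reference small RNA (U6 in the assay this models) and
  expressed as fold change 2**(-ddCt) against a calibrator sample;
* the microarray-style candidate screen: per feature, a Welch two-sample
  t-test on log2 values combined with a >= 2-fold change gate at alpha=0.05;
* the group-comparison tests used on qPCR expression levels: paired t,
  Tukey-Kramer all-pairs comparison, and pairwise Mann-Whitney U.

Fold changes are geometric (mean of log2 values, exponentiated) and the
Welch test runs on the log2 scale, the standard treatment for intensity/RQ
data.  All tests are two-sided.  No multiple-testing correction is applied
by default; a Benjamini-Hochberg column is available behind a flag.

The test engines are the scipy.stats implementations; the surrounding
contracts (zero-variance errors, the exact/asymptotic Mann-Whitney switch,
the screen rule) are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05
MIN_FOLD_DEFAULT = 2.0

#: Total sample size at or below which Mann-Whitney uses exact enumeration
#: (when no ties are present).
MW_EXACT_MAX_N = 12


# ------------------------------------------------------------ comparative Ct

@dataclass(frozen=True)
class CtMeasurement:
    """Replicate-averaged Ct values for one sample: the target assay and the
    reference (normalizer) assay."""

    sample_id: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, reps in (("target", self.target_ct), ("reference", self.reference_ct)):
            if len(reps) < 1:
                raise ValueError(f"{self.sample_id}: {name} Ct needs >= 1 replicate")
            for v in reps:
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"{self.sample_id}: non-finite or non-positive {name} Ct")

    @property
    def mean_target(self) -> float:
        return float(np.mean(self.target_ct))

    @property
    def mean_reference(self) -> float:
        return float(np.mean(self.reference_ct))

    @property
    def delta_ct(self) -> float:
        return self.mean_target - self.mean_reference


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    delta_ct: float
    ddct: float
    rq: float


def relative_expression(
    measurements: list[CtMeasurement], calibrator_id: str
) -> list[RelativeExpression]:
    """Comparative-Ct quantification: rq = 2**(-(dCt_sample - dCt_calibrator)).

    The calibrator's rq is exactly 1."""
    by_id = {m.sample_id: m for m in measurements}
    if calibrator_id not in by_id:
        raise ValueError(f"calibrator {calibrator_id!r} not among samples")
    cal_dct = by_id[calibrator_id].delta_ct
    out = []
    for m in measurements:
        ddct = m.delta_ct - cal_dct
        out.append(
            RelativeExpression(
                sample_id=m.sample_id,
                delta_ct=m.delta_ct,
                ddct=ddct,
                rq=float(2.0 ** (-ddct)),
            )
        )
    return out


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Ct TSV with columns sample_id, target_ct, reference_ct; replicates as
    repeated rows."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        out.append(
            CtMeasurement(
                sample_id=str(sid),
                target_ct=tuple(float(v) for v in grp["target_ct"]),
                reference_ct=tuple(float(v) for v in grp["reference_ct"]),
            )
        )
    return out


# ------------------------------------------------------------------- tests

def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def paired_t(pairs) -> tuple[float, float]:
    """Paired t-test: one-sample t on within-pair differences, two-sided."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (x, y) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    if diffs.var(ddof=1) == 0.0:
        raise ValueError("zero-variance differences")
    res = sps.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(a, b, exact: bool | None = None) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    ``exact=None`` (default) selects exact enumeration when the total sample
    size is <= 12 and there are no ties, and otherwise the normal
    approximation with tie correction (no continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 value")
    if exact is None:
        exact = (a.size + b.size) <= MW_EXACT_MAX_N and not _has_ties(a, b)
    if exact and _has_ties(a, b):
        raise ValueError("exact Mann-Whitney requires tie-free data")
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    u, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p) and np.isclose(u, a.size * b.size / 2.0):
        # fully tied data: U sits exactly at its null mean, no evidence either way
        p = 1.0
    return u, min(p, 1.0)


def tukey_kramer(groups, names: list[str] | None = None) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparison (studentized range, unequal-n
    Kramer adjustment).  Returns a long table group_a, group_b, p_value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs >= 2 values")
    if all(g.var(ddof=1) == 0.0 for g in groups):
        raise ValueError("all groups have zero variance")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(groups))]
    if len(names) != len(groups):
        raise ValueError("one name per group")
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append((names[i], names[j], float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p_value"])


# ------------------------------------------------------------------- screen

def screen_candidates(
    expr: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    alpha: float = ALPHA_DEFAULT,
    min_fold: float = MIN_FOLD_DEFAULT,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Differential-expression candidate screen.

    ``expr`` is a linear-scale feature x sample matrix (index = feature ids,
    columns = sample ids, strictly positive values); ``labels`` maps each
    sample to 'cancer' or 'control'.  Per feature: Welch t on log2 values,
    geometric fold change cancer/control; a feature is selected when
    p < alpha and the fold change is >= min_fold in either direction.
    Rows come back sorted by p-value.

    ``bh_correct=True`` adds a Benjamini-Hochberg adjusted column ``p_adj``
    (selection still uses the raw p, matching the screen rule).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    labels = dict(labels)
    cancer = [s for s in expr.columns if labels.get(s) == "cancer"]
    control = [s for s in expr.columns if labels.get(s) == "control"]
    if len(cancer) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per class")
    if (expr[cancer + control] <= 0).any().any():
        raise ValueError("expression values must be positive (linear scale)")

    log2 = np.log2(expr[cancer + control].to_numpy(dtype=float))
    a = log2[:, : len(cancer)]
    b = log2[:, len(cancer) :]
    t_stat, p_val = sps.ttest_ind(a, b, axis=1, equal_var=False)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    fc = 2.0 ** log2_fc

    out = pd.DataFrame(
        {
            "feature_id": expr.index,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "t": t_stat,
            "p_value": p_val,
        }
    )
    out["direction"] = np.where(out["fold_change"] >= 1.0, "up", "down")
    out["selected"] = (out["p_value"] < alpha) & (
        (out["fold_change"] >= min_fold) | (out["fold_change"] <= 1.0 / min_fold)
    )
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def group_tests(
    expr: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    method: str,
) -> pd.DataFrame:
    """Per-feature group comparisons on an expression matrix.

    ``method`` is 'paired' (exactly two groups, samples matched by order),
    'tukey' (Tukey-Kramer across all groups), or 'mannwhitney' (pairwise U
    tests).  Returns a long table feature_id, comparison, statistic, p_value
    (statistic is NaN for Tukey, which reports only the family of p-values).
    """
    groups = dict(groups)
    names = sorted(set(groups.values()))
    members = {g: [s for s in expr.columns if groups.get(s) == g] for g in names}
    rows = []
    for fid, row in expr.iterrows():
        vals = {g: row[members[g]].to_numpy(dtype=float) for g in names}
        if method == "paired":
            if len(names) != 2:
                raise ValueError("paired test needs exactly two groups")
            x, y = vals[names[0]], vals[names[1]]
            if x.size != y.size:
                raise ValueError("paired groups must have equal size")
            t, p = paired_t(list(zip(x, y)))
            rows.append((fid, f"{names[0]} vs {names[1]}", t, p))
        elif method == "tukey":
            table = tukey_kramer([vals[g] for g in names], names=names)
            for ga, gb, p in table.itertuples(index=False, name=None):
                rows.append((fid, f"{ga} vs {gb}", np.nan, p))
        elif method == "mannwhitney":
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    u, p = mann_whitney(vals[names[i]], vals[names[j]])
                    rows.append((fid, f"{names[i]} vs {names[j]}", u, p))
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["feature_id", "comparison", "statistic", "p_value"])


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV: header row = sample ids, first column = feature id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>label (header optional but expected)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
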