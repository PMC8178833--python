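"""Enrichment filtering and shadow-feature selection of cell-specific markers.

The enrichment stage keeps features over-expressed in the target group
(log2 fold-change > 0.5, p <= 0.05, up-regulated only by default). The
selection stage is an iterative shadow-feature algorithm in the Boruta
family: each run appends a within-sample shuffled ("shadow") copy of
every original feature, fits a randomized-ensemble importance
provider, and a live feature scores a hit when its importance beats
the best shadow. A
two-sided binomial test on the hit count against Binomial(runs, 1/2),
Bonferroni-adjusted across undecided features, Confirms or Rejects
features; Rejected features leave the live set. Defaults follow the
published protocol: at most 10000 runs, alpha 0.01 with Bonferroni,
and a final cut at the top 35 Confirmed importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier


@dataclass
class ExpressionMatrix:
    """Features x samples abundances with binary group labels.

    ``groups`` maps sample name to a label; exactly one label is the
    target group for the differential / selection contrast.
    """

    values: pd.DataFrame  # features x samples, non-negative
    groups: dict[str, str]
    target_group: str

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.values < 0).any():
            raise ValueError("expression matrix contains negative abundances")
        labels = set(self.groups[s] for s in self.values.columns)
        if self.target_group not in labels:
            raise ValueError(f"target group {self.target_group!r} has no samples")

    @property
    def target_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == self.target_group]

    @property
    def rest_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] != self.target_group]

    def labels01(self) -> np.ndarray:
        return np.array(
            [1 if self.groups[s] == self.target_group else 0 for s in self.values.columns]
        )


@dataclass
class DiffResult:
    """Per-feature two-group effect (beta = log2 FC target vs rest) and p."""

    table: pd.DataFrame  # index: feature; columns: beta, p_value


@dataclass
class SelectionParams:
    max_runs: int = 10000
    alpha: float = 0.01
    bonferroni: bool = True
    n_top: int = 35
    beta_min: float = 0.5
    p_max: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SelectionResult:
    """Per-feature decision with hit history, importances and ranks."""

    table: pd.DataFrame  # columns: decision, hits, runs, mean_importance, rank
    runs_performed: int

    def confirmed(self) -> list[str]:
        t = self.table[self.table["decision"] == "Confirmed"]
        return list(t.sort_values("rank").index)


def two_group_test(matrix: ExpressionMatrix, epsilon: float = 1.0) -> DiffResult:
    """Log2 fold-change and Welch t-test p per feature.

    A stand-in satisfying the pluggable (beta, p) provider contract:
    beta = mean log2(x + epsilon) in target minus rest; p from a
    two-sample unequal-variance t test on the same transform. Groups
    with fewer than 2 samples yield NaN p-values (flagged).
    """
    tgt = matrix.values[matrix.target_samples]
    rest = matrix.values[matrix.rest_samples]
    if rest.shape[1] == 0:
        raise ValueError("rest group is empty")
    lt = np.log2(tgt.values + epsilon)
    lr = np.log2(rest.values + epsilon)
    beta = lt.mean(axis=1) - lr.mean(axis=1)
    if tgt.shape[1] < 2 or rest.shape[1] < 2:
        p = np.full(len(beta), np.nan)
    else:
        p = stats.ttest_ind(lt, lr, axis=1, equal_var=False).pvalue
        # identical groups give nan from zero variance; by convention p = 1
        p = np.where(np.isnan(p), 1.0, p)
    return DiffResult(
        pd.DataFrame({"beta": beta, "p_value": p}, index=matrix.values.index)
    )


def filter_overexpressed(diff: DiffResult, params: SelectionParams | None = None) -> list[str]:
    """Keep features with beta > beta_min, p <= p_max and beta > 0 (up only)."""
    params = params or SelectionParams()
    t = diff.table
    keep = (t["beta"] > params.beta_min) & (t["p_value"] <= params.p_max) & (t["beta"] > 0)
    return list(t.index[keep])


def _rf_importance_provider(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Default importance provider: impurity importances from a heavily
    randomized forest (extra-trees, one candidate feature per split).

    The strong split randomization makes per-run importances noisy
    enough to swamp the finite-sample chance correlations of noise
    features, which keeps their hit probability against the best shadow
    below 1/2 — the calibration the binomial hit test relies on. A
    plain random forest reproduces the same importance ranking every
    run, so a noise feature that happens to correlate with the labels
    in one finite sample would accumulate hits systematically.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    clf = ExtraTreesClassifier(
        n_estimators=100, max_features=1, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    return clf.feature_importances_


def rf_importance_provider(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Classic random-forest impurity importance (alternative provider)."""
    seed = int(rng.integers(0, 2**31 - 1))
    rf = RandomForestClassifier(
        n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    return rf.feature_importances_


ImportanceProvider = Callable[[np.ndarray, np.ndarray, np.random.Generator], np.ndarray]


def shadow_feature_select(
    matrix: ExpressionMatrix,
    params: SelectionParams | None = None,
    importance_provider: ImportanceProvider | None = None,
) -> SelectionResult:
    """Iterative shadow-feature selection with binomial hit testing.

    Stops when no feature is Tentative or after ``max_runs`` runs.
    Confirmed features are ranked by mean importance (descending, ties
    by feature id). A zero-variance matrix Rejects everything.
    """
    params = params or SelectionParams()
    provider = importance_provider or _rf_importance_provider
    labels = {matrix.groups[s] for s in matrix.values.columns}
    if len(labels) != 2:
        raise ValueError(f"binary group labels required, got {sorted(labels)}")
    counts = pd.Series(matrix.labels01()).value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 samples")
    features = list(matrix.values.index)
    if len(features) < 2:
        raise ValueError("need >= 2 features")

    X_all = matrix.values.values.T.astype(float)  # samples x features
    y = matrix.labels01()
    rng = np.random.default_rng(params.rng_seed)

    if np.allclose(X_all.std(axis=0), 0):
        table = pd.DataFrame(
            {
                "decision": "Rejected",
                "hits": 0,
                "runs": 0,
                "mean_importance": 0.0,
                "rank": np.nan,
            },
            index=features,
        )
        return SelectionResult(table, runs_performed=0)

    decision = {f: "Tentative" for f in features}
    hits = {f: 0 for f in features}
    runs_of = {f: 0 for f in features}
    imp_sums = {f: 0.0 for f in features}

    runs = 0
    while runs < params.max_runs:
        live = [f for f in features if decision[f] != "Rejected"]
        undecided = [f for f in features if decision[f] == "Tentative"]
        if not undecided:
            break
        runs += 1
        idx = [features.index(f) for f in live]
        X_live = X_all[:, idx]
        # shadows are shuffled copies of every ORIGINAL feature (not just
        # the live set): the max-shadow bar is the permutation null of the
        # full feature family, and letting it collapse as features are
        # rejected would hand the last survivors a near-free bar
        shadows = X_all.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        X_run = np.hstack([X_live, shadows])
        importances = provider(X_run, y, rng)
        real_imp = importances[: len(live)]
        shadow_max = importances[len(live):].max()
        for f, imp in zip(live, real_imp):
            runs_of[f] += 1
            imp_sums[f] += float(imp)
            if imp > shadow_max:
                hits[f] += 1
        # decision step: two-sided binomial test vs Binomial(runs, 0.5),
        # Bonferroni-adjusted over the full original feature set
        n_tests = len(features)
        for f in undecided:
            p = stats.binomtest(hits[f], runs_of[f], 0.5).pvalue
            if params.bonferroni:
                p = min(1.0, p * n_tests)
            if p <= params.alpha:
                decision[f] = (
                    "Confirmed" if hits[f] > runs_of[f] / 2 else "Rejected"
                )

    mean_imp = {
        f: (imp_sums[f] / runs_of[f]) if runs_of[f] else 0.0 for f in features
    }
    confirmed = sorted(
        (f for f in features if decision[f] == "Confirmed"),
        key=lambda f: (-mean_imp[f], f),
    )
    ranks = {f: i + 1 for i, f in enumerate(confirmed)}
    table = pd.DataFrame(
        {
            "decision": [decision[f] for f in features],
            "hits": [hits[f] for f in features],
            "runs": [runs_of[f] for f in features],
            "mean_importance": [mean_imp[f] for f in features],
            "rank": [ranks.get(f, np.nan) for f in features],
        },
        index=features,
    )
    return SelectionResult(table, runs_performed=runs)


def top_n(result: SelectionResult, n_top: int = 35) -> list[str]:
    """First min(n_top, #Confirmed) features by mean importance,
    descending; ties broken by feature id."""
    return result.confirmed()[:n_top]


def read_expression_tsv(
    matrix_path, sample_sheet_path, target_group: str
) -> ExpressionMatrix:
    """Load a features x samples TSV and a (sample_id, group) sheet."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if sheet.shape[1] < 2:
        raise ValueError("sample sheet needs sample_id and group columns")
    groups = dict(zip(sheet.iloc[:, 0].astype(str), sheet.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values, groups, target_group)
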