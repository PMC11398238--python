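"""Condition classification and paired nonparametric comparisons.

A random forest (Gini impurity splits) classifies the vision / no-vision
rows of the paired feature table; accuracy is summarized by the AUC of the
out-of-bag class-probability votes (no arbitrary held-out split, and every
subject contributes rows to both classes so a plain row-wise split would
leak).  The top-k features by mean decrease in impurity are then compared
between conditions with Wilcoxon signed-rank tests at a two-sided 5% level,
reporting the signed effect size r = Z/sqrt(N) and a Hodges-Lehmann 95%
confidence interval of the paired difference.  No multiple-testing
correction is applied; the report carries the number of tests so readers
can adjust.

The signed-rank test uses the exact null distribution (a dynamic program
over the tied midranks) for up to 25 nonzero pairs and the normal
approximation with continuity and tie correction beyond; zero differences
are dropped and counted, per the standard signed-rank convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .features import FEATURE_NAMES

__all__ = [
    "ImportanceRanking",
    "PairedTestResult",
    "StatsReport",
    "rf_classify",
    "top_k",
    "paired_wilcoxon",
    "run_analysis",
]

EXACT_THRESHOLD = 25  # nonzero pairs; beyond this the normal approximation is used


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by mean decrease in Gini impurity, plus OOB AUC."""

    features: tuple[str, ...]
    importances: tuple[float, ...]
    auc: float
    n_trees: int
    seed: int
    positive_class: str
    tied: bool = False

    def __post_init__(self) -> None:
        if list(self.importances) != sorted(self.importances, reverse=True):
            raise ValueError("importances must be in descending order")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank comparison of one feature between conditions."""

    feature: str
    n: int
    n_zero: int
    median_x: float
    iqr_x: tuple[float, float]
    median_y: float
    iqr_y: tuple[float, float]
    statistic: float  # W+ (sum of positive-difference ranks)
    p_value: float
    effect_size_r: float  # Z/sqrt(N), signed by the median difference x - y
    ci95: tuple[float, float]  # Hodges-Lehmann interval of the paired difference
    hl_estimate: float
    method: str  # "exact" | "approx" | "degenerate"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if abs(self.effect_size_r) > 1.0:
            raise ValueError("|r| must be <= 1")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def rf_classify(
    table: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    n_trees: int = 500,
    max_features: str | float = "sqrt",
    validation: str = "oob",
    groups: Sequence | None = None,
) -> ImportanceRanking:
    """Fit the forest and rank all features by Gini importance.

    ``table`` holds one row per subject-condition with exactly the feature
    columns; ``labels`` the condition of each row.  With the default
    ``validation="oob"`` the AUC comes from out-of-bag class-probability
    votes -- an out-of-sample estimate without an arbitrary split.  For
    paired designs where the same subject contributes a row to *both*
    classes, OOB votes leak subject identity (a row's near-duplicate twin is
    usually in-bag with the opposite label, which can push the AUC far below
    0.5); ``validation="grouped"`` with ``groups=subject_ids`` instead scores
    probabilities from subject-level cross-validation, so both rows of a
    subject are always held out together.  Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need two classes to classify, got {classes.tolist()}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 rows per class, got {counts}")
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if validation not in ("oob", "grouped"):
        raise ValueError("validation must be 'oob' or 'grouped'")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features=max_features,
        oob_score=validation == "oob",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    positive = forest.classes_[1]
    if validation == "oob":
        votes = forest.oob_decision_function_[:, 1]
        ok = ~np.isnan(votes)  # rows never out of bag carry no vote
        auc = float(roc_auc_score((y == positive)[ok], votes[ok]))
    else:
        if groups is None:
            raise ValueError("grouped validation requires groups (e.g. subject ids)")
        from sklearn.base import clone
        from sklearn.model_selection import GroupKFold

        groups = np.asarray(groups)
        n_splits = min(5, len(np.unique(groups)))
        if n_splits < 2:
            raise ValueError("grouped validation needs at least 2 groups")
        proba = np.full(len(y), np.nan)
        for train, test in GroupKFold(n_splits=n_splits).split(X, y, groups):
            fold = clone(forest).fit(X[train], y[train])
            proba[test] = fold.predict_proba(X[test])[:, list(fold.classes_).index(positive)]
        auc = float(roc_auc_score(y == positive, proba))

    names = list(table.columns)
    canon = {n: i for i, n in enumerate(FEATURE_NAMES)}
    order = sorted(
        range(len(names)),
        key=lambda i: (-forest.feature_importances_[i], canon.get(names[i], len(canon)), names[i]),
    )
    imp = forest.feature_importances_
    tied = bool(len(set(np.round(imp, 12))) < len(imp))
    return ImportanceRanking(
        features=tuple(names[i] for i in order),
        importances=tuple(float(imp[i]) for i in order),
        auc=auc,
        n_trees=n_trees,
        seed=int(seed),
        positive_class=str(positive),
        tied=tied,
    )


def top_k(ranking: ImportanceRanking, k: int = 10) -> list[str]:
    """First k features by descending importance (ties broken canonically)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.features):
        raise ValueError(f"k={k} exceeds the {len(ranking.features)} ranked features")
    return list(ranking.features[:k])


def _signed_rank_exact_p(w2: int, ranks2: np.ndarray) -> float:
    """Two-sided exact p for W+ via DP over doubled (integer) midranks."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    pmf = counts / counts.sum()
    lower = float(pmf[: w2 + 1].sum())
    upper = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def _hodges_lehmann_ci(d: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """HL point estimate and CI from the Walsh averages of the differences."""
    n = len(d)
    walsh = []
    for i in range(n):
        walsh.extend((d[i] + d[i:]) / 2.0)
    walsh = np.sort(np.asarray(walsh))
    estimate = float(np.median(walsh))
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = sps.norm.isf(alpha / 2.0)
    c = int(np.floor(mu - z * sigma))
    if c < 0:
        return estimate, (float(walsh[0]), float(walsh[-1]))
    m = len(walsh)
    return estimate, (float(walsh[c]), float(walsh[m - 1 - c]))


def paired_wilcoxon(
    x: Sequence[float], y: Sequence[float], feature: str = "", alpha: float = 0.05
) -> PairedTestResult:
    """Wilcoxon signed-rank test of paired samples ``x`` vs ``y``.

    Differences are ``x - y``; a positive effect size means ``x`` tends to be
    larger.  ``N`` in ``r = Z/sqrt(N)`` is the number of pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    n_pairs = len(x)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    q1x, med_x, q3x = np.percentile(x, [25, 50, 75])
    q1y, med_y, q3y = np.percentile(y, [25, 50, 75])
    base = dict(
        feature=feature,
        n=n_pairs,
        median_x=float(med_x),
        iqr_x=(float(q1x), float(q3x)),
        median_y=float(med_y),
        iqr_y=(float(q1y), float(q3y)),
    )

    nz = d[d != 0]
    n_zero = n_pairs - len(nz)
    if len(nz) == 0:
        return PairedTestResult(
            **base, n_zero=n_zero, statistic=0.0, p_value=1.0, effect_size_r=0.0,
            ci95=(0.0, 0.0), hl_estimate=0.0, method="degenerate", degenerate=True,
        )

    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    n = len(nz)
    mu = n * (n + 1) / 4.0

    if n <= EXACT_THRESHOLD:
        ranks2 = np.rint(2.0 * ranks).astype(int)  # midranks doubled are integers
        p = _signed_rank_exact_p(int(round(2.0 * w_plus)), ranks2)
        z_mag = float(sps.norm.isf(min(max(p, 1e-300), 1.0) / 2.0)) if p < 1.0 else 0.0
        method = "exact"
    else:
        _, tie_counts = np.unique(np.abs(nz), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            raise ValueError("degenerate variance in signed-rank approximation")
        cc = 0.5 * np.sign(w_plus - mu)  # continuity correction toward the mean
        z = (w_plus - mu - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        z_mag = abs(float(z))
        method = "approx"

    direction = float(np.sign(np.median(d)))
    if direction == 0.0:
        direction = float(np.sign(w_plus - mu))
    r = min(1.0, z_mag / np.sqrt(n_pairs)) * direction
    hl, ci = _hodges_lehmann_ci(d, alpha)
    return PairedTestResult(
        **base, n_zero=n_zero, statistic=w_plus, p_value=float(p), effect_size_r=float(r),
        ci95=ci, hl_estimate=hl, method=method, degenerate=False,
    )


@dataclass
class StatsReport:
    """Importance ranking, top-k list and paired comparisons of one cohort."""

    ranking: ImportanceRanking
    top_features: list[str]
    tests: list[PairedTestResult]
    alpha: float
    k: int
    seed: int
    condition_order: tuple[str, str]
    n_tests: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_tests = len(self.tests)
        if not set(self.top_features) <= set(self.ranking.features):
            raise ValueError("top-k features must be a subset of the ranking")

    def to_dict(self) -> dict:
        return {
            "ranking": {
                "features": list(self.ranking.features),
                "importances": list(self.ranking.importances),
                "auc": self.ranking.auc,
                "n_trees": self.ranking.n_trees,
                "seed": self.ranking.seed,
                "positive_class": self.ranking.positive_class,
                "tied": self.ranking.tied,
            },
            "top_features": list(self.top_features),
            "tests": [
                {
                    "feature": t.feature,
                    "n": t.n,
                    "n_zero_differences": t.n_zero,
                    f"median_iqr_{self.condition_order[0]}": [t.median_x, *t.iqr_x],
                    f"median_iqr_{self.condition_order[1]}": [t.median_y, *t.iqr_y],
                    "W": t.statistic,
                    "p_value": t.p_value,
                    "effect_size_r": t.effect_size_r,
                    "ci95": list(t.ci95),
                    "hodges_lehmann": t.hl_estimate,
                    "method": t.method,
                    "significant": bool(t.p_value < self.alpha),
                }
                for t in self.tests
            ],
            "alpha": self.alpha,
            "k": self.k,
            "n_tests": self.n_tests,
            "multiple_testing_correction": None,
            "seed": self.seed,
            "condition_order": list(self.condition_order),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        a, b = self.condition_order
        lines = [
            f"| Feature | {a} median (IQR) | {b} median (IQR) | p | r | 95% CI |",
            "|---|---|---|---|---|---|",
        ]
        for t in self.tests:
            lines.append(
                f"| {t.feature} | {t.median_x:.3g} ({t.iqr_x[0]:.3g}-{t.iqr_x[1]:.3g}) "
                f"| {t.median_y:.3g} ({t.iqr_y[0]:.3g}-{t.iqr_y[1]:.3g}) "
                f"| {t.p_value:.3g} | {t.effect_size_r:.2f} "
                f"| [{t.ci95[0]:.3g}, {t.ci95[1]:.3g}] |"
            )
        lines.append("")
        lines.append(
            f"OOB AUC = {self.ranking.auc:.2f}; {self.n_tests} uncorrected tests at "
            f"two-sided alpha = {self.alpha}."
        )
        return "\n".join(lines)


def run_analysis(
    table: pd.DataFrame,
    k: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = 500,
    condition_order: tuple[str, str] = ("vision", "no_vision"),
    validation: str = "oob",
) -> StatsReport:
    """Forest ranking, top-k extraction and paired tests on a cohort table.

    ``table`` must contain ``subject`` and ``condition`` columns plus the 29
    feature columns, with every subject present in both conditions.
    """
    for col in ("subject", "condition"):
        if col not in table.columns:
            raise ValueError(f"feature table lacks required column {col!r}")
    feat_cols = [c for c in table.columns if c not in ("subject", "condition")]
    conditions = set(table["condition"].unique())
    if conditions != set(condition_order):
        raise ValueError(f"expected conditions {condition_order}, found {sorted(conditions)}")
    counts = table.groupby(["subject", "condition"]).size().unstack(fill_value=0)
    bad = counts.index[(counts != 1).any(axis=1)].tolist()
    if bad:
        raise ValueError(f"unpaired subjects (must appear exactly once per condition): {bad}")

    ranking = rf_classify(
        table[feat_cols],
        table["condition"].to_list(),
        seed=seed,
        n_trees=n_trees,
        validation=validation,
        groups=table["subject"].to_numpy() if validation == "grouped" else None,
    )
    top = top_k(ranking, k)
    a, b = condition_order
    xa = table[table["condition"] == a].sort_values("subject")
    xb = table[table["condition"] == b].sort_values("subject")
    tests = [
        paired_wilcoxon(xa[f].to_numpy(), xb[f].to_numpy(), feature=f, alpha=alpha) for f in top
    ]
    return StatsReport(
        ranking=ranking, top_features=top, tests=tests, alpha=alpha, k=k,
        seed=int(seed), condition_order=condition_order,
    )
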