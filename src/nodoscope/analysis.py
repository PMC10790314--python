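"""Group statistics and stimulus classification on responder features.

Group differences per feature are assessed with the non-parametric
Kruskal-Wallis test (tie-corrected H against a chi-square reference,
with an exact permutation option at small n) followed by Dunn's
rank-based pairwise comparisons with Bonferroni adjustment.  Stimulus
identity is decoded from transient features with a random forest under
stratified ten-fold cross-validation; performance is summarised as
per-fold accuracy, pooled out-of-fold one-vs-rest ROC curves, and
per-feature additive attribution magnitudes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStatsResult",
    "ClassificationReport",
    "kruskal_wallis",
    "pairwise_posthoc",
    "group_statistics",
    "rf_classify",
    "feature_attribution",
    "tree_path_attribution",
    "make_report",
    "DEFAULT_CLASSIFIER_FEATURES",
]

#: transient features fed to the classifier by default
DEFAULT_CLASSIFIER_FEATURES = [
    "amplitude_dff",
    "duration_s",
    "n_peaks",
    "integral_dff_s",
]


def kruskal_wallis(
    groups: dict[str, np.ndarray], exact_max_n: int = 0
) -> tuple[float, float]:
    """Kruskal-Wallis H and p over k groups of values.

    H is computed from rank sums with tie correction; p comes from the
    chi-square approximation, or from full permutation enumeration when
    the pooled sample size is at most ``exact_max_n`` (feasible up to
    about 12).  All-identical values give H = 0, p = 1.
    """
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2 or any(v.size < 1 for v in vals):
        raise ValueError("need >= 2 groups, each nonempty")
    pooled = np.concatenate(vals)
    if pooled.size < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H = _kw_h(vals)
    k = len(vals)
    if pooled.size <= exact_max_n:
        p = _kw_exact_p(vals, H)
    else:
        p = float(stats.chi2.sf(H, k - 1))
    return H, p


def _kw_h(vals: list[np.ndarray]) -> float:
    pooled = np.concatenate(vals)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    ssq = 0.0
    for v in vals:
        r = ranks[start : start + v.size]
        ssq += r.sum() ** 2 / v.size
        start += v.size
    H = 12.0 / (N * (N + 1)) * ssq - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    denom = 1.0 - ties / (N**3 - N)
    if denom <= 0:
        return 0.0
    return float(H / denom)


def _kw_exact_p(vals: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p by full enumeration of group assignments."""
    from itertools import permutations

    pooled = np.concatenate(vals)
    sizes = [v.size for v in vals]
    seen = set()
    count = total = 0
    for perm in permutations(range(pooled.size)):
        key = tuple(
            tuple(sorted(perm[sum(sizes[:i]) : sum(sizes[: i + 1])]))
            for i in range(len(sizes))
        )
        if key in seen:
            continue
        seen.add(key)
        arranged = pooled[list(perm)]
        start = 0
        gs = []
        for s in sizes:
            gs.append(arranged[start : start + s])
            start += s
        total += 1
        if _kw_h(gs) >= h_obs - 1e-12:
            count += 1
    return count / total


def pairwise_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-comparisons on the pooled ranking.

    Each pair's z uses the pooled-rank means with the tie-corrected
    variance; two-sided p-values are multiplicity-adjusted across all
    pairs (Bonferroni by default, Holm available) and capped at 1.
    Empty groups are skipped.
    """
    keys = [k for k, v in groups.items() if len(v) > 0]
    vals = [np.asarray(groups[k], dtype=float) for k in keys]
    pooled = np.concatenate(vals)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k, v in zip(keys, vals):
        mean_ranks[k] = ranks[start : start + v.size].mean()
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    raw = {}
    for a, b in combinations(keys, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        raw[(a, b)] = 2.0 * float(stats.norm.sf(abs(z)))
    m = len(raw)
    if adjust == "bonferroni":
        return {k: min(1.0, p * m) for k, p in raw.items()}
    if adjust == "holm":
        order = sorted(raw, key=raw.get)
        adj = {}
        running = 0.0
        for i, k in enumerate(order):
            running = max(running, raw[k] * (m - i))
            adj[k] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {adjust!r}")


@dataclass
class GroupStatsResult:
    feature: str
    H: float
    p: float
    pairwise_p: dict[tuple[str, str], float]
    group_mean_sem: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": self.feature,
                "comparison": "omnibus",
                "statistic": self.H,
                "p": self.p,
            }
        ]
        for (a, b), p in self.pairwise_p.items():
            rows.append(
                {
                    "feature": self.feature,
                    "comparison": f"{a} vs {b}",
                    "statistic": np.nan,
                    "p": p,
                }
            )
        return pd.DataFrame(rows)


def group_statistics(
    table: pd.DataFrame,
    features: list[str],
    label_col: str = "event_label",
) -> list[GroupStatsResult]:
    """Omnibus + post-hoc statistics for each feature across classes."""
    out = []
    for feat in features:
        groups = {
            lab: sub[feat].to_numpy()
            for lab, sub in table.groupby(label_col, sort=True)
        }
        H, p = kruskal_wallis(groups)
        pw = pairwise_posthoc(groups)
        ms = {
            lab: (float(np.mean(v)), float(stats.sem(v)) if len(v) > 1 else 0.0)
            for lab, v in groups.items()
        }
        out.append(GroupStatsResult(feat, H, p, pw, ms))
    return out


@dataclass
class ClassificationReport:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    classes: list[str]
    roc: dict[str, tuple[np.ndarray, np.ndarray, float]]  # label -> (fpr, tpr, auc)
    attribution: pd.Series  # mean |contribution| per feature, descending
    features: list[str]
    seed: int
    oof_scores: np.ndarray = field(repr=False, default=None)
    oof_labels: np.ndarray = field(repr=False, default=None)


def tree_path_attribution(forest, X: np.ndarray) -> np.ndarray:
    """Additive per-feature attributions of a fitted sklearn forest.

    Decomposes each tree's prediction into the sum of probability
    changes along the decision path, credited to the feature split at
    each step (the classic tree-path / Saabas decomposition; exact for
    a stump, additive by construction).  Returns |contributions|
    averaged over samples, classes and trees: shape (n_features,).
    """
    X = np.asarray(X, dtype=np.float32)
    n, d = X.shape
    total = np.zeros(d)
    for est in forest.estimators_:
        t = est.tree_
        value = t.value[:, 0, :]  # node -> class distribution
        prob = value / value.sum(axis=1, keepdims=True)
        node = np.zeros(n, dtype=int)
        contrib = np.zeros((n, d))
        active = np.arange(n)
        while active.size:
            cur = node[active]
            leaf = t.children_left[cur] == -1
            go = active[~leaf]
            if go.size == 0:
                break
            cur = node[go]
            f = t.feature[cur]
            left = X[go, f] <= t.threshold[cur]
            nxt = np.where(left, t.children_left[cur], t.children_right[cur])
            delta = prob[nxt] - prob[cur]  # probability shift at this split
            np.add.at(contrib, (go, f), np.abs(delta).mean(axis=1))
            node[go] = nxt
            active = go
        total += contrib.mean(axis=0)
    return total / len(forest.estimators_)


def rf_classify(
    table: pd.DataFrame,
    features: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    label_col: str = "event_label",
    n_estimators: int = 500,
    attribution_method: str = "tree_path",
) -> ClassificationReport:
    """Stratified k-fold random-forest classification of stimulus labels.

    Accuracy is reported per fold (mean +/- SD); one-vs-rest ROC curves
    are computed from the pooled out-of-fold probability scores; feature
    attribution is averaged across the fold models on their held-out
    samples.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance
    from sklearn.metrics import roc_curve, auc
    from sklearn.model_selection import StratifiedKFold

    features = features or DEFAULT_CLASSIFIER_FEATURES
    if table[features].isna().any().any():
        raise ValueError("feature table contains missing values")
    X = table[features].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has n={counts.min()} < folds={folds}; "
            "reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    oof = np.zeros((len(y), len(classes)))
    attr = np.zeros(len(features))
    for tr_idx, te_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        clf.fit(X[tr_idx], y[tr_idx])
        accs.append(clf.score(X[te_idx], y[te_idx]))
        proba = clf.predict_proba(X[te_idx])
        cols = [list(clf.classes_).index(c) for c in classes]
        oof[te_idx] = proba[:, cols]
        if attribution_method == "tree_path":
            attr += tree_path_attribution(clf, X[te_idx])
        else:
            pi = permutation_importance(
                clf, X[te_idx], y[te_idx], n_repeats=5, random_state=seed
            )
            attr += np.abs(pi.importances_mean)
    attr /= folds
    accs = np.array(accs)
    roc = {}
    for j, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), oof[:, j])
        roc[c] = (fpr, tpr, float(auc(fpr, tpr)))
    attribution = pd.Series(attr, index=features).sort_values(ascending=False)
    return ClassificationReport(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)),
        classes=classes,
        roc=roc,
        attribution=attribution,
        features=list(features),
        seed=seed,
        oof_scores=oof,
        oof_labels=y,
    )


def feature_attribution(report: ClassificationReport) -> pd.Series:
    """Ranked mean |attribution| per feature from a classification run."""
    return report.attribution


def make_report(
    stats_results: list[GroupStatsResult],
    classification: ClassificationReport | None,
    outdir: str | Path,
    config_echo: dict | None = None,
    plots: bool = True,
) -> list[Path]:
    """Write CSV tables (stats, fold accuracy, ROC coordinates,
    attribution), plots, and a config echo; returns written paths."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    stats_df = (
        pd.concat([r.to_frame() for r in stats_results], ignore_index=True)
        if stats_results
        else pd.DataFrame(columns=["feature", "comparison", "statistic", "p"])
    )
    p = outdir / "group_stats.csv"
    stats_df.to_csv(p, index=False)
    written.append(p)

    if classification is not None:
        p = outdir / "fold_accuracy.csv"
        pd.DataFrame(
            {
                "fold": np.arange(len(classification.fold_accuracies)),
                "accuracy": classification.fold_accuracies,
            }
        ).to_csv(p, index=False)
        written.append(p)
        rows = []
        for c, (fpr, tpr, a) in classification.roc.items():
            for f, t in zip(fpr, tpr):
                rows.append({"class": c, "fpr": f, "tpr": t, "auc": a})
        p = outdir / "roc_curves.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
        p = outdir / "feature_attribution.csv"
        classification.attribution.rename("mean_abs_attribution").rename_axis(
            "feature"
        ).to_csv(p)
        written.append(p)
        if plots:
            written += _plot_classification(classification, outdir)
    echo = dict(config_echo or {})
    if classification is not None:
        echo.setdefault("seed", classification.seed)
    p = outdir / "run_config.json"
    p.write_text(json.dumps(echo, indent=2, default=str))
    written.append(p)
    return written


def _plot_classification(report: ClassificationReport, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for c, (fpr, tpr, a) in report.roc.items():
        ax.plot(fpr, tpr, label=f"{c} (AUC {a:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = outdir / "roc_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3))
    report.attribution.iloc[::-1].plot.barh(ax=ax)
    ax.set_xlabel("mean |attribution|")
    fig.tight_layout()
    p = outdir / "feature_attribution.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
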