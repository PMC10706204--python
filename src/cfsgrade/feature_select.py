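"""Four-step feature-selection cascade producing ranked signatures.

Starting from the z-score-normalized 974-feature table, the cascade is:

1. one-way ANOVA across the five OSS grades (keep p < alpha);
2. Pearson redundancy filter: greedy scan in descending ANOVA-F order,
   dropping any feature correlated at |r| >= threshold with a kept one;
3. backward elimination on an ordinary least-squares fit of the grade
   (treated as a numeric response) on the surviving features, repeatedly
   removing the least significant coefficient while its p exceeds p_out;
4. gini-impurity importance from a decision tree, ranking the survivors.

From the ranking four named signatures are built: the overall top-10
(``A-10``), the top-10 non-topological (``NT-10``), and the top-5
topological / non-topological subsets (``T-5`` / ``NT-5``).

Retained sets nest across stages; normalization statistics and every
selection decision are computed on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "Signature",
    "SelectionConfig",
    "anova_filter",
    "pearson_redundancy_filter",
    "backward_elimination",
    "tree_importance",
    "build_signatures",
    "run_selection",
]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05  # ANOVA retention level
    redundancy_threshold: float = 0.9  # |Pearson r| at which a feature is redundant
    p_out: float = 0.05  # backward-elimination exit level
    seed: int = 0


@dataclass
class FeatureTable:
    """Feature matrix (images x features), labels, and the normalization
    statistics the matrix was standardized with."""

    data: pd.DataFrame = field(repr=False)
    labels: np.ndarray = field(repr=False)
    norm_mean: pd.Series | None = field(default=None, repr=False)
    norm_std: pd.Series | None = field(default=None, repr=False)

    @classmethod
    def from_raw(cls, data: pd.DataFrame, labels) -> "FeatureTable":
        """Z-score normalize columns (constant columns map to 0)."""
        labels = np.asarray(labels)
        if len(labels) != len(data):
            raise ValueError("labels and rows must align")
        mean = data.mean()
        std = data.std(ddof=0).replace(0.0, 1.0)
        normed = (data - mean) / std
        return cls(data=normed, labels=labels, norm_mean=mean, norm_std=std)

    def apply_normalization(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Normalize held-out rows with the frozen training statistics."""
        return (raw[self.data.columns] - self.norm_mean) / self.norm_std

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class Signature:
    """Ordered selected features with provenance and importance scores."""

    names: list[str]
    importance: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)


def _anova_f(table: FeatureTable) -> pd.Series:
    """Per-feature one-way F statistic across the label classes."""
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (table.labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    groups = [table.data.values[table.labels == c] for c in classes]
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = stats.f_oneway(*groups)
    # degenerate features with zero within-class variance yield F = inf;
    # cap to keep orderings finite (ties then break by name downstream)
    f = np.nan_to_num(f, nan=0.0, posinf=1e30)
    return pd.Series(f, index=table.data.columns)


def anova_filter(table: FeatureTable, alpha: float = 0.05) -> list[str]:
    """Names of features whose one-way ANOVA across grades has p < alpha.

    Constant (zero between-class variance relative to noise) features yield
    NaN statistics and are removed.
    """
    classes = np.unique(table.labels)
    groups = [table.data.values[table.labels == c] for c in classes]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (table.labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups)
    p = np.where(np.isnan(p), 1.0, p)
    keep = np.asarray(p) < alpha
    return [n for n, k in zip(table.data.columns, keep) if k]


def pearson_redundancy_filter(
    table: FeatureTable, retained: list[str], threshold: float = 0.9
) -> list[str]:
    """Greedy redundancy removal in descending ANOVA-F order.

    A feature is dropped when |Pearson r| with any already-kept feature
    reaches the threshold, so of two near-duplicates the more
    class-separating one survives.
    """
    if not retained:
        return []
    f_stats = _anova_f(table)[retained]
    order = sorted(retained, key=lambda n: (-f_stats[n], n))
    X = table.data[order].values
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(abs(corr[i, j]) < threshold for j in kept_idx):
            kept_idx.append(i)
    kept = {order[i] for i in kept_idx}
    return [n for n in table.data.columns if n in kept]


def backward_elimination(
    table: FeatureTable, retained: list[str], p_out: float = 0.05
) -> list[str]:
    """OLS backward elimination of the grade-on-features regression.

    The grade is treated as a numeric response.  Exact collinears are
    dropped first (pivoted QR), then the largest-p coefficient is removed
    while it exceeds `p_out`, stopping when all remaining p < p_out or only
    two features remain.
    """
    current = [n for n in retained]
    if not current:
        return []
    y = table.labels.astype(float)
    # drop exact collinears so the design has full column rank
    X = table.data[current].values
    if X.shape[1] > 1:
        # greedy: keep columns that increase rank
        keep: list[int] = []
        basis = np.zeros((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([basis, X[:, j]])
            if np.linalg.matrix_rank(cand, tol=1e-8) > basis.shape[1]:
                keep.append(j)
                basis = cand
        current = [current[j] for j in keep]

    while len(current) > 2:
        design = sm.add_constant(table.data[current].values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(y, design).fit()
        pvals = fit.pvalues[1:]  # skip intercept
        worst = int(np.argmax(pvals))
        if pvals[worst] <= p_out:
            break
        current.pop(worst)
    return current


def tree_importance(
    table: FeatureTable, retained: list[str], seed: int = 0
) -> Signature:
    """Rank surviving features by total gini-impurity decrease in a
    decision-tree classifier (fixed seed); ties are broken by ANOVA F and
    then by name, so the ranking is reproducible."""
    if not retained:
        raise ValueError("no features retained for importance ranking")
    X = table.data[retained].values
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
    tree.fit(X, table.labels)
    imp = dict(zip(retained, tree.feature_importances_))
    f_stats = _anova_f(table)[retained]
    ranked = sorted(retained, key=lambda n: (-imp[n], -f_stats[n], n))
    return Signature(
        names=ranked,
        importance={n: float(imp[n]) for n in ranked},
        provenance={n: "anova>prbf>backward>tree" for n in ranked},
    )


def is_topological(name: str) -> bool:
    return name.startswith("topology-")


def build_signatures(signature: Signature) -> dict[str, Signature]:
    """The four named signatures: A-10, NT-10, T-5, NT-5.

    When fewer features than requested are available in a category, all of
    them are taken (with a warning).
    """
    ranked = signature.names

    def take(names: list[str], k: int, label: str) -> list[str]:
        if len(names) < k:
            warnings.warn(f"{label}: only {len(names)} features available, requested {k}")
        return names[:k]

    topo = [n for n in ranked if is_topological(n)]
    non_topo = [n for n in ranked if not is_topological(n)]
    subsets = {
        "A-10": take(ranked, 10, "A-10"),
        "NT-10": take(non_topo, 10, "NT-10"),
        "T-5": take(topo, 5, "T-5"),
        "NT-5": take(non_topo, 5, "NT-5"),
    }
    return {
        key: Signature(
            names=names,
            importance={n: signature.importance[n] for n in names},
            provenance={n: key for n in names},
        )
        for key, names in subsets.items()
    }


def run_selection(
    table: FeatureTable, cfg: SelectionConfig | None = None
) -> tuple[Signature, dict[str, list[str]]]:
    """Run the full cascade; returns the ranked signature and the per-stage
    retention lists (which nest)."""
    cfg = cfg or SelectionConfig()
    s1 = anova_filter(table, cfg.alpha)
    s2 = pearson_redundancy_filter(table, s1, cfg.redundancy_threshold)
    s3 = backward_elimination(table, s2, cfg.p_out)
    sig = tree_importance(table, s3, cfg.seed)
    stages = {"anova": s1, "prbf": s2, "backward": s3, "ranked": sig.names}
    return sig, stages
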