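"""Group- and individual-level statistics on inferred bifurcation parameters.

Group level: node-mean bifurcation values are compared across all cohort
pairs with the Mann-Whitney-Wilcoxon test under Benjamini-Hochberg false
discovery control.  Individual level: a linear SVM classifies subjects into
cohorts from their full bifurcation vector, with stratified cross-validation
and permutation feature importance identifying the discriminative regions.
Network level: rest-referenced activation maps aggregate node values into
canonical resting-state networks (seven cortical networks plus a subcortical
group).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .inference import CohortPredictions

__all__ = [
    "NetworkMap",
    "SvmResult",
    "node_mean",
    "pairwise_mwu_bh",
    "classify_cohorts_svm",
    "permutation_importance",
    "network_activation",
    "significance_band",
    "load_network_map",
    "default_network_map",
]


@dataclass(frozen=True)
class NetworkMap:
    """Assignment of each region to exactly one large-scale network."""

    region_to_network: dict
    networks: tuple

    def __post_init__(self):
        missing = set(self.region_to_network.values()) - set(self.networks)
        if missing:
            raise ValueError(f"labels not in network list: {sorted(missing)}")

    def indices(self, region_names) -> dict:
        """Map each network label to the positions of its regions."""
        out = {net: [] for net in self.networks}
        for i, r in enumerate(region_names):
            if r not in self.region_to_network:
                raise ValueError(f"region {r!r} is not mapped to any network")
            out[self.region_to_network[r]].append(i)
        return out


@dataclass(frozen=True)
class SvmResult:
    test_accuracy: float
    cv_mean: float
    cv_std: float
    confusion: np.ndarray
    classes: tuple
    model: object
    X_test: np.ndarray
    y_test: np.ndarray


def load_network_map(path: str | Path) -> NetworkMap:
    """Read a two-column region/network TSV into a NetworkMap."""
    df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    networks = tuple(dict.fromkeys(df.iloc[:, 1]))
    return NetworkMap(mapping, networks)


def default_network_map() -> NetworkMap:
    """The editable DK80 table shipped with the package (7 Yeo + Subcortical)."""
    with resources.as_file(resources.files("hopfbif.data") / "dk80_yeo_map.tsv") as p:
        return load_network_map(p)


def node_mean(preds: CohortPredictions) -> np.ndarray:
    """Mean bifurcation value over nodes, per cohort and subject (C x S)."""
    return preds.a_hat.mean(axis=2)


def significance_band(p: float) -> str:
    """Asterisk convention: **** p<=1e-4, *** <=1e-3, ** <=0.01, * <=0.05, else ns."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def pairwise_mwu_bh(
    values: np.ndarray,
    cohort_labels=None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """All pairwise Mann-Whitney-Wilcoxon tests with joint BH correction.

    ``values`` is C x S (cohorts by subjects).  Returns one row per cohort
    pair with the U statistic, raw and BH-adjusted p-values and the
    significance band of the adjusted value.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("values must be C x S with C >= 2 and S >= 2")
    C = values.shape[0]
    if cohort_labels is None:
        cohort_labels = [f"cohort{c}" for c in range(C)]
    rows = []
    for i in range(C):
        for j in range(i + 1, C):
            res = stats.mannwhitneyu(values[i], values[j], alternative=alternative, method="auto")
            rows.append({"cohort_a": cohort_labels[i], "cohort_b": cohort_labels[j],
                         "U": float(res.statistic), "p_raw": float(res.pvalue)})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    table["significance"] = table["p_adj"].map(significance_band)
    return table


def classify_cohorts_svm(
    features: np.ndarray,
    labels,
    test_fraction: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    C_reg: float = 1.0,
) -> SvmResult:
    """Linear-kernel SVM cohort classification with stratified evaluation.

    Features are standardized with training-split statistics inside a
    pipeline; data are split stratified 80/20, cross-validation runs on the
    training portion only, and the confusion matrix holds raw held-out
    counts (row-normalize for recall when displaying).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= cv_folds ({cv_folds})"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C_reg, random_state=seed))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(pipe, X_tr, y_tr, cv=cv, scoring="accuracy")
    pipe.fit(X_tr, y_tr)
    y_pred = pipe.predict(X_te)
    return SvmResult(
        test_accuracy=float(accuracy_score(y_te, y_pred)),
        cv_mean=float(cv_scores.mean()),
        cv_std=float(cv_scores.std()),
        confusion=confusion_matrix(y_te, y_pred, labels=classes),
        classes=tuple(classes),
        model=pipe,
        X_test=X_te,
        y_test=y_te,
    )


def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    feature_names=None,
) -> pd.DataFrame:
    """Per-feature mean/std accuracy drop when that feature is shuffled.

    Each column is shuffled ``n_repeats`` times with the others held fixed;
    the drop is baseline accuracy minus permuted accuracy.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 for a standard deviation")
    res = _sk_permutation_importance(
        model, X_test, y_test, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    n_feat = X_test.shape[1]
    if feature_names is None:
        feature_names = [f"region{i:03d}" for i in range(n_feat)]
    return pd.DataFrame(
        {"feature": list(feature_names), "mean_drop": res.importances_mean,
         "std_drop": res.importances_std}
    )


def network_activation(
    preds: CohortPredictions,
    network_map: NetworkMap,
    rest_label: str,
    region_names=None,
) -> pd.DataFrame:
    """Rest-referenced mean bifurcation change per network and task cohort.

    Subject means give a C x N matrix; the rest cohort's row is subtracted
    from every task row; nodes are then averaged within each network,
    yielding a (C-1) x B table.
    """
    if rest_label not in preds.cohort_labels:
        raise ValueError(f"rest cohort {rest_label!r} not found")
    N = preds.a_hat.shape[2]
    if region_names is None:
        region_names = [f"region{i:03d}" for i in range(N)]
    idx = network_map.indices(region_names)
    cohort_mean = preds.a_hat.mean(axis=1)  # C x N
    rest_row = cohort_mean[preds.cohort_labels.index(rest_label)]
    rows = {}
    for label, row in zip(preds.cohort_labels, cohort_mean):
        if label == rest_label:
            continue
        delta = row - rest_row
        rows[label] = [delta[idx[net]].mean() if idx[net] else np.nan for net in network_map.networks]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(network_map.networks))
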