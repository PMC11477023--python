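"""Damage-classifier screen: threshold classifiers, feature selection, CV.

Given the activity matrix of the high- and low-damage cohorts, the screen
evaluates every protein as a single-variable classifier (optimal linear or
quadratic threshold found by exhaustive search over inter-sample midpoints)
and feature-selected protein pairs under GLM-binomial, Gaussian naive-Bayes
or small-MLP classifiers. Performance is measured by threshold-averaging
stratified 10-fold cross-validation: the per-fold fitted parameters are
averaged into the final reported classifier, the cross-validated accuracy
is the mean held-out accuracy, and the cross-validated p-value is a
one-sided exact binomial test of the pooled held-out correct count against
the majority-class rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .ensemble import SolutionEnsemble
from .errors import ConfigError, EmptyScreenError, FoldError, ValidationError

ONE_VAR_FAMILIES = ("linear-threshold", "quadratic-threshold")
TWO_VAR_FAMILIES = ("glm-binomial", "naive-bayes", "mlp")
FEATURE_METHODS = ("chow-liu", "mrmr", "relieff", "rfe-svm", "sffs", "wilcoxon-corr")

VAR_EPSILON = 1e-12


@dataclass(frozen=True)
class ClassifierSpec:
    variables: tuple[str, ...]
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.variables) == 1 and self.family not in ONE_VAR_FAMILIES:
            raise ValidationError(
                f"1-variable classifiers use threshold families, not {self.family}"
            )
        if len(self.variables) == 2 and self.family not in TWO_VAR_FAMILIES:
            raise ValidationError(
                f"2-variable classifiers use {TWO_VAR_FAMILIES}, not {self.family}"
            )


@dataclass
class ScreenResult:
    spec: ClassifierSpec
    cv_accuracy: float  # percent
    cv_pvalue: float
    final_params: dict
    fold_accuracies: list[float]  # percent


@dataclass
class ScreenConfig:
    k_folds: int = 10
    methods: tuple[str, ...] = FEATURE_METHODS
    top_k: int = 5
    families: tuple[str, ...] = TWO_VAR_FAMILIES
    exhaustive_pairs: bool = False
    var_epsilon: float = VAR_EPSILON
    seed: int = 0

    def __post_init__(self):
        for m in self.methods:
            if m not in FEATURE_METHODS:
                raise ConfigError(f"unknown feature-selection method {m!r}")
        for f in self.families:
            if f not in TWO_VAR_FAMILIES:
                raise ConfigError(f"unknown 2-variable family {f!r}")


def pair_universe(p: int) -> int:
    """Number of ordered variable pairs among p variables: p·(p−1)."""
    return p * (p - 1)


# ---------------------------------------------------------------------------
# cleaning


def clean_variables(
    ensemble: SolutionEnsemble, labels, var_epsilon: float = VAR_EPSILON
) -> list[str]:
    """Drop variables that are constant or near-constant across samples."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("need two label groups")
    variances = ensemble.matrix.var(axis=0)
    kept = [p for p, v in zip(ensemble.protein_index, variances) if v >= var_epsilon]
    if not kept:
        raise EmptyScreenError("every variable is uninformative")
    return kept


# ---------------------------------------------------------------------------
# 1-variable threshold classifiers


def _candidate_cuts(xs: np.ndarray) -> np.ndarray:
    """Cut grid: midpoints between consecutive distinct sorted values plus
    one cut below and one above the sample range."""
    distinct = np.unique(xs)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def fit_threshold_1d(values, labels, mode: str = "linear") -> tuple[dict, float]:
    """Exhaustive optimal threshold classifier on one variable.

    linear: one cut with an orientation (class 1 above or below);
    quadratic: one interval classified inside-vs-outside. Ties resolve to
    the smallest threshold, then the narrowest interval, then the
    class-1-above / class-1-inside orientation. Returns (params, training
    accuracy as a fraction).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim != 1 or len(x) != len(y):
        raise ValidationError("values and labels must be equal-length 1-D")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 < 1 or n1 < 1:
        raise ValidationError("both classes must be present")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cuts = _candidate_cuts(xs)
    pos = np.searchsorted(xs, cuts)  # samples strictly below each cut
    cum1 = np.concatenate(([0], np.cumsum(ys)))
    below1 = cum1[pos]
    below0 = pos - below1

    if mode == "linear":
        acc_up = (n1 - below1) + below0  # class 1 iff x >= cut
        acc_dn = below1 + (n0 - below0)  # class 1 iff x < cut
        best = max(acc_up.max(), acc_dn.max())
        # ties: smallest cut, then the "up" orientation
        idx_up = np.flatnonzero(acc_up == best)
        idx_dn = np.flatnonzero(acc_dn == best)
        cut_up = cuts[idx_up[0]] if len(idx_up) else np.inf
        cut_dn = cuts[idx_dn[0]] if len(idx_dn) else np.inf
        if cut_up <= cut_dn:
            params = {"cut": float(cut_up), "direction": 1}
        else:
            params = {"cut": float(cut_dn), "direction": -1}
        return params, best / len(y)

    if mode == "quadratic":
        # interval [cuts[i], cuts[j]] with i<j; counts inside via prefix sums
        in1 = below1[None, :] - below1[:, None]  # class-1 count in [cut_i, cut_j)
        in0 = below0[None, :] - below0[:, None]
        acc_in = in1 + (n0 - in0)  # class 1 iff inside
        acc_out = (n1 - in1) + in0  # class 1 iff outside
        iu = np.triu_indices(len(cuts), k=1)
        flat_in, flat_out = acc_in[iu], acc_out[iu]
        best = int(max(flat_in.max(), flat_out.max()))
        lo_idx, hi_idx = iu
        width = cuts[hi_idx] - cuts[lo_idx]

        def pick(flat):
            mask = flat == best
            if not mask.any():
                return None
            cand = np.flatnonzero(mask)
            key = np.lexsort((width[cand], cuts[lo_idx[cand]]))
            c = cand[key[0]]
            return float(cuts[lo_idx[c]]), float(cuts[hi_idx[c]])

        choice_in = pick(flat_in)
        choice_out = pick(flat_out)
        if choice_in is not None and (
            choice_out is None
            or (choice_in[0], choice_in[1] - choice_in[0])
            <= (choice_out[0], choice_out[1] - choice_out[0])
        ):
            lo, hi = choice_in
            params = {"low": lo, "high": hi, "inside": 1}
        else:
            lo, hi = choice_out
            params = {"low": lo, "high": hi, "inside": 0}
        return params, best / len(y)

    raise ConfigError(f"unknown threshold mode {mode!r}")


def predict_threshold(params: dict, values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if "cut" in params:
        above = x >= params["cut"]
        return (above if params["direction"] == 1 else ~above).astype(int)
    inside = (x >= params["low"]) & (x <= params["high"])
    return (inside if params["inside"] == 1 else ~inside).astype(int)


# ---------------------------------------------------------------------------
# feature selection for 2-variable classifiers


def _f_relevance(X, y):
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _rank_mrmr(X, y, top_k):
    rel = _f_relevance(X, y)
    rel = rel / rel.max() if rel.max() > 0 else rel
    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.abs(np.atleast_2d(corr)), nan=1.0)
    selected = [int(np.argmax(rel))]
    while len(selected) < min(top_k, X.shape[1]):
        redundancy = corr[:, selected].mean(axis=1)
        score = rel - redundancy
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def _rank_relieff(X, y, top_k, k_neighbors=10):
    rng_range = X.max(axis=0) - X.min(axis=0)
    rng_range[rng_range == 0] = 1.0
    Z = (X - X.min(axis=0)) / rng_range
    n = len(y)
    k = min(k_neighbors, min(np.bincount(y)) - 1)
    k = max(k, 1)
    d2 = np.square(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(X.shape[1])
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        diff = np.flatnonzero(y != y[i])
        hits = same[np.argsort(d2[i, same], kind="stable")[:k]]
        misses = diff[np.argsort(d2[i, diff], kind="stable")[:k]]
        w += np.abs(Z[i] - Z[misses]).mean(axis=0) - np.abs(Z[i] - Z[hits]).mean(axis=0)
    return list(np.argsort(-w, kind="stable")[:top_k])


def _rank_rfe_svm(X, y, top_k):
    est = LinearSVC(C=1.0, dual=False, max_iter=5000)
    rfe = RFE(est, n_features_to_select=min(top_k, X.shape[1]), step=0.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        rfe.fit(X, y)
    chosen = np.flatnonzero(rfe.support_)
    coef = np.abs(rfe.estimator_.coef_).ravel()
    return list(chosen[np.argsort(-coef, kind="stable")])


def _lda_cv_score(X, y, cols):
    sub = X[:, cols]
    skf = StratifiedKFold(n_splits=3, shuffle=False)
    accs = []
    for tr, te in skf.split(sub, y):
        lda = LinearDiscriminantAnalysis()
        lda.fit(sub[tr], y[tr])
        accs.append(float((lda.predict(sub[te]) == y[te]).mean()))
    return float(np.mean(accs))


def _rank_sffs(X, y, top_k):
    """Sequential floating forward selection with an LDA wrapper criterion."""
    p = X.shape[1]
    target = min(top_k, p)
    best_at_size: dict[int, float] = {}
    S: list[int] = []
    while len(S) < target:
        scores = [
            (_lda_cv_score(X, y, S + [j]), -j) for j in range(p) if j not in S
        ]
        score, negj = max(scores)
        S.append(-negj)
        best_at_size[len(S)] = max(best_at_size.get(len(S), -1.0), score)
        # conditional exclusion: drop a member if the reduced set beats the
        # best set of that size seen so far
        while len(S) > 2:
            drops = [
                (_lda_cv_score(X, y, [s for s in S if s != r]), -r) for r in S
            ]
            d_score, negr = max(drops)
            if d_score > best_at_size.get(len(S) - 1, -1.0) + 1e-12:
                S.remove(-negr)
                best_at_size[len(S)] = d_score
            else:
                break
    return S


def _rank_wilcoxon_corr(X, y, top_k, corr_cap=0.9):
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = X[y == 0, j], X[y == 1, j]
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            continue
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    order = np.argsort(pvals, kind="stable")
    kept: list[int] = []
    for j in order:
        if len(kept) >= top_k:
            break
        if kept:
            c = np.abs(
                np.corrcoef(X[:, kept + [j]], rowvar=False)[-1, :-1]
            )
            if np.nan_to_num(c, nan=1.0).max() >= corr_cap:
                continue
        kept.append(int(j))
    for j in order:  # backfill if the correlation cap exhausted the list
        if len(kept) >= top_k:
            break
        if j not in kept:
            kept.append(int(j))
    return kept


def _discretize(X, bins=4):
    out = np.empty_like(X, dtype=int)
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], np.linspace(0, 1, bins + 1)[1:-1])
        out[:, j] = np.searchsorted(edges, X[:, j])
    return out


def _plugin_mi(a, b):
    joint = pd.crosstab(a, b).to_numpy(dtype=float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return float(np.nansum(terms))


def _rank_chow_liu(X, y, top_k):
    """Chow–Liu dependence tree over variables + label; rank by proximity
    to the label node in the maximum mutual-information spanning tree."""
    import networkx as nx

    D = _discretize(X)
    p = X.shape[1]
    g = nx.Graph()
    label_node = "__label__"
    mi_label = {}
    for j in range(p):
        mi_label[j] = _plugin_mi(D[:, j], y)
        g.add_edge(label_node, j, weight=mi_label[j])
    for i in range(p):
        for j in range(i + 1, p):
            g.add_edge(i, j, weight=_plugin_mi(D[:, i], D[:, j]))
    tree = nx.maximum_spanning_tree(g, weight="weight")
    dist = nx.single_source_shortest_path_length(tree, label_node)
    ranked = sorted(
        range(p), key=lambda j: (dist.get(j, np.inf), -mi_label[j], j)
    )
    return ranked[:top_k]


_RANKERS = {
    "chow-liu": _rank_chow_liu,
    "mrmr": _rank_mrmr,
    "relieff": _rank_relieff,
    "rfe-svm": _rank_rfe_svm,
    "sffs": _rank_sffs,
    "wilcoxon-corr": _rank_wilcoxon_corr,
}


def select_feature_pairs(
    ensemble: SolutionEnsemble,
    labels,
    methods=FEATURE_METHODS,
    top_k: int = 5,
    seed: int = 0,
    variables: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Ordered candidate pairs: each method's top_k variables paired among
    themselves; the union over methods, first-occurrence order."""
    for m in methods:
        if m not in _RANKERS:
            raise ConfigError(f"unknown feature-selection method {m!r}")
    variables = variables or list(ensemble.protein_index)
    X = ensemble.columns(variables)
    y = np.asarray(labels).astype(int)
    pairs: list[tuple[str, str]] = []
    seen = set()
    for m in methods:
        idx = _RANKERS[m](X, y, top_k)
        names = [variables[j] for j in idx]
        for a in names:
            for b in names:
                if a != b and (a, b) not in seen:
                    seen.add((a, b))
                    pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# cross-validation


def _pooled_cv_pvalue(correct: int, n: int, p0: float, k: int) -> float:
    """One-sided test of the pooled held-out correct rate against p0.

    Held-out predictions from k-fold CV are not independent: every pair of
    folds shares most of its training data, which inflates the variance of
    the pooled correct count by roughly 1 + k·(n_test/n_train) relative to a
    binomial (the Nadeau–Bengio correction; measured empirically at ≈2 for
    k=10). A naive exact binomial is therefore anti-conservative; we test
    the pooled rate with the inflation-corrected normal tail instead.
    """
    if n == 0:
        return 1.0
    vif = 1.0 + k / max(k - 1.0, 1.0)
    se = np.sqrt(p0 * (1 - p0) * vif / n)
    if se == 0:
        return 1.0 if correct / n <= p0 else float(np.nextafter(0, 1))
    z = (correct / n - p0) / se
    pvalue = stats.norm.sf(z)
    return float(min(max(pvalue, np.nextafter(0, 1)), 1.0))


def _fit_predict_family(family, Xtr, ytr, Xte, seed):
    if family == "glm-binomial":
        model = LogisticRegression(solver="lbfgs", max_iter=1000)
    elif family == "naive-bayes":
        model = GaussianNB()
    elif family == "mlp":
        model = MLPClassifier(
            hidden_layer_sizes=(3,), max_iter=500, random_state=seed
        )
    else:
        raise ConfigError(f"unknown family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    if family == "glm-binomial":
        params = {
            "intercept": float(model.intercept_[0]),
            "coef": model.coef_.ravel().tolist(),
        }
    elif family == "naive-bayes":
        params = {
            "theta": model.theta_.tolist(),
            "var": model.var_.tolist(),
            "priors": model.class_prior_.tolist(),
        }
    else:
        params = {
            "coefs": [c.tolist() for c in model.coefs_],
            "intercepts": [b.tolist() for b in model.intercepts_],
        }
    return pred, params


def _average_params(family: str, fold_params: list[dict]) -> dict:
    """Parameter-wise arithmetic mean across folds (threshold averaging)."""

    def mean_of(key):
        return np.mean([np.asarray(p[key], dtype=float) for p in fold_params], axis=0)

    if family == "linear-threshold":
        dirs = [p["direction"] for p in fold_params]
        direction = 1 if sum(dirs) >= 0 else -1
        return {"cut": float(mean_of("cut")), "direction": direction}
    if family == "quadratic-threshold":
        insides = [p["inside"] for p in fold_params]
        return {
            "low": float(mean_of("low")),
            "high": float(mean_of("high")),
            "inside": 1 if sum(insides) >= len(insides) / 2 else 0,
        }
    if family == "glm-binomial":
        return {
            "intercept": float(mean_of("intercept")),
            "coef": mean_of("coef").tolist(),
        }
    if family == "naive-bayes":
        return {k: mean_of(k).tolist() for k in ("theta", "var", "priors")}
    if family == "mlp":
        n_layers = len(fold_params[0]["coefs"])
        return {
            "coefs": [
                np.mean(
                    [np.asarray(p["coefs"][li]) for p in fold_params], axis=0
                ).tolist()
                for li in range(n_layers)
            ],
            "intercepts": [
                np.mean(
                    [np.asarray(p["intercepts"][li]) for p in fold_params], axis=0
                ).tolist()
                for li in range(n_layers)
            ],
        }
    raise ConfigError(f"unknown family {family!r}")


def cross_validate(
    family: str,
    variables: tuple[str, ...],
    ensemble: SolutionEnsemble,
    labels,
    k: int = 10,
    seed: int = 0,
) -> ScreenResult:
    """Threshold-averaging stratified k-fold CV of one classifier spec."""
    y = np.asarray(labels).astype(int)
    variables = tuple(variables)
    X = ensemble.columns(list(variables))
    counts = np.bincount(y)
    if k > counts.min():
        raise FoldError(
            f"k={k} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accs: list[float] = []
    fold_params: list[dict] = []
    pooled_correct = 0
    pooled_n = 0
    is_threshold = family in ONE_VAR_FAMILIES
    mode = "linear" if family == "linear-threshold" else "quadratic"
    for tr, te in skf.split(X, y):
        if is_threshold:
            params, _ = fit_threshold_1d(X[tr, 0], y[tr], mode=mode)
            pred = predict_threshold(params, X[te, 0])
        else:
            pred, params = _fit_predict_family(family, X[tr], y[tr], X[te], seed)
        correct = int((pred == y[te]).sum())
        fold_accs.append(100.0 * correct / len(te))
        fold_params.append(params)
        pooled_correct += correct
        pooled_n += len(te)

    p0 = counts.max() / counts.sum()  # majority-class baseline rate
    pvalue = _pooled_cv_pvalue(pooled_correct, pooled_n, p0, k)
    return ScreenResult(
        spec=ClassifierSpec(
            variables=variables, family=family, params=_average_params(family, fold_params)
        ),
        cv_accuracy=float(np.mean(fold_accs)),
        cv_pvalue=pvalue,
        final_params=_average_params(family, fold_params),
        fold_accuracies=fold_accs,
    )


# ---------------------------------------------------------------------------
# full screen


@dataclass
class ScreenOutput:
    results: list[ScreenResult]
    kept_variables: list[str]
    pair_universe: int  # ordered-pair count p·(p−1) over surviving variables
    n_pairs_evaluated: int

    def to_frame(self) -> pd.DataFrame:
        import json as _json

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.results) + 1),
                "variables": [";".join(r.spec.variables) for r in self.results],
                "family": [r.spec.family for r in self.results],
                "cv_accuracy": [r.cv_accuracy for r in self.results],
                "cv_pvalue": [r.cv_pvalue for r in self.results],
                "final_params_json": [
                    _json.dumps(r.final_params) for r in self.results
                ],
            }
        )


def screen_all(
    ensemble: SolutionEnsemble, labels, config: ScreenConfig | None = None
) -> ScreenOutput:
    """Evaluate every surviving single variable and all candidate pairs.

    Per variable the better of the linear and quadratic threshold modes is
    kept; per pair the best of the enabled 2-variable families. Results are
    sorted by cv_accuracy descending, cv_pvalue ascending, then variable
    ids. The reported pair universe counts ordered pairs p·(p−1) over the
    cleaned variables even when feature selection evaluates fewer.
    """
    config = config or ScreenConfig()
    y = np.asarray(labels).astype(int)
    kept = clean_variables(ensemble, y, config.var_epsilon)

    results: list[ScreenResult] = []
    for v in kept:
        best = None
        for family in ONE_VAR_FAMILIES:
            r = cross_validate(family, (v,), ensemble, y, k=config.k_folds, seed=config.seed)
            if best is None or (-r.cv_accuracy, r.cv_pvalue) < (
                -best.cv_accuracy,
                best.cv_pvalue,
            ):
                best = r
        results.append(best)

    if config.exhaustive_pairs:
        pairs = [(a, b) for a in kept for b in kept if a != b]
    elif config.methods and len(kept) >= 2:
        pairs = select_feature_pairs(
            ensemble, y, methods=config.methods, top_k=config.top_k,
            seed=config.seed, variables=kept,
        )
    else:
        pairs = []

    for pair in pairs:
        best = None
        for family in config.families:
            r = cross_validate(family, pair, ensemble, y, k=config.k_folds, seed=config.seed)
            if best is None or (-r.cv_accuracy, r.cv_pvalue) < (
                -best.cv_accuracy,
                best.cv_pvalue,
            ):
                best = r
        if best is not None:
            results.append(best)

    results.sort(key=lambda r: (-r.cv_accuracy, r.cv_pvalue, r.spec.variables))
    return ScreenOutput(
        results=results,
        kept_variables=kept,
        pair_universe=pair_universe(len(kept)),
        n_pairs_evaluated=len(pairs),
    )
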