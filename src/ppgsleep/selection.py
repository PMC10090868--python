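"""Statistical feature selection and feature-strength ranking.

For the two-class (sleep/wake) problem, features are screened with the
Kruskal-Wallis test and kept at p < alpha.  For the three- and four-class
problems each feature receives a ``sigPair`` score: the number of class
pairs whose two-group nonparametric test falls below alpha.  A feature is
selected when it separates at least 2 of the 3 pairs (three-class) or 5 of
the 6 pairs (four-class).  Shapiro-Wilk normality screening motivates the
nonparametric path and is reported, not gating.

Feature strength is the Spearman rank correlation between the feature and
the ordinal stage encoding (WAKE=0 < LS=1 < DS=2 < REM=3 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stages import SCHEME_CLASSES, encode_labels

SIGPAIR_MIN = {"three": 2, "four": 5}


def class_pairs(scheme: str) -> list[tuple[str, str]]:
    """All unordered class pairs of a scheme, in canonical order.

    One pair for two-class, three for three-class (wake/NREM, wake/REM,
    NREM/REM) and six for four-class.
    """
    if scheme not in SCHEME_CLASSES:
        raise ValueError(f"unknown scheme {scheme!r}")
    return list(itertools.combinations(SCHEME_CLASSES[scheme], 2))


@dataclass
class SelectionReport:
    """Per-feature selection statistics.

    ``table`` is indexed by feature name with columns ``kw_p`` (two-class)
    or one ``p_<A>_vs_<B>`` column per pair plus ``sigPair``, and always
    ``spearman_r``, ``selected`` and ``rank``.
    """

    scheme: str
    alpha: float
    table: pd.DataFrame
    g_t: int = field(default=0)

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")

    @classmethod
    def from_csv(cls, path, scheme: str = "four", alpha: float = 0.05
                 ) -> "SelectionReport":
        table = pd.read_csv(path, index_col="feature")
        table.index.name = None
        table["selected"] = table["selected"].astype(bool)
        n_classes = len(SCHEME_CLASSES[scheme])
        return cls(scheme=scheme, alpha=alpha, table=table,
                   g_t=n_classes * (n_classes - 1) // 2)


def _group_values(X: pd.DataFrame, labels: np.ndarray, cls: str,
                  feature: str) -> np.ndarray:
    v = X.loc[labels == cls, feature].to_numpy(dtype=float)
    return v[np.isfinite(v)]


def shapiro_normality(X: pd.DataFrame, labels) -> pd.DataFrame:
    """Shapiro-Wilk p-value of every feature within every class.

    A constant (zero-variance) group gets p = 0 with a warning, marking it
    maximally non-normal for the screening's purpose.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    out = pd.DataFrame(index=X.columns, columns=classes, dtype=float)
    for cls in classes:
        for feat in X.columns:
            v = _group_values(X, labels, cls, feat)
            if len(v) < 3:
                out.loc[feat, cls] = np.nan
                continue
            if np.ptp(v) == 0:
                warnings.warn(f"feature {feat!r} constant within class {cls}")
                out.loc[feat, cls] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.loc[feat, cls] = stats.shapiro(v).pvalue
    return out


def _kw_p(groups: list[np.ndarray]) -> float:
    if any(len(g) == 0 for g in groups):
        return np.nan
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0  # no group difference possible
    res = stats.kruskal(*groups)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # H can round to a tiny negative number when the rank sums are
        # exactly balanced; that is zero evidence against the null
        return 1.0 if res.statistic <= 0 else p
    return p


def kruskal_wallis_select(X: pd.DataFrame, labels, alpha: float = 0.05
                          ) -> SelectionReport:
    """Two-class feature screening: Kruskal-Wallis p < alpha."""
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    rows = {}
    for feat in X.columns:
        groups = [_group_values(X, labels, c, feat) for c in classes]
        rows[feat] = _kw_p(groups)
    table = pd.DataFrame({"kw_p": pd.Series(rows)})
    table["selected"] = table["kw_p"] < alpha
    table["rank"] = table["kw_p"].rank(method="first").astype(int)
    table["spearman_r"] = spearman_strength(X, labels, scheme="two")
    table = table.loc[list(X.columns)]
    return SelectionReport(scheme="two", alpha=alpha, table=table, g_t=1)


def sigpair_rank(X: pd.DataFrame, labels, scheme: str, alpha: float = 0.05,
                 adjust: str | None = None) -> SelectionReport:
    """Pairwise-significance selection for the multi-class schemes.

    Each class pair is tested with a two-group Kruskal-Wallis (rank-sum)
    test; sigPair counts the pairs with p < alpha (unadjusted by default,
    ``adjust="bonferroni"`` multiplies p by the number of pairs).  Features
    rank by descending sigPair, ties broken by ascending mean pairwise p,
    and are selected at sigPair >= 2 (three-class) / >= 5 (four-class).
    """
    if scheme not in SIGPAIR_MIN:
        raise ValueError(f"sigPair selection applies to three/four-class, "
                         f"not {scheme!r}")
    labels = np.asarray(labels)
    pairs = class_pairs(scheme)
    present = set(labels)
    missing = [c for c in SCHEME_CLASSES[scheme] if c not in present]
    if missing:
        raise ValueError(f"classes missing from labels: {missing}")
    pcols = {}
    for a, b in pairs:
        ps = []
        for feat in X.columns:
            p = _kw_p([_group_values(X, labels, a, feat),
                       _group_values(X, labels, b, feat)])
            if adjust == "bonferroni" and np.isfinite(p):
                p = min(1.0, p * len(pairs))
            ps.append(p)
        pcols[f"p_{a}_vs_{b}"] = ps
    table = pd.DataFrame(pcols, index=X.columns)
    pv = table.to_numpy(dtype=float)
    table["sigPair"] = (pv < alpha).sum(axis=1)
    table["mean_pair_p"] = np.nanmean(pv, axis=1)
    table["selected"] = table["sigPair"] >= SIGPAIR_MIN[scheme]
    order = table.sort_values(["sigPair", "mean_pair_p"],
                              ascending=[False, True], kind="stable")
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["spearman_r"] = spearman_strength(X, labels, scheme=scheme)
    return SelectionReport(scheme=scheme, alpha=alpha, table=table,
                           g_t=len(pairs))


def spearman_strength(X: pd.DataFrame, labels, scheme: str = "four"
                      ) -> pd.Series:
    """Spearman rank correlation of each feature with the stage encoding.

    Zero-variance features get r = 0 with a warning; |r| orders the
    strength ranking.
    """
    y = np.asarray(encode_labels(list(labels), scheme), dtype=float)
    out = {}
    for feat in X.columns:
        v = X[feat].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or np.ptp(v[ok]) == 0:
            warnings.warn(f"feature {feat!r} has no variance; r set to 0")
            out[feat] = 0.0
            continue
        out[feat] = float(stats.spearmanr(v[ok], y[ok]).statistic)
    return pd.Series(out)


def select_features(X: pd.DataFrame, labels, scheme: str,
                    alpha: float = 0.05) -> SelectionReport:
    """Scheme dispatch: Kruskal-Wallis for two-class, sigPair otherwise."""
    if scheme == "two":
        return kruskal_wallis_select(X, labels, alpha)
    return sigpair_rank(X, labels, scheme, alpha)
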