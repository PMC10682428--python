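"""Classical reference-gene stability algorithms and a rank-aggregate comparison.

Three widely used single-candidate stability measures are implemented for
benchmarking the combinatorial method against:

* geNorm — M_j is the mean, over the other candidates k, of the sample SD
  of the pairwise difference Cq_j - Cq_k (the log-ratio SD under perfect
  doubling); candidates are excluded stepwise from the highest M.
* BestKeeper — per-candidate Cq SD and CV, plus the Pearson correlation of
  each candidate against the BestKeeper index (the per-sample mean Cq of
  all candidates).
* NormFinder — a model-based decomposition on sample-centred Cq: for each
  candidate the stability value adds the mean absolute intergroup bias of
  the group means to the mean group-mean uncertainty sqrt(s^2/n).  Lower is
  more stable.  With a single group it falls back to the SD of the
  candidate-minus-sample-mean residuals.

All three operate on Cq directly under the perfect-doubling convention
(log2 expression = -Cq), matching the ddCq arithmetic used elsewhere in the
package.  ``aggregate_and_compare`` ranks all size-k combinations under
each method (single-candidate methods score a combination by the mean of
its members' stabilities — a documented convention of this package) plus a
mean-rank aggregate, and reports cross-method Spearman correlations.
"""

from __future__ import annotations

import warnings
from itertools import combinations as iter_combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .ranking import run_bestmirnorm

__all__ = [
    "genorm",
    "bestkeeper",
    "normfinder",
    "aggregate_and_compare",
    "GeNorm",
    "BestKeeper",
    "NormFinder",
]


def _check_input(cq: pd.DataFrame, candidates, min_candidates: int) -> list[str]:
    candidates = list(candidates) if candidates is not None else list(cq.columns)
    absent = [c for c in candidates if c not in cq.columns]
    if absent:
        raise ValueError(f"candidate assay(s) absent from Cq table: {absent}")
    if len(candidates) < min_candidates:
        raise ValueError(f"need at least {min_candidates} candidates")
    if cq.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    return candidates


def _genorm_m(values: np.ndarray) -> np.ndarray:
    """geNorm M per column: mean over other columns of SD(col_j - col_k)."""
    n = values.shape[1]
    m = np.zeros(n)
    for j in range(n):
        sds = [
            np.nanstd(values[:, j] - values[:, k], ddof=1)
            for k in range(n)
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return m


def genorm(cq: pd.DataFrame, candidates=None) -> pd.DataFrame:
    """geNorm stability values and stepwise exclusion order.

    Returns one row per candidate with ``M`` (lower = more stable) computed
    on the full panel, and ``exclusion_step``: 1 for the first candidate
    removed (least stable), increasing; the final most-stable pair shares
    the highest step number.
    """
    candidates = _check_input(cq, candidates, min_candidates=2)
    values = cq[candidates].to_numpy(float)
    m_full = _genorm_m(values)

    remaining = list(range(len(candidates)))
    exclusion_step = {}
    step = 1
    while len(remaining) > 2:
        m = _genorm_m(values[:, remaining])
        worst = remaining[int(np.argmax(m))]
        exclusion_step[worst] = step
        remaining.remove(worst)
        step += 1
    for idx in remaining:
        exclusion_step[idx] = step
    out = pd.DataFrame(
        {
            "M": m_full,
            "exclusion_step": [exclusion_step[i] for i in range(len(candidates))],
        },
        index=pd.Index(candidates, name="candidate"),
    )
    return out.sort_values("M")


def bestkeeper(cq: pd.DataFrame, candidates=None) -> pd.DataFrame:
    """BestKeeper descriptive stability: SD, CV (%), r against the index.

    The index is the per-sample arithmetic mean of candidate Cq.  A
    zero-variance candidate gets r = NaN with a reason rather than an
    arbitrary value.
    """
    candidates = _check_input(cq, candidates, min_candidates=1)
    sub = cq[candidates]
    index = sub.mean(axis=1)
    rows = []
    for c in candidates:
        x = sub[c].dropna()
        sd = x.std(ddof=1)
        cv = 100.0 * sd / x.mean() if x.mean() != 0 else np.nan
        if len(candidates) == 1:
            r, reason = 1.0, ""
        elif sd == 0 or index.loc[x.index].std(ddof=1) == 0:
            r, reason = np.nan, "zero variance"
        else:
            r = float(stats.pearsonr(x, index.loc[x.index]).statistic)
            reason = ""
        rows.append({"candidate": c, "SD": sd, "CV_pct": cv, "r": r, "reason": reason})
    return pd.DataFrame(rows).set_index("candidate")


def normfinder(
    cq: pd.DataFrame, candidates=None, groups: pd.Series | None = None
) -> pd.DataFrame:
    """NormFinder-style stability values (lower = more stable).

    On sample-centred Cq z = Cq - (sample mean over candidates): for each
    candidate i and group g, d_ig is the group mean of z and s2_ig the
    within-group sample variance.  stability_i = mean_g |d_ig - mean_g d_ig|
    + mean_g sqrt(s2_ig / n_g).  The simple uncorrected variance estimator
    is used (no small-sample shrinkage).  With one group (or none given)
    the fallback stability is the SD of z over all samples, with a warning.
    """
    candidates = _check_input(cq, candidates, min_candidates=3)
    sub = cq[candidates]
    z = sub.sub(sub.mean(axis=1), axis=0)

    if groups is not None:
        groups = groups.loc[sub.index]
        labels = [g for g in pd.unique(groups.dropna())]
        labels = [g for g in labels if (groups == g).sum() >= 2]
    else:
        labels = []
    if len(labels) < 2:
        if groups is not None:
            warnings.warn(
                "fewer than 2 groups with >=2 samples; falling back to "
                "single-group residual SD",
                stacklevel=2,
            )
        stability = z.std(ddof=1)
        return pd.DataFrame(
            {"stability": stability, "bias": 0.0, "variation": stability}
        ).sort_values("stability")

    rows = []
    for c in candidates:
        d, var_term = [], []
        for g in labels:
            zv = z.loc[groups == g, c].dropna()
            d.append(zv.mean())
            var_term.append(np.sqrt(zv.var(ddof=1) / len(zv)))
        d = np.asarray(d)
        bias = float(np.mean(np.abs(d - d.mean())))
        variation = float(np.mean(var_term))
        rows.append(
            {"candidate": c, "stability": bias + variation, "bias": bias,
             "variation": variation}
        )
    return pd.DataFrame(rows).set_index("candidate").sort_values("stability")


def _combination_ranking_from_stability(
    stability: pd.Series, candidates: list[str], k: int
) -> pd.Series:
    """Rank size-k combinations by mean member stability (ascending)."""
    combos = list(iter_combinations(candidates, k))
    score = pd.Series(
        {"+".join(c): float(np.mean([stability[m] for m in c])) for c in combos}
    )
    return pd.Series(
        stats.rankdata(score.to_numpy(), method="average"), index=score.index
    )


def aggregate_and_compare(
    cq: pd.DataFrame,
    groups: pd.Series,
    candidates=None,
    k: int = 3,
    top: int = 10,
    control_label: str = "HC",
    case_label: str = "AD",
    methods=("genorm", "bestkeeper", "normfinder", "bestmirnorm"),
) -> dict:
    """Rank every size-k combination under each method and compare.

    Single-candidate methods (geNorm M, BestKeeper SD, NormFinder
    stability) score a combination by the mean of its members' values; the
    combinatorial method ranks size-k subsets natively by its weighted
    point total.  The ``aggregate`` column is the mean of the constituent
    methods' ranks (mean-rank composite).  Returns a dict with ``ranks``
    (combination x method rank matrix, 1 = best), ``top`` (per-method top
    lists), and ``spearman`` (pairwise rank correlations).
    """
    candidates = _check_input(cq, candidates, min_candidates=2)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds panel size {len(candidates)}")
    rank_cols: dict[str, pd.Series] = {}
    if "genorm" in methods:
        g = genorm(cq, candidates)
        rank_cols["genorm"] = _combination_ranking_from_stability(
            g["M"], candidates, k
        )
    if "bestkeeper" in methods:
        b = bestkeeper(cq, candidates)
        rank_cols["bestkeeper"] = _combination_ranking_from_stability(
            b["SD"], candidates, k
        )
    if "normfinder" in methods:
        nf = normfinder(cq, candidates, groups)
        rank_cols["normfinder"] = _combination_ranking_from_stability(
            nf["stability"], candidates, k
        )
    if "bestmirnorm" in methods:
        meta = pd.DataFrame({"group": groups.loc[cq.index]})
        result = run_bestmirnorm(
            cq, meta=meta, candidates=candidates,
            control_label=control_label, case_label=case_label,
        )
        size_k = result.rank_table[result.rank_table["size"] == k]
        # final_rank order restricted to size-k subsets -> dense 1..count
        order = size_k.sort_values("final_rank")["members"]
        rank_cols["bestmirnorm"] = pd.Series(
            np.arange(1, len(order) + 1, dtype=float), index=order.to_numpy()
        )
    ranks = pd.DataFrame(rank_cols)
    constituents = [m for m in ("genorm", "bestkeeper", "normfinder") if m in ranks]
    if constituents:
        ranks["aggregate"] = stats.rankdata(
            ranks[constituents].mean(axis=1), method="average"
        )
    top_lists = {
        m: ranks[m].sort_values().head(top).index.tolist() for m in ranks.columns
    }
    method_names = list(ranks.columns)
    rho = pd.DataFrame(np.eye(len(method_names)), index=method_names,
                       columns=method_names)
    for i, a in enumerate(method_names):
        for b_ in method_names[i + 1:]:
            r = float(stats.spearmanr(ranks[a], ranks[b_]).statistic)
            rho.loc[a, b_] = rho.loc[b_, a] = r
    ranks.index.name = "members"
    return {"ranks": ranks, "top": top_lists, "spearman": rho}


class GeNorm(BaseEstimator):
    """Estimator wrapper: ``fit(X)`` exposes ``stability_`` (M values),
    ``ranking_`` (most stable first) and ``exclusion_order_``."""

    def fit(self, X: pd.DataFrame, y=None) -> "GeNorm":
        table = genorm(X)
        self.stability_ = table["M"]
        self.ranking_ = list(table.index)
        self.exclusion_order_ = list(
            table.sort_values("exclusion_step").index
        )
        self.n_features_in_ = X.shape[1]
        return self


class BestKeeper(BaseEstimator):
    """Estimator wrapper: ``fit(X)`` exposes the descriptive table as
    ``stability_`` (SD) plus ``cv_``, ``r_`` and ``index_`` (per-sample)."""

    def fit(self, X: pd.DataFrame, y=None) -> "BestKeeper":
        table = bestkeeper(X)
        self.stability_ = table["SD"]
        self.cv_ = table["CV_pct"]
        self.r_ = table["r"]
        self.index_ = X.mean(axis=1)
        self.n_features_in_ = X.shape[1]
        return self


class NormFinder(BaseEstimator):
    """Estimator wrapper: ``fit(X, y)`` with y the group labels exposes
    ``stability_``, ``bias_`` and ``variation_``."""

    def fit(self, X: pd.DataFrame, y=None) -> "NormFinder":
        groups = pd.Series(np.asarray(y), index=X.index) if y is not None else None
        table = normfinder(X, groups=groups)
        self.stability_ = table["stability"]
        self.bias_ = table["bias"]
        self.variation_ = table["variation"]
        self.ranking_ = list(table.index)
        self.n_features_in_ = X.shape[1]
        return self
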