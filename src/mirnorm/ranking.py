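"""Exhaustive combinatorial selection of optimal normalizer sets.

Given a panel of n candidate reference miRNAs, every one of the 2^n - 1
non-empty subsets is used in turn as the normalizer combination: each
candidate target is normalized to -ddCq against the subset, and the subset
is scored on three stability metrics across the two biological groups
(e.g. disease vs control):

* ``ks`` — mean over targets of the two-sample Kolmogorov-Smirnov statistic
  D between the case and control value distributions (0 = identical,
  1 = disjoint);
* ``dev`` — mean over targets and groups of the absolute deviation of the
  group mean of -ddCq from zero;
* ``sd`` — mean over targets and groups of the within-group sample SD of
  -ddCq.

Lower is better on all three.  Each metric is converted to rank points
(best = n_combinations - 1, worst = 0, ties averaged), the points are
combined with user weights, and combinations are ranked by the weighted
total.  Subsets are identified by a bitmask code over the declared panel
order, so codes cover 1..2^n - 1 exactly once; a code <-> members
translation table is always emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .io import MAX_CANDIDATES, Dataset, PanelConfig
from .normalization import age_sex_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "Combination",
    "CombinationScore",
    "enumerate_combinations",
    "score_combination",
    "rank_combinations",
    "run_bestmirnorm",
    "weight_grid_scan",
    "default_weight_grid",
    "two_sample_ks_statistic",
    "BestMiRNormRanker",
]

MIN_GROUP_SIZE = 3
METRICS = ("ks", "dev", "sd")


@dataclass(frozen=True)
class Combination:
    """A non-empty subset of the candidate panel with its bitmask code."""

    members: tuple[str, ...]
    code: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CombinationScore:
    """Raw stability metrics for one combination (lower = more stable)."""

    combination: Combination
    ks_metric: float
    dev_metric: float
    sd_metric: float
    n_targets: int
    n_control: int
    n_case: int
    evaluable: bool = True
    status: str = "ok"


def enumerate_combinations(
    candidates, allow_large: bool = False
) -> list[Combination]:
    """All 2^n - 1 non-empty subsets of the panel, ordered by bitmask code.

    Code = sum of 2^i over the 0-based panel indices of the members, so the
    code <-> members map is a bijection onto 1..2^n - 1.
    """
    if isinstance(candidates, PanelConfig):
        candidates = candidates.candidate_normalizers
    candidates = list(candidates)
    n = len(candidates)
    if n == 0:
        raise ValueError("empty candidate panel")
    if len(set(candidates)) != n:
        raise ValueError("candidate panel contains duplicates")
    if n > MAX_CANDIDATES and not allow_large:
        raise ValueError(
            f"{n} candidates would enumerate {2**n - 1} combinations; "
            "pass allow_large=True to accept the cost (doubles per candidate)"
        )
    out = []
    for code in range(1, 2**n):
        members = tuple(c for i, c in enumerate(candidates) if code >> i & 1)
        out.append(Combination(members=members, code=code))
    return out


def combination_code_table(combinations: list[Combination]) -> pd.DataFrame:
    """The code <-> members translation table."""
    return pd.DataFrame(
        {
            "code": [c.code for c in combinations],
            "size": [c.size for c in combinations],
            "members": ["+".join(c.members) for c in combinations],
        }
    ).set_index("code")


def two_sample_ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic D = sup |F_x - F_y| over both samples' points."""
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.abs(cdf_x - cdf_y).max())


def _ks_value(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    if measure == "statistic":
        return two_sample_ks_statistic(x, y)
    if measure == "pvalue":
        from scipy.stats import ks_2samp

        # smaller = more stable, so the complement of the p-value is scored
        return 1.0 - float(ks_2samp(x, y, method="asymp").pvalue)
    raise ValueError(f"unknown ks_measure {measure!r}")


def _score_arrays(
    values: np.ndarray,
    member_idx: np.ndarray,
    target_idx: np.ndarray,
    control_mask: np.ndarray,
    case_mask: np.ndarray,
    reference_mode: str,
    ks_measure: str,
    min_group_size: int = MIN_GROUP_SIZE,
) -> tuple[float, float, float, int]:
    """Score one combination on a raw Cq matrix (samples x assays).

    Returns (ks, dev, sd, n_targets); n_targets == 0 marks unevaluable.
    NaN-aware: a sample enters a target's evaluation only when its target Cq
    and every member Cq are present.
    """
    ref = values[:, member_idx].mean(axis=1)  # NaN propagates per sample
    ks_sum = dev_sum = sd_sum = 0.0
    n_targets = 0
    for t in target_idx:
        dcq = values[:, t] - ref
        ok = ~np.isnan(dcq)
        ctrl = dcq[ok & control_mask]
        case = dcq[ok & case_mask]
        if ctrl.size < min_group_size or case.size < min_group_size:
            continue
        if reference_mode == "control_group_mean":
            anchor = ctrl.mean()
        else:
            anchor = np.concatenate([ctrl, case]).mean()
        v_ctrl = -(ctrl - anchor)
        v_case = -(case - anchor)
        ks_sum += _ks_value(v_ctrl, v_case, ks_measure)
        dev_sum += (abs(v_ctrl.mean()) + abs(v_case.mean())) / 2.0
        sd_sum += (v_ctrl.std(ddof=1) + v_case.std(ddof=1)) / 2.0
        n_targets += 1
    if n_targets == 0:
        return np.nan, np.nan, np.nan, 0
    return ks_sum / n_targets, dev_sum / n_targets, sd_sum / n_targets, n_targets


def score_combination(
    cq: pd.DataFrame,
    combination: Combination | tuple[str, ...],
    groups: pd.Series,
    control_label: str,
    case_label: str,
    targets=None,
    exclude_self_targets: bool = False,
    reference_mode: str = "control_group_mean",
    ks_measure: str = "statistic",
    min_group_size: int = MIN_GROUP_SIZE,
) -> CombinationScore:
    """Score one normalizer combination on the three stability metrics.

    ``targets`` defaults to every column of ``cq`` (by convention the table
    passed here holds the candidate panel only); with
    ``exclude_self_targets`` the combination's own members are dropped from
    the evaluation set.  Targets where either group has fewer than
    ``min_group_size`` complete samples are dropped with a warning; if all
    targets drop the combination is marked unevaluable (never silently
    zero).
    """
    if not isinstance(combination, Combination):
        members = tuple(combination)
        combination = Combination(members=members, code=0)
    groups = groups.loc[cq.index]
    labels = set(groups.dropna().unique())
    for lbl in (control_label, case_label):
        if lbl not in labels:
            raise ValueError(f"group label {lbl!r} not present in groups")
    target_names = list(targets) if targets is not None else list(cq.columns)
    if exclude_self_targets:
        target_names = [t for t in target_names if t not in combination.members]
    col_index = {c: i for i, c in enumerate(cq.columns)}
    values = cq.to_numpy(dtype=float)
    ks, dev, sd, n_targets = _score_arrays(
        values,
        np.array([col_index[m] for m in combination.members]),
        np.array([col_index[t] for t in target_names]),
        (groups == control_label).to_numpy(),
        (groups == case_label).to_numpy(),
        reference_mode,
        ks_measure,
        min_group_size,
    )
    if n_targets < len(target_names):
        warnings.warn(
            f"combination {combination.members}: "
            f"{len(target_names) - n_targets} target(s) dropped "
            f"(fewer than {min_group_size} complete samples in a group)",
            stacklevel=2,
        )
    return CombinationScore(
        combination=combination,
        ks_metric=ks,
        dev_metric=dev,
        sd_metric=sd,
        n_targets=n_targets,
        n_control=int((groups == control_label).sum()),
        n_case=int((groups == case_label).sum()),
        evaluable=n_targets > 0,
        status="ok" if n_targets > 0 else "unevaluable: all targets dropped",
    )


def _validate_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be (w_ks, w_dev, w_sd)")
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be nonnegative with at least one > 0")
    return w


def rank_combinations(
    scores: list[CombinationScore], weights=(1.0, 1.0, 1.0)
) -> pd.DataFrame:
    """Convert raw metrics to tie-averaged rank points and a final ranking.

    Per metric, the combination with the smallest value earns
    n_combinations - 1 points and the largest earns 0 (ties receive the
    average of their positions' points, so points always sum to
    n_c (n_c - 1) / 2).  The weighted point total decides the final rank
    (1 = best); total ties break by lower ks metric, then lower sd metric,
    then smaller code.
    """
    w = _validate_weights(weights)
    usable = [s for s in scores if s.evaluable]
    if len(usable) < 2:
        raise ValueError("need at least 2 evaluable combinations to rank")
    df = pd.DataFrame(
        {
            "code": [s.combination.code for s in usable],
            "members": ["+".join(s.combination.members) for s in usable],
            "size": [s.combination.size for s in usable],
            "ks_metric": [s.ks_metric for s in usable],
            "dev_metric": [s.dev_metric for s in usable],
            "sd_metric": [s.sd_metric for s in usable],
            "n_targets": [s.n_targets for s in usable],
        }
    )
    n_c = len(df)
    for metric, weight in zip(METRICS, w):
        col = f"{metric}_metric"
        vals = df[col].to_numpy()
        if np.unique(vals).size == 1:
            warnings.warn(f"all {col} values equal; points degenerate", stacklevel=2)
        points = n_c - rankdata(vals, method="average")
        df[f"{metric}_points"] = points
    df["total"] = (
        w[0] * df["ks_points"] + w[1] * df["dev_points"] + w[2] * df["sd_points"]
    )
    df = df.sort_values(
        by=["total", "ks_metric", "sd_metric", "code"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["final_rank"] = np.arange(1, n_c + 1)
    return df


@dataclass
class RankingResult:
    """Output bundle of a full combinatorial run."""

    rank_table: pd.DataFrame
    code_table: pd.DataFrame
    scores: list[CombinationScore]
    config: dict

    @property
    def best_combination(self) -> tuple[str, ...]:
        code = int(self.rank_table.iloc[0]["code"])
        return tuple(self.code_table.loc[code, "members"].split("+"))

    def top_k_membership(self, k: int = 10) -> pd.DataFrame:
        """Candidate x rank membership matrix for the top-k combinations."""
        top = self.rank_table.head(k)
        candidates = self.config["candidates"]
        data = {
            int(row.final_rank): {
                c: c in row.members.split("+") for c in candidates
            }
            for row in top.itertuples()
        }
        return pd.DataFrame(data, index=list(candidates))


def _prepare_run(
    dataset_or_cq,
    meta: pd.DataFrame | None,
    candidates,
    control_label: str,
    case_label: str,
    adjust_age_sex: bool,
    exclude_samples,
    allow_large: bool,
):
    if isinstance(dataset_or_cq, Dataset):
        cq = dataset_or_cq.cq
        meta = dataset_or_cq.meta if meta is None else meta
        if candidates is None:
            candidates = dataset_or_cq.panel.candidate_normalizers
    else:
        cq = dataset_or_cq
    if meta is None:
        raise ValueError("sample metadata (with a 'group' column) is required")
    candidates = list(candidates) if candidates is not None else list(cq.columns)
    absent = [c for c in candidates if c not in cq.columns]
    if absent:
        raise ValueError(f"candidate assay(s) absent from Cq table: {absent}")
    if exclude_samples is not None:
        keep = [s for s in cq.index if s not in set(exclude_samples)]
        cq = cq.loc[keep]
    meta = meta.loc[cq.index]
    if adjust_age_sex:
        cq, _ = age_sex_adjust(cq, meta)
    combos = enumerate_combinations(candidates, allow_large=allow_large)
    return cq[candidates], meta, candidates, combos


def _score_all(
    cq: pd.DataFrame,
    meta: pd.DataFrame,
    candidates: list[str],
    combos: list[Combination],
    control_label: str,
    case_label: str,
    exclude_self_targets: bool,
    reference_mode: str,
    ks_measure: str,
) -> list[CombinationScore]:
    groups = meta["group"]
    control_mask = (groups == control_label).to_numpy()
    case_mask = (groups == case_label).to_numpy()
    if control_mask.sum() == 0 or case_mask.sum() == 0:
        raise ValueError(
            f"both group labels {control_label!r} and {case_label!r} must be present"
        )
    values = cq.to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(cq.columns)}
    cand_idx = np.array([col_index[c] for c in candidates])
    scores = []
    for combo in combos:
        member_idx = np.array([col_index[m] for m in combo.members])
        if exclude_self_targets:
            target_idx = np.array(
                [col_index[c] for c in candidates if c not in combo.members],
                dtype=int,
            )
        else:
            target_idx = cand_idx
        if target_idx.size == 0:
            scores.append(
                CombinationScore(
                    combo, np.nan, np.nan, np.nan, 0,
                    int(control_mask.sum()), int(case_mask.sum()),
                    evaluable=False, status="unevaluable: no targets",
                )
            )
            continue
        ks, dev, sd, n_t = _score_arrays(
            values, member_idx, target_idx, control_mask, case_mask,
            reference_mode, ks_measure,
        )
        scores.append(
            CombinationScore(
                combo, ks, dev, sd, n_t,
                int(control_mask.sum()), int(case_mask.sum()),
                evaluable=n_t > 0,
                status="ok" if n_t > 0 else "unevaluable: all targets dropped",
            )
        )
    return scores


def run_bestmirnorm(
    dataset_or_cq,
    meta: pd.DataFrame | None = None,
    candidates=None,
    control_label: str = "HC",
    case_label: str = "AD",
    weights=(1.0, 1.0, 1.0),
    exclude_self_targets: bool = False,
    reference_mode: str = "control_group_mean",
    ks_measure: str = "statistic",
    adjust_age_sex: bool = False,
    exclude_samples=None,
    allow_large: bool = False,
) -> RankingResult:
    """End-to-end combinatorial ranking: enumerate, score, rank.

    Accepts either an assembled :class:`~mirnorm.io.Dataset` or a Cq
    DataFrame plus a metadata table carrying a ``group`` column.  QC-flagged
    samples are removed via ``exclude_samples``.
    """
    cq, meta, candidates, combos = _prepare_run(
        dataset_or_cq, meta, candidates, control_label, case_label,
        adjust_age_sex, exclude_samples, allow_large,
    )
    scores = _score_all(
        cq, meta, candidates, combos, control_label, case_label,
        exclude_self_targets, reference_mode, ks_measure,
    )
    rank_table = rank_combinations(scores, weights)
    config = {
        "candidates": tuple(candidates),
        "control_label": control_label,
        "case_label": case_label,
        "weights": tuple(float(x) for x in np.asarray(weights, float)),
        "exclude_self_targets": exclude_self_targets,
        "reference_mode": reference_mode,
        "ks_measure": ks_measure,
        "adjust_age_sex": adjust_age_sex,
        "n_combinations": len(combos),
    }
    return RankingResult(
        rank_table=rank_table,
        code_table=combination_code_table(combos),
        scores=scores,
        config=config,
    )


def default_weight_grid() -> list[tuple[int, int, int]]:
    """{1,2,3}^3 minus the uniform non-unit scalings (2,2,2) and (3,3,3).

    Uniform scalings of (1,1,1) are redundant by scale invariance of the
    final ranking, leaving 25 distinct weightings.
    """
    return [
        w for w in product((1, 2, 3), repeat=3) if w not in ((2, 2, 2), (3, 3, 3))
    ]


def weight_grid_scan(
    dataset_or_cq,
    meta: pd.DataFrame | None = None,
    grid=None,
    top_k: int = 10,
    **run_kwargs,
) -> tuple[pd.DataFrame, pd.Series]:
    """Final top-k codes under each weighting of a grid.

    Scores are computed once; only the rank aggregation is repeated per
    weighting.  Returns (per-weighting top-k table, stability summary
    counting how often each code appears in the top-k across weightings).
    """
    grid = list(grid) if grid is not None else default_weight_grid()
    if not grid:
        raise ValueError("empty weight grid")
    candidates = run_kwargs.pop("candidates", None)
    cq, meta, candidates, combos = _prepare_run(
        dataset_or_cq, meta, candidates,
        run_kwargs.get("control_label", "HC"),
        run_kwargs.get("case_label", "AD"),
        run_kwargs.pop("adjust_age_sex", False),
        run_kwargs.pop("exclude_samples", None),
        run_kwargs.pop("allow_large", False),
    )
    scores = _score_all(
        cq, meta, candidates, combos,
        run_kwargs.pop("control_label", "HC"),
        run_kwargs.pop("case_label", "AD"),
        run_kwargs.pop("exclude_self_targets", False),
        run_kwargs.pop("reference_mode", "control_group_mean"),
        run_kwargs.pop("ks_measure", "statistic"),
    )
    rows = []
    counts: dict[int, int] = {}
    for w in grid:
        table = rank_combinations(scores, w)
        top_codes = table.head(top_k)["code"].astype(int).tolist()
        rows.append(
            {"w_ks": w[0], "w_dev": w[1], "w_sd": w[2],
             "top_codes": top_codes, "best_code": top_codes[0]}
        )
        for c in top_codes:
            counts[c] = counts.get(c, 0) + 1
    summary = pd.Series(counts, name="top_k_appearances").sort_values(
        ascending=False
    )
    summary.index.name = "code"
    return pd.DataFrame(rows), summary


class BestMiRNormRanker(BaseEstimator):
    """Scikit-learn-style estimator for combinatorial normalizer selection.

    ``fit(X, y)`` takes a Cq DataFrame (samples x candidate assays) and
    per-sample group labels; fitted attributes expose the full rank table,
    the code translation table and the winning combination.

    Parameters
    ----------
    candidates : sequence of str or None
        Candidate panel; default all columns of X (at most 11 unless
        ``allow_large``).
    control_label, case_label : str
        The two biological groups compared by every metric.
    weights : (w_ks, w_dev, w_sd)
        Nonnegative rank-point multipliers; uniform scaling does not change
        the final order.
    exclude_self_targets : bool
        Drop a combination's own members from its evaluation targets.
    reference_mode : {"control_group_mean", "grand_mean"}
    ks_measure : {"statistic", "pvalue"}
    """

    def __init__(
        self,
        candidates=None,
        control_label: str = "HC",
        case_label: str = "AD",
        weights=(1.0, 1.0, 1.0),
        exclude_self_targets: bool = False,
        reference_mode: str = "control_group_mean",
        ks_measure: str = "statistic",
        allow_large: bool = False,
    ):
        self.candidates = candidates
        self.control_label = control_label
        self.case_label = case_label
        self.weights = weights
        self.exclude_self_targets = exclude_self_targets
        self.reference_mode = reference_mode
        self.ks_measure = ks_measure
        self.allow_large = allow_large

    def fit(self, X: pd.DataFrame, y) -> "BestMiRNormRanker":
        meta = pd.DataFrame({"group": np.asarray(y)}, index=X.index)
        result = run_bestmirnorm(
            X,
            meta=meta,
            candidates=self.candidates,
            control_label=self.control_label,
            case_label=self.case_label,
            weights=self.weights,
            exclude_self_targets=self.exclude_self_targets,
            reference_mode=self.reference_mode,
            ks_measure=self.ks_measure,
            allow_large=self.allow_large,
        )
        self.result_ = result
        self.rank_table_ = result.rank_table
        self.code_table_ = result.code_table
        self.best_combination_ = result.best_combination
        self.n_combinations_ = result.config["n_combinations"]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Cq of the winning combination's members (feature-selection view)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "best_combination_")
        return X[list(self.best_combination_)]
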