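"""Covariate adjustment and the -ddCq relative-quantification engine.

Everything downstream — the combinatorial ranking and the baseline stability
algorithms — consumes the quantities produced here.

Notation.  For a sample s, target assay t and a combination C of reference
assays:

    dCq_s  = Cq(t, s) - mean_{r in C} Cq(r, s)
    ddCq_s = dCq_s - m
    value  = -ddCq_s  (identically log2(2^-ddCq), i.e. log2 relative
             expression under perfect per-cycle doubling)

where m is the mean dCq over control-group samples (``control_group_mean``,
the classical ddCq reference) or over all samples (``grand_mean``).  The
arithmetic mean of member Cq values equals the log2 of the geometric mean of
the members' relative quantities, which is why a multi-assay reference is
averaged on the Cq scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AdjustmentModel",
    "age_sex_adjust",
    "reference_mean",
    "neg_ddcq",
    "AgeSexAdjuster",
    "NegDDCqNormalizer",
]

MIN_STRATUM_SIZE = 3


@dataclass
class AdjustmentModel:
    """Fitted age-on-Cq regressions, one per (sex stratum, assay).

    ``coefficients`` is indexed by (stratum, assay) with columns
    ``intercept``, ``slope``, ``stratum_mean``, ``n``.
    """

    coefficients: pd.DataFrame


def age_sex_adjust(
    cq: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, AdjustmentModel]:
    """Remove linear age trends within sex strata, preserving the Cq scale.

    Within each sex stratum and assay a least-squares line Cq ~ age is
    fitted; the adjusted value is the residual recentred on the stratum
    assay mean, so location and spread per stratum are preserved and Cq
    thresholds stay meaningful.  Strata with fewer than 3 samples, or with
    constant age, are passed through unadjusted with a warning.
    """
    for col in ("age", "sex"):
        if col not in meta.columns:
            raise ValueError(f"metadata column {col!r} required for adjustment")
    meta = meta.loc[cq.index]
    if meta[["age", "sex"]].isna().any().any():
        raise ValueError("age and sex must be available for every sample")

    adjusted = cq.copy()
    records = []
    for stratum, idx in meta.groupby("sex", sort=False).groups.items():
        idx = pd.Index(idx)
        age = meta.loc[idx, "age"].to_numpy(float)
        if len(idx) < MIN_STRATUM_SIZE:
            warnings.warn(
                f"sex stratum {stratum!r} has {len(idx)} sample(s); passed "
                "through unadjusted",
                stacklevel=2,
            )
            continue
        constant_age = np.ptp(age) == 0
        if constant_age:
            warnings.warn(
                f"constant age in sex stratum {stratum!r}; adjustment is a no-op",
                stacklevel=2,
            )
        age_c = age - age.mean()
        denom = float(age_c @ age_c)
        for assay in cq.columns:
            y = cq.loc[idx, assay].to_numpy(float)
            present = ~np.isnan(y)
            n = int(present.sum())
            if n < MIN_STRATUM_SIZE or constant_age:
                slope = 0.0
                mean_y = float(np.nanmean(y)) if n else np.nan
                intercept = mean_y
            else:
                ac = age[present] - age[present].mean()
                d = float(ac @ ac)
                slope = float(ac @ y[present] / d) if d > 0 else 0.0
                mean_y = float(y[present].mean())
                intercept = mean_y - slope * age[present].mean()
                adjusted.loc[idx[present], assay] = (
                    y[present] - (intercept + slope * age[present]) + mean_y
                )
            records.append(
                {
                    "stratum": stratum,
                    "assay": assay,
                    "intercept": intercept,
                    "slope": slope,
                    "stratum_mean": mean_y,
                    "n": n,
                }
            )
    model = AdjustmentModel(
        coefficients=pd.DataFrame(records).set_index(["stratum", "assay"])
        if records
        else pd.DataFrame(
            columns=["intercept", "slope", "stratum_mean", "n"]
        )
    )
    return adjusted, model


def reference_mean(cq: pd.DataFrame, combination) -> pd.Series:
    """Per-sample reference Cq: arithmetic mean of the member assays.

    A sample missing any member's Cq gets a missing reference (it is
    excluded pairwise downstream, never imputed).
    """
    members = list(combination)
    if not members:
        raise ValueError("empty combination")
    absent = [m for m in members if m not in cq.columns]
    if absent:
        raise ValueError(f"combination assay(s) absent from Cq table: {absent}")
    sub = cq[members]
    ref = sub.mean(axis=1)
    ref[sub.isna().any(axis=1)] = np.nan
    return ref


def neg_ddcq(
    cq: pd.DataFrame,
    target: str,
    combination,
    groups: pd.Series,
    control_label: str,
    reference_mode: str = "control_group_mean",
) -> pd.Series:
    """-ddCq (log2 relative expression) of ``target`` against a combination.

    Samples missing the target or any combination member are returned as
    NaN.  Under ``control_group_mean`` the control-group mean of the result
    is exactly 0 by construction; under ``grand_mean`` the all-sample mean
    is.  A target that is the sole member of its own combination yields
    exactly 0 everywhere (legal degenerate case).
    """
    if target not in cq.columns:
        raise ValueError(f"target assay {target!r} absent from Cq table")
    if reference_mode not in ("control_group_mean", "grand_mean"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    ref = reference_mean(cq, combination)
    dcq = cq[target] - ref
    groups = groups.loc[cq.index]
    if reference_mode == "control_group_mean":
        control = dcq[groups == control_label].dropna()
        if control.empty:
            raise ValueError(
                f"no complete control ({control_label!r}) samples for target "
                f"{target!r}"
            )
        m = control.mean()
    else:
        complete = dcq.dropna()
        if complete.empty:
            raise ValueError(f"no complete samples for target {target!r}")
        m = complete.mean()
    values = -(dcq - m)
    values.name = target
    return values


class AgeSexAdjuster(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`age_sex_adjust`.

    Because the adjustment is defined within the cohort being analysed (each
    stratum is recentred on its own mean), ``fit_transform(X, meta=meta)``
    is the intended entry point; ``transform`` re-applies the fitted lines
    to new data with the same sex labels.
    """

    def fit(self, X: pd.DataFrame, y=None, *, meta: pd.DataFrame) -> "AgeSexAdjuster":
        adjusted, model = age_sex_adjust(X, meta)
        self.model_ = model
        self.adjusted_ = adjusted
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).adjusted_

    def transform(self, X: pd.DataFrame, meta: pd.DataFrame | None = None):
        if meta is None:
            raise ValueError("transform requires the metadata table")
        coef = self.model_.coefficients
        out = X.copy()
        for (stratum, assay), row in coef.iterrows():
            if assay not in X.columns:
                continue
            idx = meta.index[meta["sex"] == stratum].intersection(X.index)
            fitted = row["intercept"] + row["slope"] * meta.loc[idx, "age"]
            out.loc[idx, assay] = X.loc[idx, assay] - fitted + row["stratum_mean"]
        return out


class NegDDCqNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer computing -ddCq for every target assay.

    Parameters
    ----------
    combination : sequence of str
        Reference assays averaged into the per-sample reference Cq.
    control_label : str
        Group label whose mean dCq anchors the ddCq (ignored under
        ``grand_mean``).
    reference_mode : {"control_group_mean", "grand_mean"}
    targets : sequence of str or None
        Assays to normalize; default every non-member column.

    ``fit(X, y)`` with y the per-sample group labels learns the per-target
    anchor means; ``transform`` maps Cq to log2 relative expression.
    """

    def __init__(
        self,
        combination=(),
        control_label: str = "HC",
        reference_mode: str = "control_group_mean",
        targets=None,
    ):
        self.combination = combination
        self.control_label = control_label
        self.reference_mode = reference_mode
        self.targets = targets

    def fit(self, X: pd.DataFrame, y=None) -> "NegDDCqNormalizer":
        members = list(self.combination)
        if not members:
            raise ValueError("combination must be non-empty")
        targets = (
            list(self.targets)
            if self.targets is not None
            else [c for c in X.columns if c not in members]
        )
        ref = reference_mean(X, members)
        groups = pd.Series(np.asarray(y), index=X.index) if y is not None else None
        anchors = {}
        for t in targets:
            dcq = X[t] - ref
            if self.reference_mode == "control_group_mean":
                if groups is None:
                    raise ValueError("control_group_mean mode requires y (group labels)")
                sel = dcq[groups == self.control_label].dropna()
                if sel.empty:
                    raise ValueError(
                        f"no complete control samples for target {t!r}"
                    )
                anchors[t] = sel.mean()
            elif self.reference_mode == "grand_mean":
                anchors[t] = dcq.dropna().mean()
            else:
                raise ValueError(f"unknown reference_mode {self.reference_mode!r}")
        self.targets_ = targets
        self.anchor_ = pd.Series(anchors)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        ref = reference_mean(X, list(self.combination))
        out = {}
        for t in self.targets_:
            out[t] = -(X[t] - ref - self.anchor_[t])
        return pd.DataFrame(out, index=X.index)
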