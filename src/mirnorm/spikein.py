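"""Exogenous spike-in control evaluation.

Synthetic C. elegans miRNAs are added at a fixed amount before RNA isolation
(cel-miR-39-3p, cel-miR-2-3p) and before reverse transcription
(cel-miR-238-3p, cel-miR-54-3p); their Cq should therefore be constant across
samples up to technical noise.  This module computes per-sample z-scores of
each spike-in within a stratum (default: cohort), flags samples whose
recovery deviates on ANY spike-in of a stage, and optionally corrects target
Cq values by the sample's mean spike-in deviation from the batch median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpikeInConfig",
    "spikein_zscores",
    "spikein_correction",
    "SpikeInCorrector",
]

MIN_STRATUM_SIZE = 3


@dataclass(frozen=True)
class SpikeInConfig:
    isolation_assays: tuple[str, ...] = ("cel-miR-39-3p", "cel-miR-2-3p")
    rt_assays: tuple[str, ...] = ("cel-miR-238-3p", "cel-miR-54-3p")
    z_flag_threshold: float = 2.0
    grouping: str | None = "cohort"  # metadata column used as stratum

    def __post_init__(self) -> None:
        if not self.z_flag_threshold > 0:
            raise ValueError("z_flag_threshold must be > 0")
        if not self.isolation_assays and not self.rt_assays:
            raise ValueError("at least one spike-in assay must be configured")

    @property
    def all_assays(self) -> tuple[str, ...]:
        return tuple(self.isolation_assays) + tuple(self.rt_assays)


def _strata(cq: pd.DataFrame, meta: pd.DataFrame | None, config: SpikeInConfig):
    """Yield (label, sample index) pairs for z-score stratification."""
    if config.grouping is None or meta is None or config.grouping not in getattr(
        meta, "columns", ()
    ):
        yield "all", cq.index
        return
    for label, grp in meta.loc[cq.index].groupby(config.grouping, sort=False):
        yield str(label), grp.index


def spikein_zscores(
    cq: pd.DataFrame,
    config: SpikeInConfig | None = None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample spike-in z-scores and stage outlier flags.

    z = (Cq - stratum mean) / stratum sample SD, per spike-in assay within
    each stratum.  A stage flag (``isolation_outlier`` / ``rt_outlier``) is
    set when |z| exceeds the threshold for ANY spike-in of that stage.
    Strata with fewer than 3 samples, or with zero SD, yield undefined
    z-scores (NaN) with a reason; such samples are never flagged.

    Returns a DataFrame indexed by sample with one ``z_<assay>`` column per
    spike-in, the two stage flags, per-stage mean deviation from the stratum
    mean (Cq units), and a ``reason`` column for unevaluable samples.
    """
    config = config or SpikeInConfig()
    absent = [a for a in config.all_assays if a not in cq.columns]
    if absent:
        raise ValueError(f"spike-in assay(s) absent from Cq table: {absent}")

    z = pd.DataFrame(np.nan, index=cq.index, columns=list(config.all_assays))
    dev = pd.DataFrame(np.nan, index=cq.index, columns=list(config.all_assays))
    reason = pd.Series("", index=cq.index, dtype=object)
    for label, idx in _strata(cq, meta, config):
        if len(idx) < MIN_STRATUM_SIZE:
            reason.loc[idx] = f"stratum {label!r} has <{MIN_STRATUM_SIZE} samples"
            continue
        for assay in config.all_assays:
            vals = cq.loc[idx, assay]
            sd = vals.std(ddof=1)
            dev.loc[idx, assay] = vals - vals.mean()
            if not sd > 0:
                reason.loc[idx] = f"zero SD for {assay!r} in stratum {label!r}"
                continue
            z.loc[idx, assay] = (vals - vals.mean()) / sd

    def stage_flag(assays: tuple[str, ...]) -> pd.Series:
        if not assays:
            return pd.Series(False, index=cq.index)
        return (z[list(assays)].abs() > config.z_flag_threshold).any(axis=1)

    report = z.add_prefix("z_")
    report["isolation_outlier"] = stage_flag(config.isolation_assays)
    report["rt_outlier"] = stage_flag(config.rt_assays)
    if config.isolation_assays:
        report["isolation_mean_dev"] = dev[list(config.isolation_assays)].mean(axis=1)
    if config.rt_assays:
        report["rt_mean_dev"] = dev[list(config.rt_assays)].mean(axis=1)
    report["reason"] = reason
    return report


def spikein_correction(
    cq: pd.DataFrame,
    config: SpikeInConfig | None = None,
    mode: str = "none",
    keep_spikeins: bool = True,
) -> pd.DataFrame:
    """Optionally remove per-sample technical offsets estimated from spike-ins.

    ``mode="none"`` returns the input unchanged (the default: the correction
    rule is a documented convention, not a published formula).  With
    ``mode="subtract_stage_deviation"`` each sample's deviation d_s = mean
    over configured spike-ins of (Cq(spike, s) - median over samples of
    Cq(spike)) is subtracted from every non-spike-in assay.  The batch
    reference is the median, robust to the very outliers the controls exist
    to find.  Samples missing any spike-in Cq are left uncorrected with a
    warning.
    """
    if mode == "none":
        return cq.copy()
    if mode != "subtract_stage_deviation":
        raise ValueError(f"unknown correction mode {mode!r}")
    config = config or SpikeInConfig()
    spikes = list(config.all_assays)
    absent = [a for a in spikes if a not in cq.columns]
    if absent:
        raise ValueError(f"spike-in assay(s) absent from Cq table: {absent}")

    deviation = (cq[spikes] - cq[spikes].median(axis=0)).mean(axis=1)
    incomplete = cq[spikes].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} sample(s) missing spike-in Cq left "
            "uncorrected",
            stacklevel=2,
        )
        deviation[incomplete] = 0.0
    targets = [c for c in cq.columns if c not in spikes]
    out = cq.copy()
    out[targets] = cq[targets].sub(deviation, axis=0)
    if not keep_spikeins:
        out = out[targets]
    return out


class SpikeInCorrector(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`spikein_correction`.

    ``fit`` learns the per-sample deviations on the training table's own
    rows; because the correction is per-sample relative to the batch median,
    ``transform`` recomputes deviations on the table it is given (each batch
    is its own reference).
    """

    def __init__(
        self,
        mode: str = "none",
        isolation_assays: tuple[str, ...] = ("cel-miR-39-3p", "cel-miR-2-3p"),
        rt_assays: tuple[str, ...] = ("cel-miR-238-3p", "cel-miR-54-3p"),
        keep_spikeins: bool = True,
    ):
        self.mode = mode
        self.isolation_assays = isolation_assays
        self.rt_assays = rt_assays
        self.keep_spikeins = keep_spikeins

    def _config(self) -> SpikeInConfig:
        return SpikeInConfig(
            isolation_assays=tuple(self.isolation_assays),
            rt_assays=tuple(self.rt_assays),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "SpikeInCorrector":
        if self.mode != "none":
            spikein_correction(X, self._config(), mode=self.mode)  # validates
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return spikein_correction(
            X, self._config(), mode=self.mode, keep_spikeins=self.keep_spikeins
        )
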