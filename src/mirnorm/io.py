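"""Input/output and data model for Cq tables, sample metadata and assay panels.

The in-memory representation of a Cq table is a :class:`pandas.DataFrame`
indexed by sample id with one column per miRNA assay; missing quantification
cycles (e.g. ``Undetermined`` wells) are ``NaN``.  Validation lives here so
every downstream module can assume a well-formed table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Cell contents treated as "no Cq measured" by default.
DEFAULT_MISSING_TOKENS = ("Undetermined", "undetermined", "NA", "N/A", "NaN", "")

#: Plausibility gate for quantification cycles.  Values outside are almost
#: always unit or export errors; the permissive flag disables the gate.
CQ_MIN, CQ_MAX = 0.0, 45.0

REQUIRED_META_COLUMNS = ("sample_id", "group", "sex", "age")

#: Hard ceiling on candidate panel size (override flag relaxes it): the
#: exhaustive 2^n - 1 enumeration is designed for up to 11 candidates.
MAX_CANDIDATES = 11


class CqTableError(ValueError):
    """Raised when a Cq table or its source file violates an invariant."""


@dataclass(frozen=True)
class PanelConfig:
    """Declares the assay panel: candidate normalizers, spike-ins, markers.

    Parameters
    ----------
    candidate_normalizers : list of str
        Endogenous miRNAs evaluated as reference candidates (at most 11
        unless ``allow_large_panel``).
    spikein_isolation, spikein_rt : list of str
        Exogenous controls added before RNA isolation and before reverse
        transcription, respectively.
    haemolysis_plasma_marker, haemolysis_rbc_marker : str
        The plasma-enriched / red-blood-cell-enriched miRNA pair used by the
        dCq haemolysis rule.
    """

    candidate_normalizers: tuple[str, ...]
    spikein_isolation: tuple[str, ...] = ("cel-miR-39-3p", "cel-miR-2-3p")
    spikein_rt: tuple[str, ...] = ("cel-miR-238-3p", "cel-miR-54-3p")
    haemolysis_plasma_marker: str = "hsa-miR-23a-3p"
    haemolysis_rbc_marker: str = "hsa-miR-451a"
    allow_large_panel: bool = False

    def __post_init__(self) -> None:
        cands = tuple(self.candidate_normalizers)
        object.__setattr__(self, "candidate_normalizers", cands)
        object.__setattr__(self, "spikein_isolation", tuple(self.spikein_isolation))
        object.__setattr__(self, "spikein_rt", tuple(self.spikein_rt))
        if not cands:
            raise ValueError("candidate_normalizers must be non-empty")
        if len(set(cands)) != len(cands):
            raise ValueError("candidate_normalizers contains duplicates")
        if len(cands) > MAX_CANDIDATES and not self.allow_large_panel:
            raise ValueError(
                f"panel has {len(cands)} candidates; the exhaustive enumeration "
                f"is designed for at most {MAX_CANDIDATES} "
                "(set allow_large_panel=True to override; cost doubles per candidate)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        """Load a panel config from a ``key: [list]`` YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"panel config {path} must be a mapping")
        kwargs = {}
        for key in (
            "candidate_normalizers",
            "spikein_isolation",
            "spikein_rt",
            "haemolysis_plasma_marker",
            "haemolysis_rbc_marker",
            "allow_large_panel",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class Dataset:
    """An analysis-ready bundle: validated Cq table + metadata + panel."""

    cq: pd.DataFrame
    meta: pd.DataFrame
    panel: PanelConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.cq.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.cq.equals(other.cq)
            and self.meta.equals(other.meta)
            and self.panel == other.panel
        )


def validate_cq_table(cq: pd.DataFrame, permissive: bool = False) -> pd.DataFrame:
    """Check CqTable invariants; returns the (float-typed) table.

    Rejects duplicate sample/assay ids, non-finite present values and values
    outside the [0, 45] plausibility window unless ``permissive``.
    """
    if cq.shape[0] == 0 or cq.shape[1] == 0:
        raise CqTableError("empty Cq table")
    if cq.index.has_duplicates:
        dupes = cq.index[cq.index.duplicated()].unique().tolist()
        raise CqTableError(f"duplicate sample ids: {dupes}")
    if cq.columns.has_duplicates:
        dupes = cq.columns[cq.columns.duplicated()].unique().tolist()
        raise CqTableError(f"duplicate assay ids: {dupes}")
    out = cq.astype(float)
    values = out.to_numpy()
    present = ~np.isnan(values)
    if np.isinf(values[present]).any():
        raise CqTableError("Cq table contains non-finite values")
    if not permissive:
        bad = present & ((values < CQ_MIN) | (values > CQ_MAX))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CqTableError(
                f"Cq value {values[r, c]} for sample {out.index[r]!r}, assay "
                f"{out.columns[c]!r} outside [{CQ_MIN:g}, {CQ_MAX:g}] "
                "(pass permissive=True to accept)"
            )
    return out


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    """Read comma- or tab-delimited text; anything else needs an explicit flag."""
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def load_cq_table(
    path: str | Path,
    layout: str = "wide",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    aggregate_replicates: bool = False,
    permissive: bool = False,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Load a Cq table from delimited text.

    Parameters
    ----------
    layout : {"wide", "long"}
        ``wide``: header ``sample_id,<assay1>,<assay2>,...``, one row per
        sample.  ``long``: columns ``sample_id,assay_id,cq``.
    missing_tokens : tuple of str
        Cell contents mapped to missing (never imputed).
    aggregate_replicates : bool
        In long layout, average duplicate (sample, assay) wells instead of
        raising.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    raw = _read_delimited(path, delimiter)
    if raw.shape[0] == 0:
        raise CqTableError(f"{path}: empty table")
    tokens = set(missing_tokens)

    def parse_cell(text: str, where: str) -> float:
        text = text.strip()
        if text in tokens:
            return np.nan
        try:
            return float(text)
        except ValueError:
            raise CqTableError(f"{path}: unparseable Cq {text!r} at {where}") from None

    if layout == "wide":
        if raw.shape[1] < 2:
            raise CqTableError(f"{path}: wide layout needs sample_id + >=1 assay column")
        sample_col = raw.columns[0]
        cq = raw.set_index(sample_col)
        cq.index.name = "sample_id"
        parsed = {
            assay: [
                parse_cell(v, f"sample {s!r}, assay {assay!r}")
                for s, v in zip(cq.index, cq[assay])
            ]
            for assay in cq.columns
        }
        out = pd.DataFrame(parsed, index=cq.index)
    else:
        needed = {"sample_id", "assay_id", "cq"}
        if not needed.issubset(raw.columns):
            raise CqTableError(
                f"{path}: long layout requires columns {sorted(needed)}, "
                f"found {list(raw.columns)}"
            )
        raw = raw.copy()
        raw["_cq"] = [
            parse_cell(v, f"sample {s!r}, assay {a!r}")
            for s, a, v in zip(raw["sample_id"], raw["assay_id"], raw["cq"])
        ]
        dup = raw.duplicated(subset=["sample_id", "assay_id"], keep=False)
        if dup.any() and not aggregate_replicates:
            pair = raw.loc[dup, ["sample_id", "assay_id"]].iloc[0]
            raise CqTableError(
                f"{path}: duplicate entry for sample {pair['sample_id']!r}, assay "
                f"{pair['assay_id']!r} (pass aggregate_replicates=True to average)"
            )
        out = (
            raw.groupby(["sample_id", "assay_id"], sort=False)["_cq"]
            .mean()
            .unstack("assay_id")
        )
        # preserve first-appearance order of both axes
        out = out.reindex(
            index=raw["sample_id"].drop_duplicates(),
            columns=raw["assay_id"].drop_duplicates(),
        )
        out.index.name = "sample_id"
        out.columns.name = None
    return validate_cq_table(out, permissive=permissive)


def write_cq_table(cq: pd.DataFrame, path: str | Path, layout: str = "wide") -> None:
    """Write a Cq table to CSV in wide or long layout (round-trip safe)."""
    if layout == "wide":
        out = cq.copy()
        out.index.name = "sample_id"
        out.to_csv(path, float_format="%.17g")
    elif layout == "long":
        long = cq.stack(future_stack=True).reset_index()
        long.columns = ["sample_id", "assay_id", "cq"]
        long = long.dropna(subset=["cq"])
        long.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def load_metadata(
    path: str | Path,
    required: tuple[str, ...] = REQUIRED_META_COLUMNS,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Load a sample metadata table: ``sample_id,group,sex,age[,batch,cohort]``.

    Extra columns are preserved untouched.  Returns a DataFrame indexed by
    sample_id with ``age`` as float.
    """
    raw = _read_delimited(path, delimiter)
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s): {missing}")
    if raw["sample_id"].duplicated().any():
        dupes = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicated sample_id(s): {dupes}")
    meta = raw.set_index("sample_id")
    if "age" in meta.columns:
        try:
            meta["age"] = meta["age"].astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric age value ({exc})") from None
        if (meta["age"] < 0).any():
            raise ValueError(f"{path}: negative age")
    return meta


def assemble_dataset(
    cq: pd.DataFrame,
    meta: pd.DataFrame,
    panel: PanelConfig,
    mode: str = "strict",
) -> Dataset:
    """Join a Cq table with metadata under a panel declaration.

    ``strict`` mode requires the sample sets to match exactly; ``lenient``
    takes the intersection with a warning.  Every assay the panel references
    must exist in the table.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    cq = validate_cq_table(cq, permissive=True)
    referenced = (
        list(panel.candidate_normalizers)
        + list(panel.spikein_isolation)
        + list(panel.spikein_rt)
        + [panel.haemolysis_plasma_marker, panel.haemolysis_rbc_marker]
    )
    absent = [a for a in referenced if a not in cq.columns]
    if absent:
        raise ValueError(f"panel assay(s) absent from Cq table: {absent}")

    cq_ids, meta_ids = set(cq.index), set(meta.index)
    if cq_ids != meta_ids:
        unmatched = sorted(cq_ids.symmetric_difference(meta_ids))
        if mode == "strict":
            raise ValueError(
                f"sample sets differ between Cq table and metadata: {unmatched}"
            )
        shared = [s for s in cq.index if s in meta_ids]
        warnings.warn(
            f"lenient assembly dropped {len(unmatched)} unmatched sample(s); "
            f"keeping {len(shared)}",
            stacklevel=2,
        )
        cq = cq.loc[shared]
        meta = meta.loc[shared]
    else:
        meta = meta.loc[cq.index]
    logger.info("assembled dataset: %d samples, %d assays", *cq.shape)
    return Dataset(cq=cq, meta=meta, panel=panel)
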