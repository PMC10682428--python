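"""Seeded synthetic cohorts: Cq tables, metadata and absorbance spectra.

The generator emulates the structure the analyses assume: a two-group
ageing cohort (controls vs cases), a small panel of candidate normalizers
with per-candidate baseline Cq, optional case-group shifts and within-group
noise, linear age trends within sex strata, exogenous spike-ins with planted
recovery outliers, and haemolysed samples whose contamination level both
lowers the red-blood-cell marker's Cq and raises the oxyhaemoglobin
absorbance band at 414 nm.  Ground truth is shipped in the metadata as
``gt_*`` columns so tests never have to re-derive it.

Cq noise is Gaussian: Cq lives on a log2 scale, where multiplicative
expression noise is approximately additive.  Spectral bands are Gaussians
rather than measured haemoglobin extinction curves — adequate for
structural tests, deliberately non-physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Dataset, PanelConfig

__all__ = [
    "CandidateSpec",
    "SpikeInSpec",
    "HaemolysisSpec",
    "SimSpec",
    "default_candidates",
    "planted_spec",
    "simulate_cq_dataset",
    "simulate_spectra",
]


@dataclass(frozen=True)
class CandidateSpec:
    """One simulated assay: baseline Cq, case-group shift, within-group SD."""

    baseline_cq: float
    group_shift: float = 0.0
    sd: float = 0.2
    age_slope: float = 0.0  # Cq per year, applied around the mean age
    sex_effect: float = 0.0  # Cq added for female samples

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("candidate sd must be >= 0")


@dataclass(frozen=True)
class SpikeInSpec:
    """Per-stage exogenous controls: names, shared baseline/SD, outliers."""

    isolation_assays: tuple[str, ...] = ("cel-miR-39-3p", "cel-miR-2-3p")
    rt_assays: tuple[str, ...] = ("cel-miR-238-3p", "cel-miR-54-3p")
    baseline_cq: float = 23.0
    sd: float = 0.3
    outlier_fraction: float = 0.05
    outlier_shift: float = 3.0  # Cq added to every spike-in of an outlier sample

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.sd < 0:
            raise ValueError("spike-in sd must be >= 0")


@dataclass(frozen=True)
class HaemolysisSpec:
    """Contamination mechanism shared by the Cq and spectrum generators."""

    fraction: float = 0.2
    level_range: tuple[float, float] = (0.5, 2.0)
    rbc_marker: str = "hsa-miR-451a"
    plasma_marker: str = "hsa-miR-23a-3p"
    rbc_baseline_cq: float = 21.0
    rbc_sd: float = 0.3
    rbc_cq_per_level: float = 2.0  # Cq decrease of the RBC marker per unit level
    band_height_per_level: float = 0.3  # OD at 414 nm per unit level

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("haemolysis fraction must be in [0, 1]")


def default_candidates() -> dict[str, CandidateSpec]:
    """The 7-candidate endogenous panel with realistic plasma baselines."""
    return {
        "hsa-miR-93-5p": CandidateSpec(24.0),
        "hsa-miR-192-5p": CandidateSpec(27.0),
        "hsa-miR-24-3p": CandidateSpec(25.0),
        "hsa-miR-126-3p": CandidateSpec(26.0),
        "hsa-miR-16-5p": CandidateSpec(21.0),
        "hsa-miR-484": CandidateSpec(26.5),
        "hsa-miR-23a-3p": CandidateSpec(26.0),
    }


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic cohort (deterministic under seed)."""

    n_per_group: int = 40
    groups: tuple[str, str] = ("HC", "AD")  # (control, case)
    candidates: dict[str, CandidateSpec] = field(default_factory=default_candidates)
    age_range: tuple[float, float] = (55.0, 85.0)
    female_fraction: float = 0.5
    spikeins: SpikeInSpec = field(default_factory=SpikeInSpec)
    haemolysis: HaemolysisSpec = field(default_factory=HaemolysisSpec)
    spectrum_noise_sd: float = 0.005
    cohort_label: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.candidates:
            raise ValueError("candidates must be non-empty")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.spectrum_noise_sd < 0:
            raise ValueError("spectrum_noise_sd must be >= 0")

    def panel(self) -> PanelConfig:
        return PanelConfig(
            candidate_normalizers=tuple(self.candidates),
            spikein_isolation=self.spikeins.isolation_assays,
            spikein_rt=self.spikeins.rt_assays,
            haemolysis_plasma_marker=self.haemolysis.plasma_marker,
            haemolysis_rbc_marker=self.haemolysis.rbc_marker,
        )


def planted_spec(
    n_stable: int = 5,
    n_shifted: int = 2,
    shift: float = 1.5,
    sd: float = 0.2,
    n_per_group: int = 40,
    seed: int = 0,
    **kwargs,
) -> SimSpec:
    """A cohort with a known stable subset and case-shifted candidates.

    Stable candidates carry no group shift; shifted ones move by ``shift``
    Cq in the case group.  Candidate names record the ground truth
    (``stable-1..``, ``shifted-1..``).
    """
    cands = {}
    for i in range(n_stable):
        cands[f"stable-{i + 1}"] = CandidateSpec(24.0 + i, 0.0, sd)
    for i in range(n_shifted):
        cands[f"shifted-{i + 1}"] = CandidateSpec(24.5 + i, shift, sd)
    return SimSpec(
        n_per_group=n_per_group, candidates=cands, seed=seed, **kwargs
    )


def simulate_cq_dataset(spec: SimSpec) -> Dataset:
    """Generate the paired Cq table + metadata for one cohort.

    Cq(sample, assay) = baseline + shift * [case] + slope * (age - mean age)
    + sex effect * [female] + N(0, sd).  Spike-in columns get per-stage
    planted outliers; the RBC marker's Cq drops in proportion to each
    haemolysed sample's contamination level.  Ground truth lands in
    ``gt_contamination_level``, ``gt_is_contaminated`` and
    ``gt_spikein_outlier`` metadata columns.
    """
    rng = np.random.default_rng(spec.seed)
    control, case = spec.groups
    n = 2 * spec.n_per_group
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array([control] * spec.n_per_group + [case] * spec.n_per_group)
    is_case = group == case
    age = rng.uniform(*spec.age_range, size=n)
    mean_age = float(np.mean(spec.age_range))
    female = rng.random(n) < spec.female_fraction
    sex = np.where(female, "F", "M")

    cq = {}
    for name, c in spec.candidates.items():
        cq[name] = (
            c.baseline_cq
            + c.group_shift * is_case
            + c.age_slope * (age - mean_age)
            + c.sex_effect * female
            + rng.normal(0.0, c.sd, size=n)
        )

    # haemolysis markers: plasma marker may double as a candidate
    h = spec.haemolysis
    contaminated = rng.random(n) < h.fraction
    level = np.where(contaminated, rng.uniform(*h.level_range, size=n), 0.0)
    if h.plasma_marker not in cq:
        cq[h.plasma_marker] = 26.0 + rng.normal(0.0, 0.3, size=n)
    cq[h.rbc_marker] = (
        h.rbc_baseline_cq
        + rng.normal(0.0, h.rbc_sd, size=n)
        - h.rbc_cq_per_level * level
    )

    s = spec.spikeins
    outlier = rng.random(n) < s.outlier_fraction
    for assay in tuple(s.isolation_assays) + tuple(s.rt_assays):
        cq[assay] = (
            s.baseline_cq
            + rng.normal(0.0, s.sd, size=n)
            + s.outlier_shift * outlier
        )

    cq_df = pd.DataFrame(cq, index=pd.Index(sample_ids, name="sample_id"))
    meta = pd.DataFrame(
        {
            "group": group,
            "sex": sex,
            "age": age,
            "batch": "machine-1",
            "cohort": spec.cohort_label,
            "gt_contamination_level": level,
            "gt_is_contaminated": contaminated,
            "gt_spikein_outlier": outlier,
        },
        index=cq_df.index,
    )
    return Dataset(cq=cq_df, meta=meta, panel=spec.panel())


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def plasma_baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth featureless plasma absorbance: decaying from the UV end."""
    return 0.08 + 0.9 * np.exp(-(wl - 220.0) / 120.0)


def haemoglobin_band(wl: np.ndarray) -> np.ndarray:
    """Unit-level contamination signature: Soret band at 414 nm plus the
    smaller oxyhaemoglobin Q bands at 541 and 577 nm (Gaussian shapes)."""
    return (
        _gauss(wl, 414.0, 20.0)
        + 0.25 * _gauss(wl, 541.0, 10.0)
        + 0.25 * _gauss(wl, 577.0, 10.0)
    )


def simulate_spectra(
    spec: SimSpec,
    dataset: Dataset | None = None,
    levels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample absorbance scans, 220-750 nm at 1 nm steps (long format).

    A(wl) = baseline(wl) + level * band_height * signature(wl) + noise.
    Contamination levels come from the paired dataset's ground truth when
    given (standalone mode draws its own).  Returns columns
    ``sample_id,wavelength_nm,absorbance``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if levels is None:
        if dataset is not None:
            levels = dataset.meta["gt_contamination_level"]
        else:
            sim = simulate_cq_dataset(spec)
            levels = sim.meta["gt_contamination_level"]
    wl = np.arange(220.0, 751.0, 1.0)
    base = plasma_baseline(wl)
    sig = haemoglobin_band(wl) * spec.haemolysis.band_height_per_level
    frames = []
    for sid, lev in levels.items():
        a = base + float(lev) * sig
        if spec.spectrum_noise_sd > 0:
            a = a + rng.normal(0.0, spec.spectrum_noise_sd, size=wl.size)
        frames.append(
            pd.DataFrame(
                {"sample_id": sid, "wavelength_nm": wl, "absorbance": a}
            )
        )
    return pd.concat(frames, ignore_index=True)
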