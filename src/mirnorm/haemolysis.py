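"""Haemolysis quality control for plasma miRNA samples.

Two families of detector are provided:

* the dCq rule — Cq(plasma marker miR-23a-3p) - Cq(red-blood-cell marker
  miR-451a); a difference strictly above 7 cycles flags red-blood-cell
  contamination,
* absorbance scores read off a 220-750 nm wavelength scan of the plasma,
  exploiting the oxyhaemoglobin Soret band near 414 nm.  Named presets score
  a primary wavelength against a straight-line baseline through two
  reference wavelengths; an arbitrary wavelength->weight map is also
  accepted for published multi-wavelength equations.

``method_concordance`` quantifies how well the detectors agree (Pearson r
and least-squares fit of each score against a reference score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "AbsorbanceSpectrum",
    "HaemolysisSettings",
    "ABSORBANCE_PRESETS",
    "dcq_haemolysis",
    "absorbance_haemolysis",
    "method_concordance",
    "load_spectra",
    "DCqHaemolysisDetector",
]


@dataclass(frozen=True)
class AbsorbancePreset:
    """A named wavelength scheme: primary band + straight-line baseline refs."""

    primary_nm: float
    reference_nm: tuple[float, ...]


#: Named wavelength schemes.  "shkurnikov" and "kahn" carry the wavelength
#: triples of the published equations; the combination rule here is
#: baseline-corrected peak height (the published coefficient constants can be
#: supplied instead as a coefficient map).  "peak414" is the raw absorbance at
#: the oxyhaemoglobin Soret peak.
ABSORBANCE_PRESETS: dict[str, AbsorbancePreset] = {
    "shkurnikov": AbsorbancePreset(primary_nm=415.0, reference_nm=(450.0, 700.0)),
    "kahn": AbsorbancePreset(primary_nm=578.0, reference_nm=(562.0, 598.0)),
    "peak414": AbsorbancePreset(primary_nm=414.0, reference_nm=()),
}


@dataclass(frozen=True)
class HaemolysisSettings:
    """Thresholds and marker assays for haemolysis detection.

    ``dcq_threshold`` is the contamination cut-off in Cq units (default 7);
    ``dcq_pair`` is (plasma marker, RBC marker); miR-16-5p is a supported
    alternate RBC comparator.
    """

    dcq_threshold: float = 7.0
    dcq_pair: tuple[str, str] = ("hsa-miR-23a-3p", "hsa-miR-451a")

    def __post_init__(self) -> None:
        if not self.dcq_threshold > 0:
            raise ValueError("dcq_threshold must be > 0")


class AbsorbanceSpectrum:
    """Per-sample absorbance over a wavelength grid, linearly interpolated.

    Wavelengths must be strictly increasing; queries outside the measured
    range raise rather than extrapolate.
    """

    def __init__(self, sample_id: str, wavelengths, absorbance):
        wl = np.asarray(wavelengths, dtype=float)
        ab = np.asarray(absorbance, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.sample_id = sample_id
        self.wavelengths = wl
        self.absorbance = ab

    def __call__(self, nm: float) -> float:
        """Absorbance at ``nm`` (linear interpolation between grid points)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= nm <= hi):
            raise ValueError(
                f"wavelength {nm} nm outside measured range [{lo:g}, {hi:g}] nm"
            )
        return float(np.interp(nm, self.wavelengths, self.absorbance))


def load_spectra(path) -> dict[str, AbsorbanceSpectrum]:
    """Read long-format spectra (``sample_id,wavelength_nm,absorbance``)."""
    df = pd.read_csv(path)
    needed = {"sample_id", "wavelength_nm", "absorbance"}
    if not needed.issubset(df.columns):
        raise ValueError(f"spectra file needs columns {sorted(needed)}")
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out[str(sid)] = AbsorbanceSpectrum(
            str(sid), grp["wavelength_nm"].to_numpy(), grp["absorbance"].to_numpy()
        )
    return out


def dcq_haemolysis(
    cq: pd.DataFrame, settings: HaemolysisSettings | None = None
) -> pd.DataFrame:
    """Score haemolysis by the marker-pair dCq rule.

    Returns one row per sample with ``dcq_score`` = Cq(plasma marker) -
    Cq(RBC marker), ``dcq_flag`` set exactly when the score strictly exceeds
    the threshold, ``boundary_warning`` when it equals it, and ``evaluable``
    False when either marker Cq is missing (such samples are never flagged).
    """
    settings = settings or HaemolysisSettings()
    plasma, rbc = settings.dcq_pair
    for marker in (plasma, rbc):
        if marker not in cq.columns:
            raise ValueError(f"haemolysis marker assay {marker!r} absent from Cq table")
    score = cq[plasma] - cq[rbc]
    evaluable = score.notna()
    report = pd.DataFrame(
        {
            "dcq_score": score,
            "dcq_flag": evaluable & (score > settings.dcq_threshold),
            "boundary_warning": evaluable & (score == settings.dcq_threshold),
            "evaluable": evaluable,
        },
        index=cq.index,
    )
    return report


def absorbance_haemolysis(
    spectrum: AbsorbanceSpectrum,
    preset: str | dict[float, float] = "peak414",
) -> float:
    """Haemolysis score (OD units) from one absorbance spectrum.

    ``preset`` is a name from :data:`ABSORBANCE_PRESETS` or a wavelength->
    weight coefficient map (score = sum of weight * A(wavelength)).  Named
    presets with reference wavelengths score the baseline-corrected peak
    height A(primary) - L(primary), L the line through the two references.
    """
    if isinstance(preset, dict):
        if not preset:
            raise ValueError("empty coefficient map")
        return float(sum(w * spectrum(nm) for nm, w in preset.items()))
    try:
        scheme = ABSORBANCE_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of "
            f"{sorted(ABSORBANCE_PRESETS)} or a coefficient map"
        ) from None
    peak = spectrum(scheme.primary_nm)
    if not scheme.reference_nm:
        return peak
    (x1, x2) = scheme.reference_nm
    y1, y2 = spectrum(x1), spectrum(x2)
    baseline = y1 + (y2 - y1) * (scheme.primary_nm - x1) / (x2 - x1)
    return float(peak - baseline)


def score_spectra(
    spectra: dict[str, AbsorbanceSpectrum],
    presets: list[str] | None = None,
) -> pd.DataFrame:
    """Apply each named preset to every spectrum; one column per preset."""
    presets = presets or list(ABSORBANCE_PRESETS)
    rows = {
        sid: {p: absorbance_haemolysis(spec, p) for p in presets}
        for sid, spec in spectra.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[presets]


def method_concordance(
    scores: pd.DataFrame, reference: str = "peak414"
) -> pd.DataFrame:
    """Pearson r and least-squares line of each score column vs a reference.

    One row per non-reference method with ``r``, ``slope``, ``intercept``,
    ``n`` and ``evaluable``; a pair with fewer than 3 complete observations
    or with zero variance on either side is reported as not evaluable with a
    reason instead of a spurious coefficient.
    """
    if reference not in scores.columns:
        raise ValueError(f"reference column {reference!r} not in scores")
    rows = []
    for method in scores.columns:
        if method == reference:
            continue
        pair = scores[[method, reference]].dropna()
        row = {"method": method, "n": len(pair)}
        if len(pair) < 3:
            row.update(evaluable=False, reason="fewer than 3 paired observations")
        elif pair[method].nunique() == 1 or pair[reference].nunique() == 1:
            row.update(evaluable=False, reason="zero variance")
        else:
            fit = stats.linregress(pair[reference], pair[method])
            row.update(
                evaluable=True,
                reason="",
                r=fit.rvalue,
                slope=fit.slope,
                intercept=fit.intercept,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


class DCqHaemolysisDetector(BaseEstimator):
    """Scikit-learn-style wrapper around the dCq haemolysis rule.

    The rule is stateless; ``fit`` only validates that the marker assays are
    present.  ``predict`` returns a boolean contamination flag per sample and
    ``score_samples`` the raw dCq score.

    Parameters
    ----------
    threshold : float, default 7.0
        Contamination cut-off in Cq units (flag iff score > threshold).
    plasma_marker, rbc_marker : str
        Marker assay column names.
    """

    def __init__(
        self,
        threshold: float = 7.0,
        plasma_marker: str = "hsa-miR-23a-3p",
        rbc_marker: str = "hsa-miR-451a",
    ):
        self.threshold = threshold
        self.plasma_marker = plasma_marker
        self.rbc_marker = rbc_marker

    def _settings(self) -> HaemolysisSettings:
        return HaemolysisSettings(
            dcq_threshold=self.threshold,
            dcq_pair=(self.plasma_marker, self.rbc_marker),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "DCqHaemolysisDetector":
        dcq_haemolysis(X, self._settings())  # validates markers
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean flag per sample: True = contaminated."""
        return dcq_haemolysis(X, self._settings())["dcq_flag"].to_numpy()

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """Raw dCq scores (plasma marker minus RBC marker)."""
        return dcq_haemolysis(X, self._settings())["dcq_score"].to_numpy()
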