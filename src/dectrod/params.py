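"""Quantitative DECT parameter derivations and the lesion-node similarity statistic.

Dual-energy CT (DECT) yields, for every region of interest, the attenuation of
virtual monochromatic images at 40 and 70 keV (HU), the iodine and water
concentrations from two-material decomposition (mg/cm^3), and the effective
atomic number of the voxel-equivalent single-element material (Eff-Z).

From these raw quantities this module derives:

* the spectral slope ``lambda_HU = (att40 - att70) / 30`` in HU/keV, a proxy
  for iodine content;
* aorta-normalized iodine/water concentration and Eff-Z (the ROI value divided
  by the same quantity measured in the aorta, which removes inter-patient
  differences in cardiac output and contrast-bolus timing);
* the rate of difference (ROD) between an axillary lymph node and the primary
  breast lesion, ``|node - lesion| / |lesion|`` -- a dimensionless similarity
  statistic that is 0 when node and lesion are spectrally identical.  A
  metastatic node, whose tissue is replaced by tumour, is expected to resemble
  its primary lesion (small ROD); a reactive node is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpectralMeasurement",
    "AortaReference",
    "DerivedParameters",
    "SimilarityProfile",
    "UndefinedRODError",
    "compute_lambda_hu",
    "compute_rod",
    "normalize_by_aorta",
    "build_similarity_profile",
    "derive_columns",
    "round_sig",
    "ROD_PARAMETERS",
]

#: energy gap between the two virtual monochromatic images, keV
ENERGY_DIFF_KEV = 30.0

#: parameters for which a ROD is computed, in reporting order
ROD_PARAMETERS = ("att40", "att70", "lambda", "ic", "wc", "effz")


class UndefinedRODError(ValueError):
    """Raised when a ROD denominator (the primary-lesion value) is zero."""


@dataclass(frozen=True)
class SpectralMeasurement:
    """Raw DECT quantities for one ROI.

    Parameters
    ----------
    att40, att70 : float
        Mean attenuation of the 40- and 70-keV virtual monochromatic
        images over the ROI, in HU.
    ic, wc : float
        Iodine and water concentration, mg/cm^3.
    effz : float
        Effective atomic number (dimensionless).
    roi_area : float, optional
        Physical ROI area in mm^2, when the measurement came from an image.
    """

    att40: float
    att70: float
    ic: float
    wc: float
    effz: float
    roi_area: Optional[float] = None

    def __post_init__(self) -> None:
        for f in ("att40", "att70", "ic", "wc", "effz"):
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValueError(f"{f} must be finite, got {v!r}")
        if self.ic < 0:
            raise ValueError(f"iodine concentration must be >= 0, got {self.ic}")
        if self.wc <= 0:
            raise ValueError(f"water concentration must be > 0, got {self.wc}")
        if self.effz <= 0:
            raise ValueError(f"effective atomic number must be > 0, got {self.effz}")
        if self.roi_area is not None and self.roi_area <= 0:
            raise ValueError(f"roi_area must be > 0 when given, got {self.roi_area}")

    @property
    def lambda_hu(self) -> float:
        """Spectral slope of this measurement, HU/keV."""
        return compute_lambda_hu(self.att40, self.att70)


@dataclass(frozen=True)
class AortaReference:
    """Aortic IC/WC/Eff-Z used to normalize a patient's measurements."""

    ic: float
    wc: float
    effz: float

    def __post_init__(self) -> None:
        for f in ("ic", "wc", "effz"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"aorta {f} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class DerivedParameters:
    """Spectral slope and aorta-normalized quantities for one ROI."""

    lambda_hu: float
    norm_ic: float
    norm_wc: float
    norm_effz: float


@dataclass(frozen=True)
class SimilarityProfile:
    """Per-parameter ROD values for one lesion-node pair (all >= 0)."""

    rod_att40: float
    rod_att70: float
    rod_lambda: float
    rod_ic: float
    rod_wc: float
    rod_effz: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_lambda_hu(att40, att70):
    """Spectral slope (att40 - att70) / 30 in HU/keV.

    Accepts scalars or arrays.  Raises ``ValueError`` on non-finite scalar
    input; array input propagates NaN.
    """
    a40 = np.asarray(att40, dtype=float)
    a70 = np.asarray(att70, dtype=float)
    if a40.ndim == 0 and a70.ndim == 0:
        if not (math.isfinite(float(a40)) and math.isfinite(float(a70))):
            raise ValueError("attenuations must be finite")
        return (float(a40) - float(a70)) / ENERGY_DIFF_KEV
    return (a40 - a70) / ENERGY_DIFF_KEV


def compute_rod(node_value, lesion_value):
    """Rate of difference |node - lesion| / |lesion|.

    The denominator uses the absolute lesion value so that the statistic stays
    a nonnegative relative difference even for parameters that can be negative
    (attenuation of fatty tissue, say); for the positive-valued quantities of
    this study it coincides with division by the lesion value itself.

    Raises
    ------
    UndefinedRODError
        If the lesion (denominator) value is zero.
    """
    node = np.asarray(node_value, dtype=float)
    lesion = np.asarray(lesion_value, dtype=float)
    scalar = node.ndim == 0 and lesion.ndim == 0
    if np.any(lesion == 0):
        raise UndefinedRODError("ROD undefined: primary-lesion value is zero")
    out = np.abs(node - lesion) / np.abs(lesion)
    return float(out) if scalar else out


def normalize_by_aorta(measurement: SpectralMeasurement, aorta: AortaReference):
    """Divide a measurement's IC, WC and Eff-Z by the aortic values.

    Returns a ``(norm_ic, norm_wc, norm_effz)`` tuple of dimensionless ratios.
    """
    if aorta.ic <= 0 or aorta.wc <= 0 or aorta.effz <= 0:
        raise ValueError("aorta reference values must be strictly positive")
    return (
        measurement.ic / aorta.ic,
        measurement.wc / aorta.wc,
        measurement.effz / aorta.effz,
    )


def derive_parameters(
    measurement: SpectralMeasurement, aorta: AortaReference
) -> DerivedParameters:
    """Bundle spectral slope and aorta-normalized values for one ROI."""
    norm_ic, norm_wc, norm_effz = normalize_by_aorta(measurement, aorta)
    return DerivedParameters(
        lambda_hu=measurement.lambda_hu,
        norm_ic=norm_ic,
        norm_wc=norm_wc,
        norm_effz=norm_effz,
    )


def build_similarity_profile(
    lesion: SpectralMeasurement,
    node: SpectralMeasurement,
    lesion_lambda_hu: Optional[float] = None,
    node_lambda_hu: Optional[float] = None,
) -> SimilarityProfile:
    """Element-wise ROD over the six DECT quantities of a lesion-node pair.

    By default the spectral slopes entering ``rod_lambda`` are recomputed at
    full precision from the attenuations.  Pass ``lesion_lambda_hu`` /
    ``node_lambda_hu`` to use externally reported (for instance rounded)
    slopes instead.

    Raises
    ------
    UndefinedRODError
        Naming the offending parameter when a lesion value is zero.
    """
    llam = lesion.lambda_hu if lesion_lambda_hu is None else lesion_lambda_hu
    nlam = node.lambda_hu if node_lambda_hu is None else node_lambda_hu
    pairs = {
        "att40": (node.att40, lesion.att40),
        "att70": (node.att70, lesion.att70),
        "lambda": (nlam, llam),
        "ic": (node.ic, lesion.ic),
        "wc": (node.wc, lesion.wc),
        "effz": (node.effz, lesion.effz),
    }
    rods = {}
    for name, (nv, lv) in pairs.items():
        try:
            rods[f"rod_{name}"] = compute_rod(nv, lv)
        except UndefinedRODError as exc:
            raise UndefinedRODError(
                f"ROD undefined for parameter {name!r}: lesion value is zero"
            ) from exc
    return SimilarityProfile(**rods)


# ---------------------------------------------------------------------------
# cohort-table interface

_SITES = ("lesion", "node")
_RAW = ("att40_hu", "att70_hu", "ic_mgcm3", "wc_mgcm3", "effz")


def derive_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a cohort table (copy returned).

    Input columns follow the cohort CSV schema (``lesion_att40_hu`` ...,
    ``node_att40_hu`` ..., ``aorta_ic_mgcm3`` ...).  Added columns:

    ``lambda_hu_lesion``, ``lambda_hu_node``
        spectral slopes, HU/keV;
    ``norm_ic_lesion`` ... ``norm_effz_node``
        aorta-normalized IC/WC/Eff-Z per site;
    ``rod_att40``, ``rod_att70``, ``rod_lambda``, ``rod_ic``, ``rod_wc``,
    ``rod_effz``
        lesion-node similarity statistics (``rod_lambda`` from the
        full-precision slopes).
    """
    df = cohort.copy()
    for site in _SITES:
        df[f"lambda_hu_{site}"] = compute_lambda_hu(
            df[f"{site}_att40_hu"].to_numpy(), df[f"{site}_att70_hu"].to_numpy()
        )
        for q in ("ic_mgcm3", "wc_mgcm3", "effz"):
            short = q.split("_")[0]
            df[f"norm_{short}_{site}"] = (
                df[f"{site}_{q}"].to_numpy() / df[f"aorta_{q}"].to_numpy()
            )
    rod_cols = {
        "rod_att40": ("node_att40_hu", "lesion_att40_hu"),
        "rod_att70": ("node_att70_hu", "lesion_att70_hu"),
        "rod_lambda": ("lambda_hu_node", "lambda_hu_lesion"),
        "rod_ic": ("node_ic_mgcm3", "lesion_ic_mgcm3"),
        "rod_wc": ("node_wc_mgcm3", "lesion_wc_mgcm3"),
        "rod_effz": ("node_effz", "lesion_effz"),
    }
    for col, (ncol, lcol) in rod_cols.items():
        df[col] = compute_rod(df[ncol].to_numpy(), df[lcol].to_numpy())
    return df


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
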