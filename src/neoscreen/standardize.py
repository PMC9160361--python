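"""Multiple-of-median (MoM) standardization and feature construction.

MoM divides each analyte concentration by the median of its laboratory
batch, removing multiplicative laboratory/regional scale differences.  The
model features combine analyte MoMs, diagnostic ratios computed on the MoM
scale, and the covariates gestational week, collection interval and birth
weight, in a fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FeatureError, StratumError
from .synth_cohort import Covariates, NewbornRecord, cohort_to_frame

__all__ = [
    "MedianReference",
    "MoMProfile",
    "FeatureVector",
    "RatioDef",
    "DEFAULT_RATIOS",
    "FEATURE_COVARIATES",
    "compute_median_reference",
    "to_mom",
    "mom_frame",
    "build_features",
    "feature_frame",
    "write_median_reference",
    "read_median_reference",
]

#: covariates appended to the feature vector, in this order
FEATURE_COVARIATES = ("gestational_week", "collection_interval", "birth_weight")

#: floor below which a ratio denominator is considered degenerate
RATIO_DENOMINATOR_FLOOR = 1e-6


class RatioDef(NamedTuple):
    name: str
    numerator: str
    denominator: str


#: standard diagnostic ratios for the default panel
DEFAULT_RATIOS = (
    RatioDef("Phe/Tyr", "Phe", "Tyr"),
    RatioDef("Cit/Arg", "Cit", "Arg"),
    RatioDef("C3/C0", "C3", "C0"),
    RatioDef("C8/C0", "C8", "C0"),
)


@dataclass(frozen=True)
class MedianReference:
    """Per-stratum (laboratory batch), per-analyte sample medians (µmol/L)."""

    medians: Mapping[str, Mapping[str, float]]
    analytes: tuple

    def for_stratum(self, stratum: str) -> Mapping[str, float]:
        if stratum not in self.medians:
            raise ConfigurationError(f"unknown stratum {stratum!r} in median reference")
        return self.medians[stratum]


@dataclass(frozen=True)
class MoMProfile:
    sample_id: str
    mom: Mapping[str, float]


@dataclass(frozen=True)
class FeatureVector:
    sample_id: str
    names: tuple
    values: np.ndarray


def compute_median_reference(
    cohort: Sequence[NewbornRecord],
    stratify_by: str = "batch_id",
    min_count: int = 50,
) -> MedianReference:
    """Per-stratum, per-analyte sample median.

    The even-n median is the midpoint of the two central order statistics
    (numpy's convention).  A stratum below ``min_count`` raises
    :class:`StratumError` naming the stratum: a median from a handful of
    newborns is not a usable laboratory reference.
    """
    if not cohort:
        raise StratumError("cannot compute a median reference from an empty cohort")
    frame = cohort_to_frame(cohort)
    analytes = tuple(a for a in cohort[0].concentrations)
    medians: dict = {}
    for stratum, sub in frame.groupby(stratify_by, sort=True):
        if len(sub) < min_count:
            raise StratumError(
                f"stratum {stratum!r} has {len(sub)} samples, below the minimum of {min_count}"
            )
        medians[str(stratum)] = {a: float(np.median(sub[a].to_numpy())) for a in analytes}
    return MedianReference(medians=medians, analytes=analytes)


def to_mom(record: NewbornRecord, ref: MedianReference) -> MoMProfile:
    """MoM(analyte) = concentration / stratum median."""
    stratum_medians = ref.for_stratum(record.covariates.batch_id)
    mom = {}
    for analyte in ref.analytes:
        m = stratum_medians[analyte]
        if m <= 0:
            raise ConfigurationError(f"median for {analyte!r} in stratum "
                                     f"{record.covariates.batch_id!r} is not positive")
        mom[analyte] = record.concentrations[analyte] / m
    return MoMProfile(sample_id=record.sample_id, mom=mom)


def mom_frame(cohort: Sequence[NewbornRecord], ref: MedianReference) -> pd.DataFrame:
    """Vectorized MoM table (samples x analytes)."""
    frame = cohort_to_frame(cohort)
    if frame.empty:
        return pd.DataFrame(columns=list(ref.analytes))
    med = pd.DataFrame(ref.medians).T  # strata x analytes
    unknown = set(frame["batch_id"]) - set(med.index)
    if unknown:
        raise ConfigurationError(f"unknown strata in cohort: {sorted(unknown)}")
    divisors = med.loc[frame["batch_id"], list(ref.analytes)].to_numpy()
    return pd.DataFrame(
        frame[list(ref.analytes)].to_numpy() / divisors,
        index=frame.index,
        columns=list(ref.analytes),
    )


def _ratio(mom: Mapping[str, float], rd: RatioDef, sample_id: str) -> float:
    den = mom[rd.denominator]
    if den < RATIO_DENOMINATOR_FLOOR:
        raise FeatureError(
            f"sample {sample_id}: denominator {rd.denominator!r} MoM {den} below floor"
        )
    return mom[rd.numerator] / den


def build_features(
    mom: MoMProfile,
    covariates: Covariates,
    ratio_defs: Sequence[RatioDef] = DEFAULT_RATIOS,
) -> FeatureVector:
    """Assemble one feature vector: analyte MoMs, then ratio features on
    the MoM scale, then covariates (:data:`FEATURE_COVARIATES` order)."""
    names = list(mom.mom) + [rd.name for rd in ratio_defs] + list(FEATURE_COVARIATES)
    values = [mom.mom[a] for a in mom.mom]
    for rd in ratio_defs:
        if rd.numerator not in mom.mom or rd.denominator not in mom.mom:
            raise FeatureError(f"ratio {rd.name!r} references analytes outside the MoM profile")
        values.append(_ratio(mom.mom, rd, mom.sample_id))
    for c in FEATURE_COVARIATES:
        values.append(float(getattr(covariates, c)))
    return FeatureVector(sample_id=mom.sample_id, names=tuple(names), values=np.asarray(values, dtype=float))


def feature_frame(
    cohort: Sequence[NewbornRecord],
    ref: MedianReference,
    ratio_defs: Sequence[RatioDef] = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Vectorized feature table for a whole cohort; column order is
    identical across calls for a fixed panel and ratio config."""
    moms = mom_frame(cohort, ref)
    frame = cohort_to_frame(cohort)
    out = moms.copy()
    for rd in ratio_defs:
        if rd.numerator not in moms.columns or rd.denominator not in moms.columns:
            raise FeatureError(f"ratio {rd.name!r} references analytes outside the panel")
        den = moms[rd.denominator]
        bad = den[den < RATIO_DENOMINATOR_FLOOR]
        if len(bad):
            raise FeatureError(
                f"sample {bad.index[0]}: denominator {rd.denominator!r} MoM below floor"
            )
        out[rd.name] = moms[rd.numerator] / den
    for c in FEATURE_COVARIATES:
        out[c] = frame[c].astype(float)
    return out


def write_median_reference(ref: MedianReference, path) -> None:
    rows = [
        {"stratum": s, "analyte": a, "median": m}
        for s, per in sorted(ref.medians.items())
        for a, m in per.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_median_reference(path) -> MedianReference:
    frame = pd.read_csv(path, sep="\t", dtype={"stratum": str})
    medians: dict = {}
    for _, row in frame.iterrows():
        medians.setdefault(row["stratum"], {})[row["analyte"]] = float(row["median"])
    analytes = tuple(frame["analyte"].unique())
    return MedianReference(medians=medians, analytes=analytes)
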