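"""Laboratory cutoff screening: the physician baseline.

Each disease group carries one or more cutoff rules on raw analyte
concentrations (or raw-scale ratios).  The normal range is inclusive of its
bounds: a value strictly outside [low, high] flags.  The recall protocol
re-measures initially flagged samples with multiplicative log-normal
measurement noise and calls "suspected positive" only samples flagged on
both draws, mirroring the screen -> recall -> retest flow of real
programmes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortParseError, ConfigurationError
from .synth_cohort import DiseaseGroup, NewbornRecord, cohort_to_frame

__all__ = [
    "CutoffRule",
    "ScreeningProtocol",
    "apply_cutoffs",
    "screen_cohort",
    "recall_protocol",
    "derive_cutoff_rules",
    "write_rules",
    "read_rules",
]


@dataclass(frozen=True)
class CutoffRule:
    """Normal range for one analyte or raw-scale ratio.

    ``direction``: "above" flags value > high, "below" flags value < low,
    "outside" flags either exceedance.  Bounds are inclusive of the normal
    range (a value equal to a bound does not flag).
    """

    target: str
    low: float | None = None
    high: float | None = None
    direction: str = "outside"

    def __post_init__(self):
        if self.low is None and self.high is None:
            raise ConfigurationError(f"rule for {self.target!r}: at least one bound required")
        if self.low is not None and self.high is not None and not (self.low < self.high):
            raise ConfigurationError(f"rule for {self.target!r}: low must be < high")
        if self.direction not in ("above", "below", "outside"):
            raise ConfigurationError(f"rule for {self.target!r}: unknown direction {self.direction!r}")
        if self.direction == "above" and self.high is None:
            raise ConfigurationError(f"rule for {self.target!r}: 'above' requires a high bound")
        if self.direction == "below" and self.low is None:
            raise ConfigurationError(f"rule for {self.target!r}: 'below' requires a low bound")

    def violated(self, value: float) -> bool:
        above = self.high is not None and value > self.high
        below = self.low is not None and value < self.low
        if self.direction == "above":
            return above
        if self.direction == "below":
            return below
        return above or below


@dataclass(frozen=True)
class ScreeningProtocol:
    rules: Mapping[str, tuple]  # group_id -> tuple of CutoffRule
    retest_on_flag: bool = True
    retest_cv: float = 0.10

    def __post_init__(self):
        for group, group_rules in self.rules.items():
            if not group_rules:
                raise ConfigurationError(f"group {group!r} has no cutoff rules")


def _target_values(conc: pd.DataFrame, target: str) -> pd.Series:
    if "/" in target:
        num, den = target.split("/", 1)
        for part in (num, den):
            if part not in conc.columns:
                raise ConfigurationError(f"rule target {target!r} references absent analyte {part!r}")
        return conc[num] / conc[den]
    if target not in conc.columns:
        raise ConfigurationError(f"rule references absent analyte {target!r}")
    return conc[target]


def apply_cutoffs(record: NewbornRecord, rules: Sequence[CutoffRule]) -> bool:
    """True when any rule is violated on this record's raw concentrations."""
    conc = pd.DataFrame([record.concentrations])
    for rule in rules:
        value = float(_target_values(conc, rule.target).iloc[0])
        if rule.violated(value):
            return True
    return False


def _flags_frame(conc: pd.DataFrame, protocol: ScreeningProtocol) -> pd.DataFrame:
    out = {}
    for group, group_rules in protocol.rules.items():
        flagged = pd.Series(False, index=conc.index)
        for rule in group_rules:
            values = _target_values(conc, rule.target)
            above = (values > rule.high) if rule.high is not None else False
            below = (values < rule.low) if rule.low is not None else False
            if rule.direction == "above":
                flagged |= above
            elif rule.direction == "below":
                flagged |= below
            else:
                flagged |= above | below
        out[group] = flagged
    return pd.DataFrame(out, index=conc.index)


def screen_cohort(cohort: Sequence[NewbornRecord], protocol: ScreeningProtocol) -> pd.DataFrame:
    """Initial per-group flags for a whole cohort (samples x groups)."""
    if not cohort:
        return pd.DataFrame(columns=list(protocol.rules))
    frame = cohort_to_frame(cohort)
    analytes = [c for c in cohort[0].concentrations]
    return _flags_frame(frame[analytes], protocol)


def recall_protocol(cohort: Sequence[NewbornRecord], protocol: ScreeningProtocol, seed: int = 0) -> pd.DataFrame:
    """Suspected-positive flags: initially flagged AND flagged on a retest
    draw with multiplicative log-normal noise at the protocol's CV.
    Deterministic given the seed; with ``retest_on_flag`` off (or zero CV)
    this reduces to the initial flags."""
    if not cohort:
        return pd.DataFrame(columns=list(protocol.rules))
    frame = cohort_to_frame(cohort)
    analytes = [c for c in cohort[0].concentrations]
    conc = frame[analytes]
    initial = _flags_frame(conc, protocol)
    if not protocol.retest_on_flag or protocol.retest_cv == 0:
        return initial
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(protocol.retest_cv**2)))
    retest_conc = conc * np.exp(rng.normal(0.0, sigma, conc.shape))
    retest = _flags_frame(retest_conc, protocol)
    return initial & retest


def derive_cutoff_rules(
    cohort: Sequence[NewbornRecord],
    groups: Sequence[DiseaseGroup],
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> ScreeningProtocol:
    """Percentile-based default cutoffs on each group's primary marker,
    emulating a laboratory's historical reference ranges: elevated-marker
    groups flag above the upper percentile of the unaffected population,
    deficiency-marker groups flag below the lower percentile."""
    unaffected = [r for r in cohort if r.true_group is None]
    if not unaffected:
        raise ConfigurationError("need unaffected samples to derive percentile cutoffs")
    frame = cohort_to_frame(unaffected)
    rules = {}
    for g in groups:
        values = frame[g.primary_marker].to_numpy()
        lo = float(np.percentile(values, lower_pct))
        hi = float(np.percentile(values, upper_pct))
        direction = "above" if g.signature[g.primary_marker][0] >= 0 else "below"
        rules[g.group_id] = (CutoffRule(target=g.primary_marker, low=lo, high=hi, direction=direction),)
    return ScreeningProtocol(rules=rules)


def write_rules(protocol: ScreeningProtocol, path) -> None:
    rows = []
    for group, group_rules in protocol.rules.items():
        for rule in group_rules:
            rows.append({
                "group": group,
                "target": rule.target,
                "low": "" if rule.low is None else rule.low,
                "high": "" if rule.high is None else rule.high,
                "direction": rule.direction,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rules(path, retest_on_flag: bool = True, retest_cv: float = 0.10) -> ScreeningProtocol:
    frame = pd.read_csv(path, sep="\t", dtype={"group": str, "target": str, "direction": str})
    required = {"group", "target", "low", "high", "direction"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortParseError(f"rules file missing columns: {sorted(missing)}")
    rules: dict = {}
    for _, row in frame.iterrows():
        low = None if pd.isna(row["low"]) else float(row["low"])
        high = None if pd.isna(row["high"]) else float(row["high"])
        rules.setdefault(row["group"], []).append(
            CutoffRule(target=row["target"], low=low, high=high, direction=row["direction"])
        )
    return ScreeningProtocol(
        rules={g: tuple(rs) for g, rs in rules.items()},
        retest_on_flag=retest_on_flag,
        retest_cv=retest_cv,
    )
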