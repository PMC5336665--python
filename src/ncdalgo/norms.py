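"""Stratified norms, z standardization, domain means and impairment grades.

Raw scores are standardized against sex- and education-stratified cohort norms
built from the whole sample at wave 4; longitudinal decline is standardized the
same way against the cohort distribution of (wave4 - wave3) change scores.
After standardization a z of -2 or below always means severe impairment,
regardless of whether the raw scale runs up (accuracy) or down (time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .records import DOMAINS, BatteryConfig, ParticipantRecord

__all__ = [
    "EDUCATION_BANDS",
    "NormTable",
    "DomainScores",
    "CutoffConfig",
    "NormError",
    "education_band",
    "build_norms",
    "standardize",
    "domain_scores",
    "impairment_grade",
    "percentile_to_z",
]

EDUCATION_BANDS = ("low", "medium", "high")


class NormError(ValueError):
    """A norm cell cannot be built (empty stratum or zero variance)."""


def education_band(years: int) -> str:
    """Band years of education: low <10, medium 10-14, high 15+.

    The band edges are half-open ([5,10), [10,15), [15,inf)); fewer than five
    years clamps to low.
    """
    if years < 0:
        raise ValueError("education years must be nonnegative")
    if years < 10:
        return "low"
    if years < 15:
        return "medium"
    return "high"


@dataclass(frozen=True)
class CutoffConfig:
    """Impairment cutoffs.

    severe_cutoff: z at or below this is severe (default -2.0, inclusive).
    mild_variant: "sd1_0" grades z in (-2.0, -1.0] as mild; "sd1_5" narrows
    the mild band to (-2.0, -1.5].
    """

    severe_cutoff: float = -2.0
    mild_variant: str = "sd1_0"

    def __post_init__(self) -> None:
        if self.mild_variant not in ("sd1_0", "sd1_5"):
            raise ValueError(f"unknown mild_variant {self.mild_variant!r}")
        if not self.severe_cutoff < self.mild_upper < 0:
            raise ValueError("require severe_cutoff < mild upper bound < 0")

    @property
    def mild_upper(self) -> float:
        return -1.0 if self.mild_variant == "sd1_0" else -1.5


def impairment_grade(z: float, cutoffs: CutoffConfig = CutoffConfig()) -> str:
    """Grade a z score as severe, mild or normal."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    if z <= cutoffs.severe_cutoff:
        return "severe"
    if z <= cutoffs.mild_upper:
        return "mild"
    return "normal"


def percentile_to_z(p: float) -> float:
    """Standard-normal quantile of a percentile in (0, 100)."""
    if not 0 < p < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    return float(stats.norm.ppf(p / 100.0))


@dataclass(frozen=True)
class NormTable:
    """Per (test, sex, education band, kind) mean and SD.

    ``kind`` is ``level_w4`` for wave-4 scores or ``change_w3_to_w4`` for the
    raw change score; SDs are sample SDs (ddof=1) and must be positive.
    """

    entries: dict[tuple[str, str, str, str], tuple[float, float]]

    def cell(self, test: str, sex: str, band: str, kind: str = "level_w4"):
        return self.entries.get((test, sex, band, kind))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"test": t, "sex": s, "education_band": b, "kind": k, "mean": m, "sd": sd}
            for (t, s, b, k), (m, sd) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["test", "sex", "education_band", "kind", "mean", "sd"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "NormTable":
        df = pd.read_csv(path)
        entries = {
            (r.test, r.sex, r.education_band, r.kind): (float(r["mean"]), float(r.sd))
            for r in df.itertuples(index=False)
        }
        return cls(entries)


def _cell_stats(values: list[float], name: str, min_n: int) -> tuple[float, float]:
    if len(values) < min_n:
        raise NormError(
            f"norm cell {name} has {len(values)} scores, fewer than the "
            f"required {min_n}"
        )
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd <= 0:
        raise NormError(f"norm cell {name} has zero variance")
    return mean, sd


def build_norms(
    cohort: Iterable[ParticipantRecord],
    battery: BatteryConfig,
    min_stratum_n: int = 10,
) -> NormTable:
    """Build sex x education-band norms from the whole cohort at wave 4.

    Level norms cover every configured test; change norms cover the
    decline-eligible tests, computed from (w4 - w3) differences among
    participants observed at both waves.
    """
    cohort = list(cohort)
    level: dict[tuple[str, str, str], list[float]] = {}
    change: dict[tuple[str, str, str], list[float]] = {}
    for rec in cohort:
        band = education_band(rec.education_years)
        for test in battery.tests:
            w4 = rec.score(test, 4)
            if w4 is not None:
                level.setdefault((test, rec.sex, band), []).append(w4)
            if test in battery.decline_tests:
                w3 = rec.score(test, 3)
                if w3 is not None and w4 is not None:
                    change.setdefault((test, rec.sex, band), []).append(w4 - w3)
    entries: dict[tuple[str, str, str, str], tuple[float, float]] = {}
    for test in battery.tests:
        for sex in ("male", "female"):
            for band in EDUCATION_BANDS:
                key = (test, sex, band)
                name = f"({test}, {sex}, {band})"
                entries[(test, sex, band, "level_w4")] = _cell_stats(
                    level.get(key, []), f"level {name}", min_stratum_n
                )
                if test in battery.decline_tests:
                    entries[(test, sex, band, "change_w3_to_w4")] = _cell_stats(
                        change.get(key, []), f"change {name}", min_stratum_n
                    )
    return NormTable(entries)


def standardize(
    raw: Optional[float],
    test: str,
    sex: str,
    band: str,
    norms: NormTable,
    direction: str,
    kind: str = "level_w4",
) -> Optional[float]:
    """Convert a raw score to a z score against its stratum norm.

    For lower-better (timed) tests the z is negated so that impairment is
    always a low z. Missing raw scores yield a missing z, not an error.
    """
    if raw is None:
        return None
    cell = norms.cell(test, sex, band, kind)
    if cell is None:
        raise NormError(f"no {kind} norm for ({test}, {sex}, {band})")
    mean, sd = cell
    z = (raw - mean) / sd
    if direction == "lower_better":
        z = -z
    return float(z)


@dataclass
class DomainScores:
    """Per-domain mean z, per-test level z and per-test decline z."""

    domain_z: dict[str, Optional[float]] = field(default_factory=dict)
    test_z: dict[str, Optional[float]] = field(default_factory=dict)
    decline_z: dict[str, Optional[float]] = field(default_factory=dict)
    n_tests_used: dict[str, int] = field(default_factory=dict)

    def available_domains(self) -> dict[str, float]:
        return {d: z for d, z in self.domain_z.items() if z is not None}

    def available_declines(self) -> dict[str, float]:
        return {t: z for t, z in self.decline_z.items() if z is not None}


def domain_scores(
    record: ParticipantRecord,
    norms: NormTable,
    battery: BatteryConfig,
    min_tests: int = 1,
) -> DomainScores:
    """Standardize one participant: domain means, level z and decline z.

    A domain mean is the arithmetic mean of its available member-test z at
    wave 4, reported only when at least ``min_tests`` members are observed.
    """
    band = education_band(record.education_years)
    out = DomainScores()
    for domain in DOMAINS:
        zs = []
        for test in battery.domain_map.get(domain, ()):
            z = standardize(
                record.score(test, 4),
                test,
                record.sex,
                band,
                norms,
                battery.direction[test],
            )
            out.test_z[test] = z
            if z is not None:
                zs.append(z)
        out.n_tests_used[domain] = len(zs)
        out.domain_z[domain] = float(np.mean(zs)) if len(zs) >= min_tests else None
    for test in battery.decline_tests:
        w3, w4 = record.score(test, 3), record.score(test, 4)
        raw_change = None if (w3 is None or w4 is None) else w4 - w3
        out.decline_z[test] = standardize(
            raw_change,
            test,
            record.sex,
            band,
            norms,
            battery.direction[test],
            kind="change_w3_to_w4",
        )
    return out
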