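"""Compendial single-time-point disintegration verdicts and study tables.

Pharmacopoeial disintegration tests judge a dosage form by a single time
limit: the European Pharmacopoeia accepts an orodispersible tablet that
disintegrates completely within 180 s in the basket-rack apparatus, while
the US Pharmacopeia applies a stricter 30 s limit.  A time exactly equal
to the limit passes ("30 s or less"), applied uniformly to both compendia.

The apparatus parameters carried on :class:`CompendialSpec` (31 cycles/min,
54 mm stroke, 900 mL bath, 37 degC, discs) are metadata describing the
standard method; no hydrodynamics are simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidInputError
from .kinetics import ReplicateSummary, percent_change

__all__ = [
    "CompendialSpec",
    "EUPH",
    "USP_ODT",
    "VerdictResult",
    "StudySummary",
    "verdict",
    "study_summary",
]


@dataclass(frozen=True)
class CompendialSpec:
    """A compendial disintegration criterion plus apparatus metadata."""

    name: str
    limit_s: float
    cycles_per_min: float = 31.0
    stroke_mm: float = 54.0
    bath_volume_ml: float = 900.0
    temperature_c: float = 37.0
    discs: bool = True

    def __post_init__(self) -> None:
        if self.limit_s <= 0:
            raise InvalidInputError("limit_s must be positive")


#: European Pharmacopoeia ODT criterion: complete disintegration within 3 min.
EUPH = CompendialSpec(name="EuPh", limit_s=180.0)

#: US Pharmacopeia ODT criterion: disintegration within 30 s or less.
USP_ODT = CompendialSpec(name="USP", limit_s=30.0)


@dataclass(frozen=True)
class VerdictResult:
    """Per-item pass/fail flags against one compendial limit."""

    spec: CompendialSpec
    times_s: tuple[float, ...]
    passed: tuple[bool, ...]

    @property
    def n_pass(self) -> int:
        return sum(self.passed)

    @property
    def all_pass(self) -> bool:
        return all(self.passed)


def verdict(times_s: list[float], spec: CompendialSpec) -> VerdictResult:
    """Apply the single-time-point rule: item passes iff time <= limit."""
    if len(times_s) == 0:
        raise InvalidInputError("no disintegration times supplied")
    if any(t is None or t <= 0 for t in times_s):
        raise InvalidInputError("disintegration times must be positive")
    flags = tuple(t <= spec.limit_s for t in times_s)
    return VerdictResult(spec=spec, times_s=tuple(float(t) for t in times_s),
                         passed=flags)


@dataclass(frozen=True)
class StudySummary:
    """Cross-method study table plus low-to-high hardness contrasts."""

    table: pd.DataFrame
    percent_change_ocm: float | None
    percent_change_euph: float | None


def _hardness_key(label: str) -> float:
    try:
        return float(str(label).rstrip("kp").strip())
    except ValueError:
        return float("inf")


def study_summary(
    ocm: list[ReplicateSummary], euph: list[ReplicateSummary]
) -> StudySummary:
    """Tabulate OCM vs compendial replicate means per formulation.

    Rows are ordered by increasing hardness; the contrast columns report
    the percent change in mean disintegration time from the softest to
    the hardest formulation for each method (omitted when only one
    formulation is present).
    """
    ocm_by_label = {s.formulation: s for s in ocm}
    euph_by_label = {s.formulation: s for s in euph}
    if set(ocm_by_label) != set(euph_by_label):
        raise InvalidInputError(
            "formulation labels differ between methods: "
            f"{sorted(map(str, ocm_by_label))} vs {sorted(map(str, euph_by_label))}"
        )
    labels = sorted(ocm_by_label, key=_hardness_key)
    rows = []
    for lab in labels:
        o, e = ocm_by_label[lab], euph_by_label[lab]
        rows.append(
            {
                "hardness_kp": lab,
                "ocm_mean_s": o.mean_s,
                "ocm_sd_s": o.sd_s,
                "ocm_n": o.n,
                "euph_mean_s": e.mean_s,
                "euph_sd_s": e.sd_s,
                "euph_n": e.n,
            }
        )
    table = pd.DataFrame(rows)
    if len(labels) > 1:
        pc_ocm = percent_change(
            ocm_by_label[labels[0]].mean_s, ocm_by_label[labels[-1]].mean_s
        )
        pc_euph = percent_change(
            euph_by_label[labels[0]].mean_s, euph_by_label[labels[-1]].mean_s
        )
    else:
        pc_ocm = pc_euph = None
    return StudySummary(table=table, percent_change_ocm=pc_ocm,
                        percent_change_euph=pc_euph)
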