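"""From null-model scores to assembly-process labels and summaries.

A sample pair is classified by two thresholded statistics:

* ``|βNTI| > 2``                      → selection (S), a local process
* otherwise ``RC_bray < -0.95``       → homogenizing dispersal (HD, regional)
* otherwise ``RC_bray > 0.95``        → dispersal limitation (DL, regional)
* otherwise                           → drift (D, stochastic)

All inequalities are strict; boundary values fall through to the less
specific process. Aggregation over a set of pairs reports Local = S,
Regional = HD + DL and Stochastic = D percentages. Selection is not split
into its variable (βNTI > 2) and homogeneous (βNTI < -2) flavors — the sign
is kept only for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputFormatError, InvariantViolation
from .io import SampleMetadata

__all__ = [
    "ProcessLabel",
    "ProcessSummary",
    "CascadeDesign",
    "classify_pair",
    "classify_table",
    "connected_pairs",
    "summarize_processes",
    "round_half_away",
]

DEFAULT_BNTI_CUT = 2.0
DEFAULT_RC_CUT = 0.95


class ProcessLabel(str, Enum):
    """The four assembly processes."""

    S = "S"    # selection (local)
    HD = "HD"  # homogenizing dispersal (regional)
    DL = "DL"  # dispersal limitation (regional)
    D = "D"    # drift (stochastic)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_pair(
    bnti: float,
    rc_bray: float | None = None,
    bnti_cut: float = DEFAULT_BNTI_CUT,
    rc_cut: float = DEFAULT_RC_CUT,
) -> ProcessLabel:
    """Map a (βNTI, RC_bray) pair onto its process label.

    ``rc_bray`` may be omitted only when ``|bnti| > bnti_cut`` (the pair is
    already classified as selection). A missing βNTI (degenerate null) is
    treated as non-significant and classified by RC_bray alone.
    """
    if not _is_missing(bnti) and abs(bnti) > bnti_cut:
        return ProcessLabel.S
    if _is_missing(rc_bray):
        raise InputFormatError(
            f"RC_bray required to classify a pair with |βNTI| <= {bnti_cut} "
            f"(βNTI={bnti!r})"
        )
    if not -1.0 - 1e-9 <= rc_bray <= 1.0 + 1e-9:
        raise InvariantViolation(f"RC_bray out of [-1, 1]: {rc_bray}")
    if rc_bray < -rc_cut:
        return ProcessLabel.HD
    if rc_bray > rc_cut:
        return ProcessLabel.DL
    return ProcessLabel.D


def classify_table(
    merged: pd.DataFrame,
    bnti_cut: float = DEFAULT_BNTI_CUT,
    rc_cut: float = DEFAULT_RC_CUT,
) -> pd.DataFrame:
    """Classify every row of a per-pair results frame.

    ``merged`` needs columns ``bnti`` and ``rc_bray`` (the latter may be NaN
    where ``|bnti| > bnti_cut``). Adds a ``process`` column.
    """
    labels = [
        classify_pair(row.bnti, row.rc_bray, bnti_cut=bnti_cut, rc_cut=rc_cut).value
        for row in merged.itertuples()
    ]
    out = merged.copy()
    out["process"] = labels
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ProcessSummary:
    """Counts and Local/Regional/Stochastic percentages over classified pairs."""

    counts: dict[ProcessLabel, int]
    n_pairs: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_pairs = sum(self.counts.values())
        if self.n_pairs == 0:
            raise InputFormatError("cannot summarize an empty label list")

    # raw fractions ---------------------------------------------------------

    @property
    def frac_local(self) -> float:
        return self.counts.get(ProcessLabel.S, 0) / self.n_pairs

    @property
    def frac_regional(self) -> float:
        return (
            self.counts.get(ProcessLabel.HD, 0) + self.counts.get(ProcessLabel.DL, 0)
        ) / self.n_pairs

    @property
    def frac_stochastic(self) -> float:
        return self.counts.get(ProcessLabel.D, 0) / self.n_pairs

    # integer display percentages ------------------------------------------

    @property
    def percent_local(self) -> int:
        return round_half_away(100 * self.frac_local)

    @property
    def percent_regional(self) -> int:
        return round_half_away(100 * self.frac_regional)

    @property
    def percent_stochastic(self) -> int:
        return round_half_away(100 * self.frac_stochastic)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "counts": {k.value: v for k, v in self.counts.items()},
            "frac_local": self.frac_local,
            "frac_regional": self.frac_regional,
            "frac_stochastic": self.frac_stochastic,
            "percent_local": self.percent_local,
            "percent_regional": self.percent_regional,
            "percent_stochastic": self.percent_stochastic,
        }


def summarize_processes(labels: list[ProcessLabel | str]) -> ProcessSummary:
    """Aggregate process labels into Local/Regional/Stochastic percentages."""
    if not labels:
        raise InputFormatError("cannot summarize an empty label list")
    counts: dict[ProcessLabel, int] = {}
    for lab in labels:
        lab = ProcessLabel(lab)
        counts[lab] = counts.get(lab, 0) + 1
    return ProcessSummary(counts)


@dataclass
class CascadeDesign:
    """The ordered reservoir chain and its sampling events per season."""

    reservoirs: tuple[str, ...] = ("BB", "Pr", "NA", "TI")
    events: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "dry": ("D1", "D2", "D3"),
            "rainy": ("R1", "R2", "R3"),
        }
    )

    def __post_init__(self) -> None:
        if len(self.reservoirs) < 2:
            raise InputFormatError("cascade needs at least 2 reservoirs")

    @property
    def adjacent_reservoirs(self) -> list[tuple[str, str]]:
        return list(zip(self.reservoirs[:-1], self.reservoirs[1:]))

    def all_events(self) -> list[str]:
        return [e for evs in self.events.values() for e in evs]

    def season_of(self, event: str) -> str:
        for season, evs in self.events.items():
            if event in evs:
                return season
        raise InputFormatError(f"event {event!r} not in design")


def connected_pairs(
    design: CascadeDesign,
    metadata: SampleMetadata,
    events: list[str] | None = None,
) -> pd.DataFrame:
    """Sample pairs between directly connected reservoirs, one set per event.

    Each (reservoir, event) cell must hold exactly one sample in ``metadata``.
    Returns a DataFrame with columns ``event, season, reservoir_a,
    reservoir_b, sample_a, sample_b`` — for the default 4-reservoir cascade,
    3 pairs per event and 9 per season.
    """
    frame = metadata.frame
    if events is None:
        events = design.all_events()
    lookup: dict[tuple[str, str], str] = {}
    problems = []
    for event in events:
        for res in design.reservoirs:
            hits = frame[(frame["event"] == event) & (frame["reservoir"] == res)]
            if len(hits) == 0:
                problems.append(f"({res}, {event}): no sample")
            elif len(hits) > 1:
                problems.append(f"({res}, {event}): {len(hits)} samples")
            else:
                lookup[(res, event)] = str(hits.index[0])
    if problems:
        raise InputFormatError(
            "cascade design cells without exactly one sample: " + "; ".join(problems)
        )
    rows = [
        (
            event,
            design.season_of(event),
            ra,
            rb,
            lookup[(ra, event)],
            lookup[(rb, event)],
        )
        for event in events
        for ra, rb in design.adjacent_reservoirs
    ]
    return pd.DataFrame(
        rows,
        columns=["event", "season", "reservoir_a", "reservoir_b", "sample_a", "sample_b"],
    )
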