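"""Per-cell marker profiles, the CTC definition, and population tallies.

A segmented object becomes a phenotype: a nuclear-positivity flag plus one
boolean call per panel marker.  The default CTC rule mirrors how filter-
captured cells are counted in practice: an object is a CTC when it is
nuclear-stain-positive AND positive for at least one epithelial cytokeratin
(CK7 or CK20).  Cells that are nuclear-positive and positive for some other
panel marker but cytokeratin-negative (e.g. ER+/CK7- cells, which may have
lost CK7) are tallied in a separate category rather than being classified
either way.

Population fractions are reported as percentages rounded half-up to one
decimal place, the convention used when reporting, say, 15 ER-positive
cells out of 69 CTCs as 21.7%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataIntegrityError, UndefinedFractionError
from .scene import NUCLEAR_CHANNEL

CTC_RULES = ("epithelial", "any-marker")
EPITHELIAL_MARKERS = ("CK7", "CK20")


@dataclass(frozen=True)
class CellPhenotype:
    """Boolean marker profile of one segmented object."""

    roi_label: int
    nuclear_positive: bool
    marker_calls: Mapping[str, bool]
    is_ctc: bool

    def pattern(self, panel: Sequence[str] | None = None) -> str:
        """Human-readable profile string, e.g. ``CK7+/CK20-/TTF-1-/ER+``."""
        markers = panel if panel is not None else self.marker_calls.keys()
        return "/".join(f"{m}{'+' if self.marker_calls[m] else '-'}" for m in markers)


@dataclass
class PopulationSummary:
    """Counts and fractions over one scene's phenotypes.

    ``pattern_counts`` partitions the CTCs by full marker pattern (the
    counts sum to ``n_ctc``); ``non_ctc_pattern_counts`` tallies
    nuclear-positive, non-CTC objects that are positive for at least one
    marker — the "separate category" cells.  ``marker_percent_positive``
    is the percentage of CTCs positive for each marker.
    """

    n_objects: int = 0
    n_nuclear_positive: int = 0
    n_ctc: int = 0
    pattern_counts: dict[str, int] = field(default_factory=dict)
    non_ctc_pattern_counts: dict[str, int] = field(default_factory=dict)
    marker_positive_counts: dict[str, int] = field(default_factory=dict)
    marker_percent_positive: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_objects": self.n_objects,
            "n_nuclear_positive": self.n_nuclear_positive,
            "n_ctc": self.n_ctc,
            "pattern_counts": dict(self.pattern_counts),
            "non_ctc_pattern_counts": dict(self.non_ctc_pattern_counts),
            "marker_positive_counts": dict(self.marker_positive_counts),
            "marker_percent_positive": dict(self.marker_percent_positive),
        }


def percent_positive(k: int, n: int) -> float:
    """Percentage ``100*k/n`` rounded half-up to one decimal place.

    The half-up rule (not banker's rounding) reproduces conventional
    reporting: 15 of 69 -> 21.7, 1 of 16 -> 6.3.
    """
    if n == 0:
        raise UndefinedFractionError("percentage of an empty population is undefined")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    exact = (Decimal(100) * Decimal(k)) / Decimal(n)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assemble_phenotypes(
    measurements: pd.DataFrame,
    panel: Sequence[str],
    ctc_rule: str = "epithelial",
    nuclear_channel: str = NUCLEAR_CHANNEL,
) -> list[CellPhenotype]:
    """Turn a per-cell measurement table into phenotypes.

    ``measurements`` is the wide table produced by
    :func:`ctc_origin.segmentation.measure_scene`; it must carry a
    ``{channel}_positive`` column for the nuclear channel and every panel
    marker, with no missing values.  The ``epithelial`` rule calls a CTC
    when nuclear-positive and CK7-or-CK20-positive; ``any-marker`` widens
    the second condition to any panel marker.
    """
    if ctc_rule not in CTC_RULES:
        raise ValueError(f"ctc_rule must be one of {CTC_RULES}, got {ctc_rule!r}")
    needed = [nuclear_channel, *panel]
    for ch in needed:
        col = f"{ch}_positive"
        if col not in measurements.columns:
            raise DataIntegrityError(
                f"measurement table lacks channel {ch!r} (no column {col!r})"
            )
        bad = measurements[measurements[col].isna()]
        if len(bad):
            roi = bad["roi_label"].iloc[0]
            raise DataIntegrityError(
                f"ROI {roi} is missing a measurement for channel {ch!r}"
            )
    epithelial_in_panel = [m for m in EPITHELIAL_MARKERS if m in panel]
    phenotypes = []
    for _, row in measurements.iterrows():
        nuclear = bool(row[f"{nuclear_channel}_positive"])
        calls = {m: bool(row[f"{m}_positive"]) for m in panel}
        if ctc_rule == "epithelial":
            marker_ok = any(calls[m] for m in epithelial_in_panel)
        else:
            marker_ok = any(calls.values())
        phenotypes.append(
            CellPhenotype(
                roi_label=int(row["roi_label"]),
                nuclear_positive=nuclear,
                marker_calls=calls,
                is_ctc=nuclear and marker_ok,
            )
        )
    return phenotypes


def summarize(phenotypes: Sequence[CellPhenotype]) -> PopulationSummary:
    """Aggregate phenotypes into population counts and fractions.

    Deterministic and invariant to input order.  Per-marker percentages are
    computed among CTCs only and omitted entirely when there are no CTCs.
    """
    summary = PopulationSummary(n_objects=len(phenotypes))
    if not phenotypes:
        return summary
    panel = list(phenotypes[0].marker_calls.keys())
    for ph in phenotypes:
        if list(ph.marker_calls.keys()) != panel:
            raise DataIntegrityError("phenotypes mix different marker panels")
    ctc_patterns: Counter[str] = Counter()
    other_patterns: Counter[str] = Counter()
    marker_counts = {m: 0 for m in panel}
    for ph in phenotypes:
        summary.n_nuclear_positive += int(ph.nuclear_positive)
        if ph.is_ctc:
            summary.n_ctc += 1
            ctc_patterns[ph.pattern(panel)] += 1
            for m in panel:
                marker_counts[m] += int(ph.marker_calls[m])
        elif ph.nuclear_positive and any(ph.marker_calls.values()):
            other_patterns[ph.pattern(panel)] += 1
    summary.pattern_counts = dict(sorted(ctc_patterns.items()))
    summary.non_ctc_pattern_counts = dict(sorted(other_patterns.items()))
    if summary.n_ctc > 0:
        summary.marker_positive_counts = marker_counts
        summary.marker_percent_positive = {
            m: percent_positive(marker_counts[m], summary.n_ctc) for m in panel
        }
    return summary


def phenotypes_to_frame(phenotypes: Sequence[CellPhenotype]) -> pd.DataFrame:
    """Phenotypes as a flat table (CSV interchange for the classify stage)."""
    rows = []
    for ph in phenotypes:
        row = {"roi_label": ph.roi_label, "nuclear_positive": int(ph.nuclear_positive)}
        for m, call in ph.marker_calls.items():
            row[m] = int(call)
        row["is_ctc"] = int(ph.is_ctc)
        rows.append(row)
    return pd.DataFrame(rows)


def phenotypes_from_frame(frame: pd.DataFrame, panel: Sequence[str]) -> list[CellPhenotype]:
    """Inverse of :func:`phenotypes_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        out.append(
            CellPhenotype(
                roi_label=int(row["roi_label"]),
                nuclear_positive=bool(row["nuclear_positive"]),
                marker_calls={m: bool(row[m]) for m in panel},
                is_ctc=bool(row["is_ctc"]),
            )
        )
    return out
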