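"""Marker positivity frequency tables.

The tissue-of-origin classifier rests on a table of per-tissue marker
positivity frequencies: for each candidate primary site (prostate, breast,
colon, lung, ...) and each immunofluorescence marker (CK7, CK20, TTF-1, ER,
PSA, ...), the probability that a carcinoma of that origin stains positive.
Such frequencies are standard pathology knowledge (CK7/CK20 coordinate
patterns, TTF-1 for lung, PSA for prostate, ER for breast/ovary), but exact
values vary across cohorts and antibodies, so the table is a required,
user-editable configuration.  The defaults bundled here are illustrative
values consistent with the standard qualitative orderings:

* TTF-1 is most frequent in lung among the four tissues;
* PSA is most frequent in prostate;
* ER is more frequent in breast than in colon;
* colon is CK20-dominant (CK20 frequency exceeds its CK7 frequency).

They are not measurements and should be replaced with cohort-specific
estimates for any real application.

Probabilities used by the likelihood are clipped into ``[eps, 1 - eps]`` so
that a single discordant cell (e.g. a CK7-positive prostate CTC, which does
occur) cannot drive a tissue's likelihood to exactly zero.  The raw,
unclipped values are retained for simulation, where a frequency of 1.0 must
mean "every cell positive".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Markers restricted to one patient sex.  ER is scored only in female
#: contexts, PSA only in male contexts; the remaining markers are shared.
SEX_APPLICABILITY: dict[str, str] = {"ER": "female", "PSA": "male"}

#: Canonical marker spellings accepted in tables and panels.
KNOWN_MARKERS = ("CK7", "CK20", "TTF-1", "ER", "PSA", "AFP", "CEA")

DEFAULT_TISSUES = ("prostate", "breast", "colon", "lung")
DEFAULT_MARKERS = ("CK7", "CK20", "TTF-1", "ER", "PSA")

# Illustrative defaults (see module docstring); rows are tissues.
_DEFAULT_PROBABILITIES: dict[str, dict[str, float]] = {
    "prostate": {"CK7": 0.10, "CK20": 0.05, "TTF-1": 0.01, "ER": 0.01, "PSA": 0.95},
    "breast":   {"CK7": 0.90, "CK20": 0.05, "TTF-1": 0.02, "ER": 0.70, "PSA": 0.01},
    "colon":    {"CK7": 0.10, "CK20": 0.85, "TTF-1": 0.01, "ER": 0.02, "PSA": 0.01},
    "lung":     {"CK7": 0.90, "CK20": 0.10, "TTF-1": 0.80, "ER": 0.05, "PSA": 0.01},
}


def panel_for_sex(sex: str) -> tuple[str, ...]:
    """Minimal marker panel for a patient sex: CK7, CK20, TTF-1 plus ER
    (female) or PSA (male)."""
    if sex == "female":
        return ("CK7", "CK20", "TTF-1", "ER")
    if sex == "male":
        return ("CK7", "CK20", "TTF-1", "PSA")
    raise ConfigurationError(f"sex must be 'female' or 'male', got {sex!r}")


@dataclass(frozen=True)
class FrequencyTable:
    """Tissue x marker positivity probabilities.

    Attributes
    ----------
    tissues, markers
        Ordered labels; tissue order is the deterministic tie-break order
        for classification.
    raw
        Probabilities exactly as supplied (used by the scene simulator).
    p
        Probabilities clipped into ``[eps, 1 - eps]`` (used by the
        likelihood).
    eps
        Clipping constant in ``(0, 0.5)``.
    """

    tissues: tuple[str, ...]
    markers: tuple[str, ...]
    raw: Mapping[str, Mapping[str, float]]
    eps: float = 0.01
    p: Mapping[str, Mapping[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        errors: list[str] = []
        if not 0.0 < self.eps < 0.5:
            errors.append(f"eps must lie in (0, 0.5), got {self.eps}")
        for m in self.markers:
            if m not in KNOWN_MARKERS:
                errors.append(
                    f"unknown marker {m!r}; known markers: {', '.join(KNOWN_MARKERS)}"
                )
        for t in self.tissues:
            row = self.raw.get(t)
            if row is None:
                errors.append(f"missing probability row for tissue {t!r}")
                continue
            for m in self.markers:
                if m not in row:
                    errors.append(f"missing probability for (tissue={t!r}, marker={m!r})")
                    continue
                v = row[m]
                if not 0.0 <= v <= 1.0:
                    errors.append(
                        f"probability for (tissue={t!r}, marker={m!r}) outside [0, 1]: {v}"
                    )
        if errors:
            raise ConfigurationError(
                "invalid frequency table:\n  " + "\n  ".join(errors)
            )
        clipped = {
            t: {
                m: min(max(float(self.raw[t][m]), self.eps), 1.0 - self.eps)
                for m in self.markers
            }
            for t in self.tissues
        }
        object.__setattr__(self, "p", clipped)

    def probability(self, tissue: str, marker: str) -> float:
        """Clipped positivity probability, for likelihood evaluation."""
        self._check(tissue, marker)
        return self.p[tissue][marker]

    def raw_probability(self, tissue: str, marker: str) -> float:
        """Unclipped positivity probability, for simulation."""
        self._check(tissue, marker)
        return float(self.raw[tissue][marker])

    def _check(self, tissue: str, marker: str) -> None:
        if tissue not in self.tissues:
            raise ConfigurationError(
                f"unknown tissue {tissue!r}; table tissues: {', '.join(self.tissues)}"
            )
        if marker not in self.markers:
            raise ConfigurationError(
                f"unknown marker {marker!r}; table markers: {', '.join(self.markers)}"
            )

    def sex_for_marker(self, marker: str) -> str | None:
        """Return the sex a marker is restricted to, or None if unrestricted."""
        return SEX_APPLICABILITY.get(marker)

    def to_dict(self) -> dict:
        return {
            "tissues": list(self.tissues),
            "markers": list(self.markers),
            "probabilities": {t: dict(self.raw[t]) for t in self.tissues},
            "eps": self.eps,
        }


def default_frequency_table(eps: float = 0.01) -> FrequencyTable:
    """The bundled illustrative table over prostate/breast/colon/lung."""
    return FrequencyTable(
        tissues=DEFAULT_TISSUES,
        markers=DEFAULT_MARKERS,
        raw={t: dict(row) for t, row in _DEFAULT_PROBABILITIES.items()},
        eps=eps,
    )


def load_frequency_table(document: Mapping | str | Path) -> FrequencyTable:
    """Load a frequency table from a mapping or a YAML/JSON file path.

    The schema is ``{tissues: [...], markers: [...], probabilities:
    {tissue: {marker: p}}, eps: float}``.  Validation problems are
    aggregated into a single :class:`ConfigurationError` naming every
    offending entry.
    """
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            document = yaml.safe_load(fh)
    if not isinstance(document, Mapping):
        raise ConfigurationError("frequency table document must be a mapping")
    missing = [k for k in ("tissues", "markers", "probabilities") if k not in document]
    if missing:
        raise ConfigurationError(
            f"frequency table document missing keys: {', '.join(missing)}"
        )
    return FrequencyTable(
        tissues=tuple(document["tissues"]),
        markers=tuple(document["markers"]),
        raw={t: dict(row) for t, row in document["probabilities"].items()},
        eps=float(document.get("eps", 0.01)),
    )
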