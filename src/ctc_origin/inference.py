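"""Tissue-of-origin inference from CTC marker profiles.

The model treats each cell's panel calls as independent Bernoulli draws
whose success probabilities are the frequency table's per-tissue marker
positivity frequencies (only marginal frequencies are available, so no
dependence between markers within a cell is modelled).  For a candidate
tissue ``t`` and a cell with calls ``x_m`` over panel markers ``m``:

    log L_cell(t) = sum_m [ x_m * log p(t, m) + (1 - x_m) * log(1 - p(t, m)) ]

Over a population the per-marker positive counts are sufficient: with
``k_m`` positives among ``n`` cells,

    log L(t) = sum_m [ k_m * log p(t, m) + (n - k_m) * log(1 - p(t, m)) ]

which is the binomial kernel per marker.  Both forms are implemented and
must agree; the population form is what runs.  The posterior is prior times
likelihood, normalised in log space.  A call is issued when the posterior
margin (top minus next-best tissue) reaches a configurable threshold,
otherwise the result is "indeterminate" — an abstention mirroring how a
poorly differentiated tumor can defeat marker-based diagnosis.

Probabilities come pre-clipped away from 0 and 1 by the frequency table, so
one discordant cell shifts, but can never zero, a tissue's likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError
from .frequency import SEX_APPLICABILITY, FrequencyTable
from .phenotyping import CellPhenotype

INDETERMINATE = "indeterminate"

#: Default posterior-margin threshold for issuing a call.
DEFAULT_CALL_MARGIN = 0.10

_TIE_ATOL = 1e-12


@dataclass
class OriginPosterior:
    """Posterior over candidate primary sites for one CTC population."""

    log_likelihood: dict[str, float]
    prior: dict[str, float]
    posterior: dict[str, float]
    call: str
    margin: float
    n_cells_used: int
    tie: bool = False
    reason: str | None = None
    marker_positive_counts: dict[str, int] = field(default_factory=dict)

    def top(self, k: int = 2) -> list[tuple[str, float]]:
        return sorted(self.posterior.items(), key=lambda kv: -kv[1])[:k]

    def to_dict(self) -> dict:
        return {
            "log_likelihood": dict(self.log_likelihood),
            "prior": dict(self.prior),
            "posterior": dict(self.posterior),
            "call": self.call,
            "margin": self.margin,
            "n_cells_used": self.n_cells_used,
            "tie": self.tie,
            "reason": self.reason,
            "marker_positive_counts": dict(self.marker_positive_counts),
        }


def _validate_panel(markers: Sequence[str], table: FrequencyTable, sex: str | None) -> None:
    restricted = {m: SEX_APPLICABILITY[m] for m in markers if m in SEX_APPLICABILITY}
    if len(set(restricted.values())) > 1:
        raise ConfigurationError(
            f"panel mixes sex-restricted markers {sorted(restricted)}; "
            "ER is female-only and PSA male-only"
        )
    if sex is not None:
        for m, required in restricted.items():
            if required != sex:
                raise ConfigurationError(
                    f"marker {m!r} is {required}-only but the context sex is {sex!r}"
                )
    for m in markers:
        if m not in table.markers:
            raise ConfigurationError(
                f"marker {m!r} not in frequency table (markers: {', '.join(table.markers)})"
            )


def cell_log_likelihood(
    phenotype: CellPhenotype,
    tissue: str,
    table: FrequencyTable,
    sex: str | None = None,
) -> float:
    """Log-likelihood of one cell's marker calls under one tissue."""
    markers = list(phenotype.marker_calls.keys())
    _validate_panel(markers, table, sex)
    total = 0.0
    for m in markers:
        p = table.probability(tissue, m)
        total += np.log(p) if phenotype.marker_calls[m] else np.log1p(-p)
    return float(total)


def binomial_log_likelihood(
    positive_counts: Mapping[str, int],
    n_cells: int,
    tissue: str,
    table: FrequencyTable,
) -> float:
    """Population log-likelihood from per-marker positive counts.

    The counts are sufficient statistics under marker independence, so this
    must equal the sum of per-cell log-likelihoods (the binomial choose
    factor is constant across tissues and omitted).
    """
    total = 0.0
    for m, k in positive_counts.items():
        if not 0 <= k <= n_cells:
            raise ValueError(f"count for {m!r} outside [0, n]: {k}")
        p = table.probability(tissue, m)
        total += k * np.log(p) + (n_cells - k) * np.log1p(-p)
    return float(total)


def _uniform_prior(tissues: Sequence[str]) -> dict[str, float]:
    return {t: 1.0 / len(tissues) for t in tissues}


def _resolve_prior(
    prior: Mapping[str, float] | str | None, tissues: Sequence[str]
) -> dict[str, float]:
    if prior is None or prior == "uniform":
        return _uniform_prior(tissues)
    if isinstance(prior, str):
        raise ConfigurationError(f"unknown prior spec {prior!r}")
    missing = [t for t in tissues if t not in prior]
    if missing:
        raise ConfigurationError(f"prior missing tissues: {missing}")
    total = float(sum(prior[t] for t in tissues))
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError(f"prior must sum to 1, got {total}")
    if any(prior[t] < 0 for t in tissues):
        raise ConfigurationError("prior probabilities must be non-negative")
    return {t: float(prior[t]) / total for t in tissues}


def classify(
    posterior: Mapping[str, float],
    call_margin: float = DEFAULT_CALL_MARGIN,
    tissue_order: Sequence[str] | None = None,
) -> tuple[str, float, bool]:
    """Turn a normalised posterior into a call.

    Returns ``(call, margin, tie)``.  The margin is the gap between the top
    posterior and the next *distinct* posterior value; a call is issued
    when it reaches ``call_margin``, else ``"indeterminate"``.  Exact ties
    at the top are broken deterministically by tissue order and flagged.
    An all-uniform posterior has zero margin and is always indeterminate
    for any positive ``call_margin``.
    """
    order = list(tissue_order) if tissue_order is not None else list(posterior)
    values = np.array([posterior[t] for t in order], dtype=float)
    top_value = values.max()
    tied = np.isclose(values, top_value, rtol=0.0, atol=_TIE_ATOL)
    tie = bool(tied.sum() > 1)
    call = order[int(np.argmax(tied))]  # first tissue in canonical order
    below = values[~tied]
    margin = float(top_value - below.max()) if below.size else 0.0
    if margin < call_margin:
        return INDETERMINATE, margin, tie
    return call, margin, tie


def population_posterior(
    phenotypes: Sequence[CellPhenotype],
    table: FrequencyTable,
    prior: Mapping[str, float] | str | None = None,
    use_ctc_only: bool = True,
    call_margin: float = DEFAULT_CALL_MARGIN,
    sex: str | None = None,
) -> OriginPosterior:
    """Posterior over tissues for a cell population.

    Cells failing the CTC filter are excluded when ``use_ctc_only`` (the
    default), so cytokeratin-negative bystanders do not vote.  An empty
    population after filtering yields an indeterminate result with a stated
    reason rather than an error, matching how a run with no evaluable CTCs
    should be reported.
    """
    tissues = list(table.tissues)
    prior_map = _resolve_prior(prior, tissues)
    cells = [ph for ph in phenotypes if ph.is_ctc] if use_ctc_only else list(phenotypes)
    if not cells:
        reason = (
            "no cells passed the CTC filter" if phenotypes else "no cells supplied"
        )
        return OriginPosterior(
            log_likelihood={t: 0.0 for t in tissues},
            prior=prior_map,
            posterior=dict(prior_map),
            call=INDETERMINATE,
            margin=0.0,
            n_cells_used=0,
            reason=reason,
        )
    panel = list(cells[0].marker_calls.keys())
    for ph in cells:
        if list(ph.marker_calls.keys()) != panel:
            raise ConfigurationError("cells mix different marker panels")
    _validate_panel(panel, table, sex)
    n = len(cells)
    counts = {m: sum(int(ph.marker_calls[m]) for ph in cells) for m in panel}
    loglik = {t: binomial_log_likelihood(counts, n, t, table) for t in tissues}
    log_post = np.array(
        [np.log(prior_map[t]) + loglik[t] if prior_map[t] > 0 else -np.inf for t in tissues]
    )
    log_post -= logsumexp(log_post)
    posterior = {t: float(np.exp(v)) for t, v in zip(tissues, log_post)}
    call, margin, tie = classify(posterior, call_margin, tissues)
    return OriginPosterior(
        log_likelihood=loglik,
        prior=prior_map,
        posterior=posterior,
        call=call,
        margin=margin,
        n_cells_used=n,
        tie=tie,
        marker_positive_counts=counts,
    )
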