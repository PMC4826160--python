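"""Synthetic immunofluorescence scenes of filter-captured CTCs.

The generator emulates what size-based CTC enrichment (microfiltration of
whole blood) followed by multiplexed immunofluorescence yields: a field of
nucleated cells on a flat background, imaged in one nuclear channel
(Hoechst/DAPI) and the sex-appropriate marker panel (CK7, CK20, TTF-1 and
ER for female or PSA for male contexts).  Tumor cells draw their per-marker
positivity independently from a tissue-specific frequency table; leukocyte
contaminants are nucleated but negative for every marker.

Cells are rendered as uniform-intensity disks with a one-pixel
Gaussian-blurred edge, which keeps every downstream quantity (areas,
centroids, mean intensities, fold ratios) analytically recoverable from the
ground-truth record.  Positive cells receive a log-normal peak intensity;
in quantum-dot mode, marker-negative cells leak a configurable fraction of
a foreground draw into the marker channel, emulating the non-specific
binding characteristic of Q-dot-conjugated antibodies (organic-dye
"dylight" mode leaks nothing).  A constant background plane plus additive
Gaussian read noise completes the image.  With some probability a cell is
placed overlapping an earlier cell, forming a clump; clumps are what make
connected-component segmentation undercount, and the ground truth records
them so tests can assert exactly that behavior.

Every random draw flows from a single integer seed, so identical
configurations produce bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .errors import ConfigurationError, GenerationError
from .frequency import FrequencyTable, panel_for_sex

NUCLEAR_CHANNEL = "nuclear"

#: Edge softness of rendered disks, in pixels (sigma of the blurred step).
EDGE_SIGMA = 1.0

#: Default non-specific leak fraction per fluorophore chemistry.
MODE_NONSPECIFIC = {"qdot": 0.15, "dylight": 0.0}

_PLACEMENT_RETRIES = 200

#: Radius floor, micrometers: cells smaller than the ~7 um pore of a
#: microfiltration device pass through and are never captured, so radius
#: draws are truncated here.  This also keeps every rendered cell above the
#: default segmentation area filter at the default pixel size.
MIN_RADIUS_UM = 3.5


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Lengths are micrometers; ``pixel_size`` converts to pixels.  Intensity
    units are arbitrary but shared by foreground, background and noise.
    ``foreground_log_mean``/``foreground_log_sd`` may be scalars (applied
    to every channel, nuclear included) or per-channel mappings.
    """

    image_height: int = 512
    image_width: int = 512
    pixel_size: float = 1.0
    n_tumor_cells: int = 50
    n_leukocytes: int = 20
    tissue_type: str = "breast"
    sex: str = "female"
    cell_radius_mean: float = 8.0
    cell_radius_sd: float = 1.5
    leukocyte_radius_factor: float = 0.6
    foreground_log_mean: float | Mapping[str, float] = 5.7
    foreground_log_sd: float | Mapping[str, float] = 0.25
    background_level: float = 100.0
    noise_sd: float = 5.0
    mode: str = "qdot"
    nonspecific_fraction: float | None = None
    clump_probability: float = 0.1
    frequency_overrides: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_tumor_cells < 0 or self.n_leukocytes < 0:
            errors.append("cell counts must be >= 0")
        if self.cell_radius_mean <= 0 or self.pixel_size <= 0:
            errors.append("radii and pixel size must be > 0")
        if self.sex not in ("female", "male"):
            errors.append(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.mode not in MODE_NONSPECIFIC:
            errors.append(f"mode must be one of {sorted(MODE_NONSPECIFIC)}, got {self.mode!r}")
        nsf = self.resolved_nonspecific_fraction()
        if not 0.0 <= nsf < 1.0:
            errors.append(f"nonspecific_fraction must lie in [0, 1), got {nsf}")
        if not 0.0 <= self.clump_probability <= 1.0:
            errors.append(f"clump_probability must lie in [0, 1], got {self.clump_probability}")
        if self.noise_sd < 0 or self.background_level < 0:
            errors.append("background_level and noise_sd must be >= 0")
        if errors:
            raise ConfigurationError("invalid scene config:\n  " + "\n  ".join(errors))

    def resolved_nonspecific_fraction(self) -> float:
        if self.nonspecific_fraction is not None:
            return float(self.nonspecific_fraction)
        return MODE_NONSPECIFIC.get(self.mode, 0.0)

    @property
    def panel(self) -> tuple[str, ...]:
        return panel_for_sex(self.sex)

    @property
    def channels(self) -> tuple[str, ...]:
        return (NUCLEAR_CHANNEL,) + self.panel

    def log_params(self, channel: str) -> tuple[float, float]:
        """(log-mean, log-sd) of the foreground intensity for a channel."""
        mu = self.foreground_log_mean
        sd = self.foreground_log_sd
        mu_c = float(mu[channel]) if isinstance(mu, Mapping) else float(mu)
        sd_c = float(sd[channel]) if isinstance(sd, Mapping) else float(sd)
        return mu_c, sd_c

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["foreground_log_mean"], Mapping):
            d["foreground_log_mean"] = dict(d["foreground_log_mean"])
        if isinstance(d["foreground_log_sd"], Mapping):
            d["foreground_log_sd"] = dict(d["foreground_log_sd"])
        if d["frequency_overrides"] is not None:
            d["frequency_overrides"] = dict(d["frequency_overrides"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scene config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticCell:
    """Ground-truth record of one rendered cell (positions in pixels)."""

    id: int
    center_row: float
    center_col: float
    radius: float
    kind: str  # "tumor" | "leukocyte"
    true_marker_states: dict[str, bool]
    true_channel_intensity: dict[str, float]
    clump_group: int | None = None


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene."""

    cells: list[SyntheticCell]
    config: SceneConfig
    marker_positive_counts: dict[str, int] = field(default_factory=dict)
    n_tumor_cells: int = 0

    def recompute_counts(self) -> tuple[dict[str, int], int]:
        """Recount positives from the cells list (consistency oracle)."""
        counts = {m: 0 for m in self.config.panel}
        n_tumor = 0
        for cell in self.cells:
            if cell.kind == "tumor":
                n_tumor += 1
            for m, state in cell.true_marker_states.items():
                counts[m] += int(state)
        return counts, n_tumor

    def validate(self) -> None:
        counts, n_tumor = self.recompute_counts()
        if counts != self.marker_positive_counts or n_tumor != self.n_tumor_cells:
            raise GenerationError("ground truth counts inconsistent with cells list")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "id": c.id,
                "center_row": c.center_row,
                "center_col": c.center_col,
                "radius": c.radius,
                "kind": c.kind,
                "clump_group": -1 if c.clump_group is None else c.clump_group,
            }
            for m, state in c.true_marker_states.items():
                row[f"{m}_state"] = int(state)
            rows.append(row)
        columns = ["id", "center_row", "center_col", "radius", "kind", "clump_group"] + [
            f"{m}_state" for m in self.config.panel
        ]
        return pd.DataFrame(rows, columns=columns)


def sample_marker_states(
    tissue: str,
    freq_table: FrequencyTable,
    n: int,
    seed: int,
    markers: Sequence[str] | None = None,
    overrides: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-cell marker positivity for ``n`` tumor cells of one tissue.

    Each cell's state for marker ``m`` is an independent Bernoulli draw with
    the table's *raw* (unclipped) frequency for ``(tissue, m)``, so a
    configured frequency of 1.0 yields all-positive draws.  ``overrides``
    replaces individual marker frequencies, which is how heterogeneity
    scenarios (e.g. a partially ER-positive breast population) are set up.

    Returns a boolean DataFrame with one row per cell, one column per
    marker; deterministic given ``seed``.
    """
    if tissue not in freq_table.tissues:
        raise ConfigurationError(
            f"unknown tissue {tissue!r}; table tissues: {', '.join(freq_table.tissues)}"
        )
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    markers = tuple(markers) if markers is not None else freq_table.markers
    rng = np.random.default_rng(seed)
    return _sample_states(rng, tissue, freq_table, n, markers, overrides)


def _sample_states(
    rng: np.random.Generator,
    tissue: str,
    freq_table: FrequencyTable,
    n: int,
    markers: Sequence[str],
    overrides: Mapping[str, float] | None,
) -> pd.DataFrame:
    overrides = overrides or {}
    probs = []
    for m in markers:
        p = overrides.get(m, freq_table.raw_probability(tissue, m))
        if not 0.0 <= float(p) <= 1.0:
            raise ConfigurationError(f"override for {m!r} outside [0, 1]: {p}")
        probs.append(float(p))
    draws = rng.random((n, len(markers))) < np.asarray(probs)[None, :]
    return pd.DataFrame(draws, columns=list(markers))


def _place_cells(
    rng: np.random.Generator, config: SceneConfig
) -> list[tuple[float, float, float, str, int | None]]:
    """Sample (row, col, radius_px, kind, clump_group) for every cell.

    Non-clumped cells are rejection-sampled to avoid overlap; clumped cells
    deliberately overlap a previously placed cell by 30-60% of their own
    radius and share its clump group.
    """
    h, w = config.image_height, config.image_width
    specs: list[tuple[str, float]] = []
    for _ in range(config.n_tumor_cells):
        r_um = max(MIN_RADIUS_UM, rng.normal(config.cell_radius_mean, config.cell_radius_sd))
        specs.append(("tumor", r_um / config.pixel_size))
    for _ in range(config.n_leukocytes):
        f = config.leukocyte_radius_factor
        r_um = max(
            MIN_RADIUS_UM,
            rng.normal(config.cell_radius_mean * f, config.cell_radius_sd * f),
        )
        specs.append(("leukocyte", r_um / config.pixel_size))

    placed: list[tuple[float, float, float, str, int | None]] = []
    next_group = 0
    for i, (kind, radius) in enumerate(specs):
        margin = radius + 3.0
        if margin * 2 >= min(h, w):
            raise GenerationError(
                f"cell radius {radius:.1f}px does not fit a {h}x{w} image; placed {i} of {len(specs)}"
            )
        clump = len(placed) > 0 and rng.random() < config.clump_probability
        ok = False
        for _ in range(_PLACEMENT_RETRIES):
            if clump:
                j = int(rng.integers(len(placed)))
                pr, pc, prad, _, pgroup = placed[j]
                overlap = rng.uniform(0.3, 0.6) * radius
                dist = prad + radius - overlap
                theta = rng.uniform(0.0, 2.0 * np.pi)
                r0 = pr + dist * np.sin(theta)
                c0 = pc + dist * np.cos(theta)
                if not (margin <= r0 <= h - margin and margin <= c0 <= w - margin):
                    continue
                if pgroup is None:
                    pgroup = next_group
                    next_group += 1
                    placed[j] = (pr, pc, prad, placed[j][3], pgroup)
                placed.append((r0, c0, radius, kind, pgroup))
                ok = True
                break
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if all(
                np.hypot(r0 - pr, c0 - pc) > radius + prad + 2.0
                for pr, pc, prad, _, _ in placed
            ):
                placed.append((r0, c0, radius, kind, None))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place cell {i} within bounds after {_PLACEMENT_RETRIES} retries; "
                f"placed {len(placed)} of {len(specs)} cells"
            )
    return placed


def render_cells(
    cells: Sequence[SyntheticCell], config: SceneConfig, noise_seed: int | None = None
) -> dict[str, np.ndarray]:
    """Render ground-truth cells into one image per channel.

    Each cell contributes a disk of its true channel intensity with a
    Gaussian-blurred edge; overlapping disks combine by maximum, so a clump
    reads as a plateau rather than a doubled-intensity hot spot.  Background
    and Gaussian read noise are then added and the result floored at zero.
    Exposed separately from :func:`generate_scene` so tests can render
    hand-constructed geometries.
    """
    h, w = config.image_height, config.image_width
    images = {ch: np.zeros((h, w), dtype=np.float64) for ch in config.channels}
    for cell in cells:
        lo_r = max(0, int(np.floor(cell.center_row - cell.radius - 4)))
        hi_r = min(h, int(np.ceil(cell.center_row + cell.radius + 5)))
        lo_c = max(0, int(np.floor(cell.center_col - cell.radius - 4)))
        hi_c = min(w, int(np.ceil(cell.center_col + cell.radius + 5)))
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist = np.hypot(rr - cell.center_row, cc - cell.center_col)
        profile = 0.5 * (1.0 + erf((cell.radius - dist) / (EDGE_SIGMA * np.sqrt(2.0))))
        for ch, peak in cell.true_channel_intensity.items():
            if peak > 0:
                patch = images[ch][lo_r:hi_r, lo_c:hi_c]
                np.maximum(patch, peak * profile, out=patch)
    rng = np.random.default_rng(config.seed if noise_seed is None else noise_seed)
    for ch in config.channels:
        img = images[ch] + config.background_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        images[ch] = np.maximum(img, 0.0)
    return images


def generate_scene(
    config: SceneConfig, freq_table: FrequencyTable
) -> tuple[dict[str, np.ndarray], SceneGroundTruth]:
    """Generate one multi-channel scene and its ground truth.

    Returns ``(images, truth)`` where ``images`` maps channel name (nuclear
    first, then the sex-appropriate panel) to a float image.  Deterministic
    given ``config.seed``.
    """
    if config.tissue_type not in freq_table.tissues:
        raise ConfigurationError(
            f"unknown tissue {config.tissue_type!r}; table tissues: "
            f"{', '.join(freq_table.tissues)}"
        )
    for m in config.panel:
        freq_table.probability(config.tissue_type, m)  # raises if panel not covered
    rng = np.random.default_rng(config.seed)
    placed = _place_cells(rng, config)
    states = _sample_states(
        rng, config.tissue_type, freq_table, config.n_tumor_cells, config.panel,
        config.frequency_overrides,
    )
    nsf = config.resolved_nonspecific_fraction()

    cells: list[SyntheticCell] = []
    tumor_idx = 0
    for i, (r0, c0, radius, kind, group) in enumerate(placed):
        if kind == "tumor":
            marker_states = {m: bool(states.iloc[tumor_idx][m]) for m in config.panel}
            tumor_idx += 1
        else:
            marker_states = {m: False for m in config.panel}
        intensity: dict[str, float] = {}
        for ch in config.channels:
            mu, sd = config.log_params(ch)
            draw = float(rng.lognormal(mu, sd))
            if ch == NUCLEAR_CHANNEL:
                intensity[ch] = draw  # every nucleated cell stains
            else:
                intensity[ch] = draw if marker_states[ch] else draw * nsf
        cells.append(
            SyntheticCell(
                id=i, center_row=r0, center_col=c0, radius=radius, kind=kind,
                true_marker_states=marker_states, true_channel_intensity=intensity,
                clump_group=group,
            )
        )

    noise_seed = int(rng.integers(0, 2**31 - 1))
    images = render_cells(cells, config, noise_seed=noise_seed)

    truth = SceneGroundTruth(cells=cells, config=config)
    truth.marker_positive_counts, truth.n_tumor_cells = truth.recompute_counts()
    return images, truth


# ---------------------------------------------------------------------------
# Disk I/O: multi-page TIFF + JSON sidecar + ground-truth CSV
# ---------------------------------------------------------------------------

def write_scene(
    images: Mapping[str, np.ndarray],
    truth: SceneGroundTruth,
    directory: str | Path,
) -> Path:
    """Write a scene to ``directory``.

    Layout: ``scene.tif`` (one 16-bit page per channel), ``channels.json``
    (channel order, marker mapping and the float->uint16 intensity scale),
    ``ground_truth.csv`` (one row per cell) and ``config.json``.  Float
    intensities are scaled by a single factor chosen so the global maximum
    maps to 65535; the factor is recorded in the sidecar and undone on read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = list(truth.config.channels)
    stack = np.stack([images[ch] for ch in channels])
    peak = float(stack.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(directory / "scene.tif", (stack * scale).round().astype(np.uint16))
    sidecar = {
        "channels": channels,
        "nuclear_channel": NUCLEAR_CHANNEL,
        "intensity_scale": scale,
        "sex": truth.config.sex,
    }
    (directory / "channels.json").write_text(json.dumps(sidecar, indent=2))
    truth.to_frame().to_csv(directory / "ground_truth.csv", index=False)
    (directory / "config.json").write_text(json.dumps(truth.config.to_dict(), indent=2))
    return directory


def read_scene(directory: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a scene directory written by :func:`write_scene` (or real data
    laid out the same way).  Returns ``(images, sidecar)`` with intensities
    rescaled back to float units."""
    directory = Path(directory)
    sidecar = json.loads((directory / "channels.json").read_text())
    stack = tifffile.imread(directory / "scene.tif").astype(np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    scale = float(sidecar.get("intensity_scale", 1.0))
    images = {ch: stack[i] / scale for i, ch in enumerate(sidecar["channels"])}
    return images, sidecar
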