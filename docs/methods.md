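# Methods

## The classification model

Each candidate primary site *t* (prostate, breast, colon, lung by default)
is characterised by marginal marker-positivity frequencies *p(t, m)* for
the panel markers *m* ∈ {CK7, CK20, TTF-1, ER or PSA}. A cell's observed
calls are modelled as independent Bernoulli draws with those frequencies;
across a population of *n* evaluable cells the per-marker positive counts
*k<sub>m</sub>* are sufficient statistics, giving the binomial log-likelihood

log L(t) = Σ<sub>m</sub> [ k<sub>m</sub> log p(t, m) + (n − k<sub>m</sub>) log(1 − p(t, m)) ].

Both the per-cell-sum and binomial-count forms are implemented
(`cell_log_likelihood`, `binomial_log_likelihood`) and tested for exact
agreement. The posterior over tissues is prior × likelihood, normalised
via log-sum-exp. Independence across markers is an assumption forced by
the data: only marginal frequencies are available, so no within-cell
dependence structure is estimable. Independence across cells ignores the
clonal structure of a real tumor; with it, posteriors concentrate faster
than they should, which is why the posterior itself — not just the call —
is always reported.

**Clipping.** Table probabilities are clipped into [ε, 1−ε], ε = 0.01 by
default, so a single discordant cell (e.g. a CK7-positive prostate cell,
which occurs at low frequency) can never zero out a tissue. The raw,
unclipped values are kept alongside and used by the simulator, where a
configured frequency of 1.0 must mean literally every cell.

**Calls and abstention.** The call is the posterior argmax when the margin
— top posterior minus the next *distinct* posterior value — reaches
`call_margin` (default 0.10); otherwise "indeterminate". Defining the
margin against the next distinct value makes an exact top tie break
deterministically by tissue order (with a `tie` flag in the output) while
an all-uniform posterior has zero margin and always abstains. Abstention
acknowledges that some tumors are too poorly differentiated for a
marker-based call.

**Sex gating.** ER is scored only in female contexts and PSA only in male
ones; a panel mixing them, or contradicting the declared patient sex, is a
validation error rather than a silent skip.

**Which cells vote.** Enumeration and classification use different filters
on purpose. A CTC is counted under the conventional strict rule
(nuclear-positive plus CK7-or-CK20). The classifier, by default, votes
every nucleated cell positive for at least one panel marker
(`classify_cells: marker_positive`). Restricting the likelihood to
epithelial-rule CTCs would condition on CK7/CK20 status and systematically
bias the evidence for mostly cytokeratin-negative tumors (prostate retains
~14% of its cells under the strict rule, a biased subset); conversely,
including fully marker-negative objects would let leukocyte contaminants
vote for whichever tissues have uniformly low frequencies. Both
alternatives remain available (`ctc`, `all`).

**The frequency table.** Exact positivity percentages vary by cohort and
antibody, so the table is required configuration with a clearly illustrative
default. The default encodes the standard qualitative orderings — TTF-1
maximal in lung, PSA maximal in prostate, ER higher in breast than colon,
colon CK20-dominant with low CK7 — and the test suite asserts those
orderings against whatever default ships. None of its numbers is presented
as a measured value.

## The synthetic scene generator

The generator emulates immunofluorescence of cells captured on a size-based
microfiltration device: a flat field with nucleated cells, one nuclear
channel plus the sex-appropriate 4-marker panel. It exists so that every
downstream stage has exact ground truth; it is first-class, tested code.

Per scene: cell radii are Gaussian (tumor mean 8 µm, SD 1.5 µm; leukocytes
scaled by 0.6), truncated below at 3.5 µm because cells smaller than the
~7 µm pore of a filtration device are not captured. Cells are placed by
rejection sampling without overlap, except that with probability
`clump_probability` (default 0.1) a cell is deliberately placed overlapping
a prior cell by 30–60% of its radius and shares its clump group. Tumor
cells draw marker states from the frequency-table row of the configured
tissue (`frequency_overrides` substitutes individual frequencies for
heterogeneity scenarios, e.g. a 21.7% ER-positive breast population);
leukocytes are marker-negative. Positive intensities are log-normal
(default log-mean ≈ log 300, log-SD 0.25 — roughly 3× the background with
moderate cell-to-cell spread); every cell is nuclear-positive. In
quantum-dot mode, marker-negative cells receive `nonspecific_fraction`
(default 0.15) of a foreground draw, a stand-in for the non-specific
binding of Q-dot-conjugated antibodies; organic-dye ("dylight") mode leaks
nothing. Neither leak level is a measured value — the source experiments
report the phenomenon, not a magnitude — so both are config-overridable.

Cells render as uniform disks with a 1-pixel Gaussian-blurred edge
(an erf radial profile); overlapping disks combine per channel by
*maximum*, so clumps read as plateaus rather than doubled-intensity spots
and ground-truth intensities stay analytic. A constant background plane
(default 100) plus i.i.d. Gaussian read noise (SD 5) is added and the image
floored at zero. Export is a multi-page 16-bit TIFF with a JSON sidecar
recording channel order and the single float→uint16 scale factor, one
ground-truth CSV row per cell, and the scene config as JSON.

All randomness flows from one integer seed; identical configs give
bit-identical scenes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: filter pore texture and autofluorescence,
uneven illumination and vignetting, spectral bleed-through between
fluorophores, z-structure and focus, irregular or apoptotic cell
morphology, intensity correlation between markers within a cell, red-cell
debris, and the 3-fluorophores-per-tube hardware limit that in practice
splits the panel across two blood tubes (scenes carry the full panel in
one pass). Results on synthetic scenes demonstrate internal consistency of
the pipeline, not clinical performance.

## Segmentation and quantification choices

* **Detection**: global Otsu on the nuclear channel, 8-connected
  components, area filter [30, 8000] px². No watershed by default:
  touching cells in a clump merge into one ROI, deliberately reproducing
  the clump undercount of manual ROI counting; `split_watershed=True`
  opts in to distance-transform watershed splitting.
* **Blank-image guard**: Otsu always returns *a* threshold, and on a pure
  noise field the resulting "foreground" percolates into spurious
  components. If the two Otsu classes are separated by less than 3
  background standard deviations the image is declared cell-free (pure
  Gaussian noise splits at ≈1.6σ; real nuclei at these settings sit at
  ≈40σ).
* **Background**: median of all pixels outside every ROI after 2-pixel
  dilation (keeps blurred edges out of the sample); global minimum if the
  ROIs cover everything. Robust to bright cells and exact on constant
  backgrounds.
* **Signal**: mean raw intensity over the ROI pixel set minus background,
  floored at zero (negative mean signal has no physical meaning here).
  Marker channels are read on the nuclear mask, which suits the nuclear
  marker TTF-1 directly; synthetic marker disks are concentric with the
  nucleus, so no cytoplasmic ring is modelled.
* **Thresholds**: positivity is corrected intensity strictly above the
  threshold — ties are negative (conservative calling). Three explicit
  policies replace interactive manual thresholding: `fixed`,
  `kfold_over_background` (k × background), and
  `negative_control_quantile` (quantile q of corrected intensities from a
  known-negative sample; q = 0.99 default — the reproducible analogue of
  thresholding against a negative control line). The pipeline defaults to
  k-fold with k = 1.0 because a simulated patient run has no
  negative-control sample; with the default intensities this sits ~6σ
  above the non-specific Q-dot leak and ~4σ below true signal.

## Numerical and testing notes

* Percentages are rounded half-up (not banker's) to one decimal, matching
  reporting conventions such as 15/69 → 21.7%.
* Posterior computation is entirely in log space; normalisation is tested
  to 1e−9, and the implementation is tested against a brute-force
  plain-float product oracle on small instances.
* Property tests (hypothesis, derandomised) cover pattern-count
  partitioning, permutation invariance of summaries, and posterior
  normalisation; recovery tests pin label recovery (100 scenes per tissue,
  ≥95% required), generator frequency recovery (3 binomial SD at n = 5000),
  a 6-fold intensity contrast recovered within ±15% through the full
  quantification path, and exact segmentation on noise-free scenes.
* Problem sizes in tests and in `scripts/acceptance.py` (512² scenes of
  50 tumor + 20 leukocyte cells; 10 scenes per deterministic check; 100
  seeds per stochastic rate) were chosen so the full suite completes in
  about a minute on one CPU while leaving the binomial test bands narrow.

## Known limitations

* The classifier is as good as its frequency table; the bundled default is
  qualitative, and no estimation of the table from data is provided.
* Marker independence within cells is assumed (see above); correlated
  marker loss (e.g. EMT down-regulating several cytokeratins together) is
  not modelled, in the generator or the likelihood.
* Cells positive for a non-epithelial panel marker only (e.g. ER+/CK7−)
  are reported as a separate category and, under the default
  `marker_positive` voter rule, do contribute to classification; whether
  such cells are genuine CTCs is not a question this package can settle.
* Two-draw mode pools cells for classification and reports per-draw
  summaries; no temporal model of marker dynamics is attempted.
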