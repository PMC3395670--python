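# Methods

## The age-distribution model

All conversion from event frequency to time rests on one assumption: the
population grows exponentially in unperturbed steady state, so the density
of cell-cycle ages t ∈ [0, 1] is φ(t) = 2 ln2 · 2⁻ᵗ, declining by exactly
a factor of two across the cycle. The cumulative frequency F of events
preceding a state then maps to time by t = 1 − log₂(2 − F), a monotone
bijection of [0, 1] onto itself with fixed points at 0 and 1. Cell loss,
death, or arrest would distort this map; no correction for them is
implemented.

Each region or fitted component along the traversal is placed at the
midpoint of its event mass, x_k = Σ_{j<k} f_j + f_k/2. Fitted G1/G2
sub-components are ordered by mean and assigned sequential frequency mass
proportional to their weights before cumulative positioning.

## Segmentation

The cell-cycle trajectory through data space is one-directional: a cell
cannot re-enter a region within one cycle. Interphase is segmented on the
DNA × cyclin A2 view by (1) estimating the modal backbone as the ridge of
a smoothed 64×64 2-D histogram (Gaussian smoothing, 1.5 bins; median
filter over the ridge), (2) projecting every event onto the backbone
polyline to obtain an arc-length coordinate — equivalent to boundaries
placed perpendicular to the local backbone direction — and (3) cutting
the S span at equal-count quantiles of that coordinate. Equal-count
boundaries are the automatic rendering of the manual rule that every
region hold a statistically effective number of events; the defaults are
12 S segments of ≥ 300 events. G1 and G2 clusters are cut where the
backbone passes 12% and 88% of the G1→G2 DNA interval; thin transition
ovals (1.5% of events nearest each cut) supply the deconvolution anchors.
An event on a shared boundary joins the earlier step (half-open
membership, chain-order tie-break). Manual region files (JSON rectangles,
polygons, ellipses) can replace the automatic chain.

Mitosis is segmented across three bivariate views in the order dictated
by the marker relay: pHH3 rise at constant cyclin A2 (pHH3 × cycA2),
cyclin A2 degradation at plateau pHH3 (same view), cyclin B1 degradation
once A2 is gone (cycA2 × cycB1), and completion with partial pHH3
dephosphorylation (cycB1 × pHH3). Stages are separated by data-driven
thresholds (fractions of upper quantiles) and each stage is split into
equal-count segments along its direction of travel, shrinking the segment
count when a stage holds fewer than 30 events per segment. Channels not
spanned by a step's view are still summarised by their median — indirect
reading, valid when the hidden marker is orthogonal to the exposed ones
within the step. A hand-off check warns when the shared marker's median
jumps across a view switch.

The interphase/mitosis split places the mitotic threshold at 1.6× the
99.9th percentile of G1-gated pHH3 (the interphase band only doubles from
G1 to G2, while the mitotic surge is ~10×) and requires DNA within
[0.8, 1.3]× the G2 mode.

## Constrained phase deconvolution

The G1 and G2 cyclin clusters are unimodal in log₁₀ intensity but contain
real expression change; reading several values out of one lump is
ill-posed without constraints, and a three-component decomposition
admits many solutions. The constraints used:

* outer component means/SDs fixed to single-Gaussian fits of the
  transition-oval distributions (S/G2 entry; G2/M exit read from early
  mitosis, topping up sparse rise windows with the highest-value events
  of the degradation track);
* center mean fixed midway between them (free SD in G2; SD transferred
  via the exit component's CV in G1);
* for a marker expressed in late G1 (cyclin B1) with no birth anchor,
  the lower component's mean is set at the histogram peak — the
  background level — with CV-transferred SD;
* amplitudes minimise histogram MSE plus λ·Σ(deviation of the component
  (frequency, linear-mean) points from the S-phase trajectory,
  extrapolated linearly)², with λ = 1 in normalised units. λ is the
  explicit rendering of "loosely constrained" amplitudes; increasing it
  monotonically reduces the trajectory deviation.

Fitting is bounded nonlinear least squares on amplitudes (and any free
SD), three seeded starts to guard against the multi-solution degeneracy.
Mixture fits operate on offset-restored (pre-background-subtraction)
intensities, since background subtraction centres negative cells on zero
where a log transform is undefined; component means are converted back
afterwards. Non-positive values are floored at 10⁻³ of the channel's
99th percentile. Anchors coinciding within a quarter SD route to a
single-component fit.

Histogram bin edges follow the Freedman–Diaconis rule (clamped to 16–256
bins). With a fixed fine grid the residual of even a perfect fit is
dominated by per-bin Poisson noise and the R² diagnostic measures the
grid, not the model; FD binning keeps expected counts per bin high enough
that R² reflects fit quality.

## Same-scale correction

Multi-color conjugate/detector gains are arbitrary per channel, so
multi-color cyclin amplitudes are not mutually comparable. Single-color
indirect assays sharing one secondary antibody are on one common scale.
DNA content, measured precisely in every file, correlates the assays:
each file's DNA axis is stretched by the exact two-point linear map
taking its G1/G2 modes to channels 350/700 (two constraints, two
parameters — a many-landmark regression would add nothing), and seven
contiguous equal-width DNA gates (width 40, centred at 525) are placed
identically in every file. Ordinary least squares of single-color against
multi-color per-gate cyclin medians gives slope and intercept per
epitope; background subtraction should force the intercept toward zero,
and leaving it free makes that assumption testable. Mode detection uses a
512-bin histogram with 3-bin Gaussian smoothing, peak prominence ≥ 5% and
a minimum G2/G1 separation of 1.3×, warning outside [1.8, 2.2].

The gate count is configurable; the default of seven follows the
procedure's description, noting that the accompanying figure legend
says six.

## Boundary heuristics

Region centres leave profile boundaries sparse where regions are large.
Three improvements: (1) the first G1 value also holds at x = 0 and is
duplicated there; (2) for a marker absent from G1 (cyclin A2), a line
through the first three S knots is extended back to its zero crossing and
a knot inserted there, skipped with a warning if the crossing falls
outside the G1–S gap; (3) the last value is duplicated at x = 1. For
epitopes known to be below detection at birth and division (the degraded
cyclins) endpoint zeroing additionally pins y(0) = y(1) = 0; this encodes
external biological knowledge and is off for DNA and pHH3. DNA is
reported in genome units by anchoring the G1 mode at 2 genomes; pHH3 is
reported relative to its own interphase G1 level (its pre-subtraction
background anchor), which is genuinely nonzero.

## The synthetic-data generator

The generator emulates the measurement process, not the reaction network:
ages are drawn exactly from φ by inverse CDF; piecewise-linear truth
profiles give each marker's clean value; the measurement model applies
per-assay gains, spillover between two fluorescence channels (default
8% from the pHH3 channel into the cyclin A2 channel), additive background
offsets (default 5 channel units per epitope), and median-preserving
multiplicative lognormal noise (default CV 3% DNA, 5% pulse height, 10%
epitopes). Doublets are summed event pairs whose pulse height is 0.6× the
singlet height per unit integral; debris is uniform sub-G1 DNA.

Default truth kinetics (fractions of cycle time): G1/S at 0.40, S/G2 at
0.75, G2/M at 0.95 — giving ~48/33/15/3.5% G1/S/G2/M event fractions
under φ. DNA runs 2C→4C linearly across S. Cyclin A2 is absent in G1,
rises through S and G2, peaks at the end of the mitotic pHH3 surge
(t = 0.96) and is degraded to zero by t = 0.972. Cyclin B1 starts at a
low nonzero level, rises from late G1, reaches peak at mitotic entry, is
held there through the spindle-checkpoint window while A2 is degraded,
and reaches zero at t = 0.984 — after cyclin A2, preserving the ordered
degradation. pHH3 doubles linearly over interphase, surges at mitotic
entry over a 1%-of-cycle window (~13 min of a 22 h cycle), and is
partially dephosphorylated in the last 1% of the cycle, ending at 2.5×
its G1 basal level; the basal level defaults to 5% of the mitotic peak.
The cyclin peak values are equal (100 a.u.) so that same-scale recovery
has a known target ratio of 1.

What the generator does **not** emulate: cell-to-cell kinetic
heterogeneity (every cell follows one truth trajectory; all variation is
measurement noise), cell loss and death, endoreduplication, instrument
drift, and non-linear detector response. Passing tests therefore show
that the procedure inverts the assumed measurement process — not that the
biological assumptions hold for any particular real culture.

## Problem sizes and numerical conventions

Tests and the acceptance script use 20 000-event multi-color populations
(≈ 700 mitotic events after gating) and 10 000-event single-color tables;
the ratio-recovery property runs 20 seeded assay triples with multi-color
cyclin gains drawn log-uniformly from [0.1, 10]. All randomness flows
through seeded `numpy` generators; two runs with one seed are
bit-identical. Log fitting uses base 10 throughout. Ties in mode
detection break toward the lower channel.

## Known limitations

* The frequency→time map assumes the ideal exponential age distribution;
  loss/death corrections are out of scope.
* The G2/M exit anchor is read from early mitosis under the orthogonality
  assumption; with very few mitotic events it is widened along the
  degradation track, which can bias the anchor slightly toward lower
  values.
* The automatic mitosis staging assumes the orthogonal (relay-like)
  degradation pattern; a curved A2/B1 relationship would need the
  backbone-following segmentation used for S phase.
* Same-scale accuracy inherits the indirect-assay caveats: equal
  secondary recognition of both primaries, comparable affinities and
  epitope exposure.
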