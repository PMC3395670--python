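"""Event-data preprocessing.

Four standard corrections applied before any segmentation or fitting:

* **Compensation** — linear removal of spectral spillover between two
  fluorescence channels (e.g. a green conjugate leaking into an orange
  detector).
* **Background subtraction** — cyclins are not expressed in early G1, so
  the G1 cluster measures pure background staining; subtracting its median
  per epitope channel sets negative cells close to zero.
* **Debris/aggregate exclusion** — sub-cellular debris sits below a DNA
  floor; aggregates (doublets) show a lower pulse *height* per unit of DNA
  *integral* than single nuclei and fall below a singlet discrimination
  line fitted to the 2C cluster.
* **Stemline gating** — restricts analysis to the main 2C->4C proliferating
  subpopulation on a (DNA, cyclin A2) view, excluding endoreduplicated or
  binucleate cells and outliers.

Negative post-subtraction intensities are retained (not clipped) so that
background clusters stay symmetric for downstream Gaussian fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events_io import EventTable

__all__ = [
    "CompensationSpec",
    "BackgroundAnchor",
    "compensate",
    "g1_mask",
    "subtract_background",
    "exclude_debris_aggregates",
    "stemline_gate",
]


@dataclass
class CompensationSpec:
    """Ordered (source, target, coefficient) spillover terms."""

    pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for src, dst, coef in self.pairs:
            if src == dst:
                raise ValueError("compensation pair must have distinct channels")
            if not 0.0 <= coef < 1.0:
                raise ValueError("spillover coefficient must lie in [0, 1)")


@dataclass
class BackgroundAnchor:
    """Per-epitope offsets subtracted during background correction."""

    offsets: dict
    g1_gate: str = "auto-dna-g1"
    n_g1: int = 0


def compensate(table: EventTable, spec) -> EventTable:
    """Subtract spectral spillover: target' = target - coef * source.

    ``spec`` is a :class:`CompensationSpec` or a bare list of
    ``(source, target, coefficient)`` triples, applied in order.
    """
    if not isinstance(spec, CompensationSpec):
        spec = CompensationSpec(list(spec))
    data = table.data.copy()
    for src, dst, coef in spec.pairs:
        for ch in (src, dst):
            if ch not in data.columns:
                raise KeyError(f"compensation references missing channel {ch!r}")
        data[dst] = data[dst] - coef * data[src]
    out = table.with_data(data)
    out.log("preprocess.compensate", pairs=[list(p) for p in spec.pairs])
    return out


def _dna_g1_mode(dna: np.ndarray, bins: int = 512) -> float:
    """Mode of the dominant (G1) DNA peak via a smoothed histogram."""
    from scipy.ndimage import gaussian_filter1d

    finite = dna[np.isfinite(dna) & (dna > 0)]
    if finite.size == 0:
        raise ValueError("DNA channel has no positive values")
    lo, hi = np.percentile(finite, [0.5, 99.5])
    counts, edges = np.histogram(finite, bins=bins, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), 3.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmax(smooth))])


def g1_mask(table: EventTable, halfwidth: float = 0.12) -> np.ndarray:
    """Boolean mask of events with DNA within +-halfwidth of the G1 mode."""
    dna = table[table.dna_channel]
    mode = _dna_g1_mode(dna)
    return np.abs(dna - mode) <= halfwidth * mode


def subtract_background(table: EventTable, g1_gate=None, min_events: int = 200
                        ) -> tuple[EventTable, BackgroundAnchor]:
    """Anchor each epitope channel so the G1 median sits at zero.

    ``g1_gate`` is a boolean mask selecting G1 events; by default a window
    around the DNA G1 mode is used.  Raises if the gate selects fewer than
    ``min_events`` events.
    """
    mask = g1_mask(table) if g1_gate is None else np.asarray(g1_gate, dtype=bool)
    n_g1 = int(mask.sum())
    if n_g1 < min_events:
        raise ValueError(f"G1 gate selects only {n_g1} events (< {min_events})")
    data = table.data.copy()
    offsets: dict[str, float] = {}
    for ch in table.epitope_channels:
        offset = float(np.median(data.loc[mask, ch]))
        offsets[ch] = offset
        data[ch] = data[ch] - offset
    anchor = BackgroundAnchor(offsets, "auto-dna-g1" if g1_gate is None else "user",
                              n_g1)
    out = table.with_data(data)
    out.log("preprocess.subtract_background", offsets=offsets, n_g1=n_g1)
    return out, anchor


def _singlet_line(dna: np.ndarray, height: np.ndarray,
                  quantile: float = 0.01) -> tuple[float, float]:
    """Quantile-regression singlet boundary fitted to the 2C cluster.

    Returns (m, b) such that singlets satisfy height >= m * dna + b.  The
    intercept is pinned at zero — pulse height vanishes with pulse
    integral — so the slope fitted on the narrow 2C cluster extrapolates
    stably to the 4C range where doublets concentrate.
    """
    import statsmodels.api as sm

    mode = _dna_g1_mode(dna)
    sel = np.abs(dna - mode) <= 0.15 * mode
    x, y = dna[sel], height[sel]
    if x.size < 50:
        raise ValueError("too few 2C-cluster events to fit the singlet line")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, x[:, None]).fit(q=quantile)
    return float(res.params[0]), 0.0


def exclude_debris_aggregates(table: EventTable, debris_floor_frac: float = 0.6,
                              quantile: float = 0.01) -> EventTable:
    """Drop sub-G1 debris and height-vs-integral aggregate (doublet) events.

    The debris floor is ``debris_floor_frac`` times the G1 DNA mode.  The
    singlet discrimination line ``height = m * dna + b`` is fitted to the 2C
    cluster at the given lower quantile; events below the line (doublets
    have lower height per unit integral) are removed.
    """
    dna = table[table.dna_channel]
    height = table[table.dna_height_channel]
    mode = _dna_g1_mode(dna)
    floor = debris_floor_frac * mode
    keep = dna >= floor
    if keep.sum() >= 50:
        m, b = _singlet_line(dna[keep], height[keep], quantile)
        keep &= height >= m * dna + b
    out = table.select(keep)
    out.log("preprocess.exclude_debris_aggregates",
            floor=float(floor), kept=int(keep.sum()), total=len(table))
    return out


def stemline_gate(table: EventTable, region=None, marker: str | None = None
                  ) -> EventTable:
    """Restrict to the 2C stemline on a (DNA, cyclin) bivariate view.

    ``region`` is a :class:`cytocycle.gating.Region` on
    ``(dna_integral, marker)``; by default an automatic rectangle spanning
    the 2C-4C DNA range and the bulk of the cyclin range is used.  An empty
    result raises a warning rather than an error.
    """
    dna = table[table.dna_channel]
    if region is not None:
        xch, ych = region.view
        inside = region.contains(table[xch], table[ych])
    else:
        if marker is None:
            epitopes = table.epitope_channels
            marker = "cyca2" if "cyca2" in epitopes else epitopes[0]
        y = table[marker]
        mode = _dna_g1_mode(dna)
        lo_y = np.percentile(y, 0.1)
        hi_y = np.percentile(y, 99.9)
        span = max(hi_y - lo_y, 1e-9)
        inside = ((dna >= 0.7 * mode) & (dna <= 2.8 * mode)
                  & (y >= lo_y - 0.25 * span) & (y <= hi_y + 0.5 * span))
    out = table.select(np.asarray(inside, dtype=bool))
    out.log("preprocess.stemline_gate", kept=int(inside.sum()), total=len(table))
    if len(out) == 0:
        warnings.warn("stemline gate excluded every event", stacklevel=2)
    return out
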