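"""Region geometry, Boolean gate algebra, and cell-cycle region chains.

An asynchronous population sweeps out a one-directional track through
multivariate data space: an individual cell cannot enter a region twice
within one cycle.  Segmentation therefore takes the form of *region
chains*: ordered sequences of non-overlapping regions, each holding a
statistically effective number of events, traced along the modal backbone
of a bivariate point cloud.

Interphase is segmented on a (DNA, cyclin A2) view from the G1 cluster to
the G2 cluster; mitosis requires three successive bivariate views because
the markers rise and fall in an ordered relay (pHH3 surge -> cyclin A2
degradation -> cyclin B1 degradation -> partial pHH3 dephosphorylation).
Channels not spanned by a step's view are still summarised per step; this
"indirect" reading assumes the hidden parameter is orthogonal to the
exposed ones within a step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events_io import EventTable

__all__ = [
    "Region",
    "GateExpr",
    "RegionRef",
    "And",
    "Or",
    "Not",
    "RegionChain",
    "ChainStep",
    "RegionStats",
    "evaluate_gate",
    "split_interphase_mitosis",
    "auto_segment_s",
    "chain_stats",
    "build_mitosis_chain",
]


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A 2-D gate: rectangle, polygon or ellipse on a channel-pair view.

    * rectangle — ``params = [x0, x1, y0, y1]``; membership is half-open
      (lower/left edge inclusive).
    * polygon — ``params = [[x, y], ...]`` with at least three vertices.
    * ellipse — ``params = [cx, cy, rx, ry, angle_deg]``.
    """

    id: str
    view: tuple
    kind: str = "rectangle"
    params: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.view = tuple(self.view)
        if len(self.view) != 2:
            raise ValueError("view must name exactly two channels")
        if self.kind == "rectangle":
            x0, x1, y0, y1 = self.params
            if not (x0 < x1 and y0 < y1):
                raise ValueError("degenerate rectangle")
        elif self.kind == "polygon":
            if len(self.params) < 3:
                raise ValueError("polygon needs >= 3 vertices")
        elif self.kind == "ellipse":
            cx, cy, rx, ry, *_ = self.params
            if rx <= 0 or ry <= 0:
                raise ValueError("degenerate ellipse")
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "rectangle":
            x0, x1, y0, y1 = map(float, self.params)
            return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        if self.kind == "polygon":
            from matplotlib.path import Path as MplPath

            path = MplPath(np.asarray(self.params, dtype=float))
            pts = np.column_stack([np.ravel(x), np.ravel(y)])
            return path.contains_points(pts).reshape(x.shape)
        cx, cy, rx, ry, angle = (list(map(float, self.params)) + [0.0])[:5]
        theta = np.deg2rad(angle)
        dx, dy = x - cx, y - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0

    def evaluate(self, table: EventTable) -> np.ndarray:
        for ch in self.view:
            if ch not in table.channel_names:
                raise KeyError(f"region {self.id!r} references missing channel {ch!r}")
        return self.contains(table[self.view[0]], table[self.view[1]])

    def to_dict(self) -> dict:
        return {"id": self.id, "view": list(self.view), "kind": self.kind,
                "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(d["id"], tuple(d["view"]), d.get("kind", "rectangle"),
                   d["params"])


def save_regions(regions, path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in regions], indent=1))


def load_regions(path) -> list[Region]:
    return [Region.from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# Boolean gate expressions
# ---------------------------------------------------------------------------

class GateExpr:
    """Base class for Boolean gate expression trees."""

    def evaluate(self, table: EventTable) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __and__(self, other):
        return And(self, other)

    def __or__(self, other):
        return Or(self, other)

    def __invert__(self):
        return Not(self)


@dataclass
class RegionRef(GateExpr):
    region: Region

    def evaluate(self, table):
        return self.region.evaluate(table)


@dataclass
class And(GateExpr):
    left: GateExpr
    right: GateExpr

    def evaluate(self, table):
        return self.left.evaluate(table) & self.right.evaluate(table)


@dataclass
class Or(GateExpr):
    left: GateExpr
    right: GateExpr

    def evaluate(self, table):
        return self.left.evaluate(table) | self.right.evaluate(table)


@dataclass
class Not(GateExpr):
    operand: GateExpr

    def evaluate(self, table):
        return ~self.operand.evaluate(table)


def evaluate_gate(table: EventTable, expr) -> np.ndarray:
    """Per-event Boolean membership for a region or gate expression."""
    if isinstance(expr, Region):
        expr = RegionRef(expr)
    if not isinstance(expr, GateExpr):
        raise TypeError("expr must be a Region or GateExpr")
    return np.asarray(expr.evaluate(table), dtype=bool)


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

@dataclass
class ChainStep:
    """One step of a region chain.

    ``role`` is ``phase_cluster`` (G1/G2-like clusters), ``segment`` (a
    slice of a continuous track) or ``transition_oval`` (thin boundary
    region used for mixture anchors, not part of the event partition).
    """

    id: str
    view: tuple
    role: str = "segment"
    region: Region | None = None
    indices: np.ndarray | None = None

    @property
    def in_partition(self) -> bool:
        return self.role != "transition_oval"


@dataclass
class RegionChain:
    """Ordered chain of steps tracing the cell-cycle trajectory.

    ``n_gated`` is the size of the gated population the chain partitions;
    partition steps assign each gated event to at most one step.
    """

    steps: list
    n_gated: int
    meta: dict = field(default_factory=dict)

    def partition_steps(self) -> list:
        return [s for s in self.steps if s.in_partition]

    def step(self, step_id: str) -> ChainStep:
        for s in self.steps:
            if s.id == step_id:
                return s
        raise KeyError(step_id)

    def validate_partition(self) -> None:
        seen = np.concatenate([s.indices for s in self.partition_steps()
                               if s.indices is not None and len(s.indices)])
        if len(seen) != len(np.unique(seen)):
            raise ValueError("chain steps assign some event to more than one step")


@dataclass
class RegionStats:
    """Per-step summary statistics over the gated population."""

    step_id: str
    role: str
    count: int
    frequency: float
    medians: dict
    log_means: dict
    log_cvs: dict


# ---------------------------------------------------------------------------
# Interphase / mitosis split
# ---------------------------------------------------------------------------

def split_interphase_mitosis(table: EventTable, phh3: str = "phh3",
                             threshold_factor: float = 1.6
                             ) -> tuple[EventTable, EventTable]:
    """Classify events as interphase or mitotic on a (pHH3, DNA) view.

    Interphase pHH3 forms a band rising from a low G1 value (2C DNA) to
    about twice that value in G2 (4C); mitotic cells carry both 4C DNA and
    a pHH3 level far above that band.  The mitotic threshold is set at
    ``threshold_factor`` times the upper tail of the G1-gated pHH3
    distribution, and the mitotic DNA window brackets the G2 (4C) mode.
    The two returned tables are disjoint.
    """
    from .samescale import find_dna_modes

    if phh3 not in table.channel_names:
        raise KeyError(f"missing pHH3 channel {phh3!r}")
    dna = table[table.dna_channel]
    values = table[phh3]
    try:
        g1_mode, g2_mode = find_dna_modes(dna)
    except ValueError:
        # effectively unimodal DNA: no 4C cluster, hence nothing mitotic
        inter = table.select(np.ones(len(table), dtype=bool))
        mito = table.select(np.zeros(len(table), dtype=bool))
        inter.log("gating.split_interphase_mitosis", mitotic=0)
        return inter, mito
    g1_sel = np.abs(dna - g1_mode) <= 0.10 * g1_mode
    band_top = np.percentile(values[g1_sel], 99.9) if g1_sel.any() else np.percentile(values, 99)
    threshold = threshold_factor * band_top
    mitotic = (values > threshold) & (dna >= 0.80 * g2_mode) & (dna <= 1.30 * g2_mode)
    interphase = (~mitotic) & (dna >= 0.70 * g1_mode) & (dna <= 1.30 * g2_mode)
    inter = table.select(interphase)
    inter.log("gating.split_interphase_mitosis", part="interphase",
              threshold=float(threshold))
    mito = table.select(mitotic)
    mito.log("gating.split_interphase_mitosis", part="mitosis",
             threshold=float(threshold))
    return inter, mito


# ---------------------------------------------------------------------------
# Interphase segmentation along the modal backbone
# ---------------------------------------------------------------------------

def _modal_backbone(x: np.ndarray, y: np.ndarray, bins: int = 64,
                    smooth_bins: float = 1.5) -> np.ndarray:
    """Ridge of the smoothed 2-D histogram: one modal y per occupied x column."""
    from scipy.ndimage import gaussian_filter
    from scipy.signal import medfilt

    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    smooth = gaussian_filter(hist, smooth_bins)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    occupied = smooth.sum(axis=1) > max(1.0, 0.001 * len(x))
    ridge_idx = np.argmax(smooth, axis=1)
    ridge = yc[ridge_idx]
    ridge = medfilt(ridge, kernel_size=5)
    pts = np.column_stack([xc[occupied], ridge[occupied]])
    if len(pts) < 2:
        raise ValueError("not enough occupied columns for a backbone")
    return pts


def _arclength_projection(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each point's nearest position on a polyline."""
    seg_start = polyline[:-1]
    seg_vec = polyline[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for i in range(len(seg_vec)):
        v = seg_vec[i]
        L2 = max(seg_len[i] ** 2, 1e-300)
        w = points - seg_start[i]
        frac = np.clip((w @ v) / L2, 0.0, 1.0)
        proj = seg_start[i] + frac[:, None] * v
        d2 = np.sum((points - proj) ** 2, axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_s[closer] = cum[i] + frac[closer] * seg_len[i]
    return best_s


def _boundary_region(step_id, view, polyline, s_lo, s_hi, cum, scale, offset):
    """Quadrilateral region between two boundaries cut perpendicular to the
    local backbone direction (serialisable approximation of the projection
    assignment)."""
    def cut(s):
        i = int(np.clip(np.searchsorted(cum, s) - 1, 0, len(polyline) - 2))
        seg = polyline[i + 1] - polyline[i]
        seg = seg / max(np.linalg.norm(seg), 1e-12)
        frac = (s - cum[i]) / max(cum[i + 1] - cum[i], 1e-12)
        pt = polyline[i] + frac * (polyline[i + 1] - polyline[i])
        normal = np.array([-seg[1], seg[0]])
        return pt, normal

    half = 5.0  # generous half-width in normalised units
    p_lo, n_lo = cut(s_lo)
    p_hi, n_hi = cut(s_hi)
    verts = np.array([p_lo + half * n_lo, p_hi + half * n_hi,
                      p_hi - half * n_hi, p_lo - half * n_lo])
    verts = verts * scale + offset
    return Region(step_id, view, "polygon", verts.tolist())


def auto_segment_s(table: EventTable, n_segments: int = 12,
                   min_events: int = 300, marker: str = "cyca2",
                   g1_cut: float = 0.12, g2_cut: float = 0.88,
                   oval_mass: float = 0.015, adapt: bool = False) -> RegionChain:
    """Segment interphase along the 2-D modal backbone of (DNA, cyclin).

    The table must be the interphase, stemline-gated population.  The
    backbone (mode ridge of a smoothed 64x64 2-D histogram) is traced from
    the G1 to the G2 cluster; events are assigned by arc-length projection,
    which is equivalent to boundaries perpendicular to the local backbone
    direction.  S-phase boundaries are placed at equal-count quantiles of
    the arc-length coordinate so every segment holds at least ``min_events``
    events.  The chain is G1 cluster, ``n_segments`` S segments, G2
    cluster, plus thin G1/S and S/G2 transition ovals (each holding
    ``oval_mass`` of the population) used as deconvolution anchors.
    """
    from .samescale import find_dna_modes

    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    dna = table[table.dna_channel]
    y = table[marker]
    g1_mode, g2_mode = find_dna_modes(dna)

    # normalised coordinates so both axes contribute comparably
    xn = (dna - g1_mode) / (g2_mode - g1_mode)
    ylo, yhi = np.percentile(y, [2, 98])
    yn = (y - ylo) / max(yhi - ylo, 1e-9)
    pts = np.column_stack([xn, yn])
    polyline = _modal_backbone(xn, yn)
    s = _arclength_projection(pts, polyline)

    seg_len = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    def s_at_x(x_target: float) -> float:
        bx = polyline[:, 0]
        idx = int(np.argmin(np.abs(bx - x_target)))
        return float(cum[idx])

    s1 = s_at_x(g1_cut)
    s2 = s_at_x(g2_cut)
    in_g1 = s < s1
    in_g2 = s >= s2
    in_s = ~in_g1 & ~in_g2
    n_s = int(in_s.sum())
    if n_s < n_segments * min_events:
        if not adapt:
            raise ValueError(
                f"S phase holds {n_s} events; cannot fill {n_segments} "
                f"segments of >= {min_events} events")
        # segment count is arbitrary, the event floor is not: relax the
        # floor first, then the count, keeping >= 50 events per segment
        min_events = max(50, n_s // n_segments)
        if n_s < n_segments * min_events:
            n_segments = max(2, n_s // min_events)
        if n_s < n_segments * min_events:
            raise ValueError(
                f"S phase holds only {n_s} events; too sparse to segment")

    idx_all = np.arange(len(table))
    scale = np.array([g2_mode - g1_mode, max(yhi - ylo, 1e-9)])
    offset = np.array([g1_mode, ylo])
    view = (table.dna_channel, marker)

    steps: list[ChainStep] = [ChainStep("G1", view, "phase_cluster",
                                        indices=idx_all[in_g1])]
    s_vals = s[in_s]
    order = np.argsort(s_vals, kind="stable")
    splits = np.array_split(idx_all[in_s][order], n_segments)
    edges = np.quantile(s_vals, np.linspace(0, 1, n_segments + 1))
    for k, seg_idx in enumerate(splits):
        region = _boundary_region(f"S{k + 1}", view, polyline,
                                  edges[k], edges[k + 1], cum, scale, offset)
        steps.append(ChainStep(f"S{k + 1}", view, "segment", region, seg_idx))
    steps.append(ChainStep("G2", view, "phase_cluster", indices=idx_all[in_g2]))

    half_mass = oval_mass / 2.0
    for name, s_cut in (("G1/S", s1), ("S/G2", s2)):
        ranks = np.abs(s - s_cut)
        take = max(int(round(oval_mass * len(table))), min(50, len(table)))
        oval_idx = idx_all[np.argsort(ranks, kind="stable")[:take]]
        steps.append(ChainStep(name, view, "transition_oval", indices=oval_idx))

    chain = RegionChain(steps, len(table),
                        meta={"marker": marker, "g1_mode": float(g1_mode),
                              "g2_mode": float(g2_mode),
                              "backbone": polyline.tolist(),
                              "oval_half_mass": half_mass})
    chain.validate_partition()
    return chain


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _log_stats(values: np.ndarray) -> tuple[float, float]:
    pos = values[values > 0]
    if pos.size == 0:
        return float("nan"), float("nan")
    logs = np.log10(pos)
    mean = float(np.mean(logs))
    sd = float(np.std(logs))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, cv


def chain_stats(table: EventTable, chain: RegionChain,
                channels: list | None = None) -> list[RegionStats]:
    """Per-step counts, frequencies and channel summaries.

    Frequencies are relative to the chain's gated population; transition
    ovals report frequency 0 (they are anchors, not partition mass).
    Channels outside a step's view are still summarised (indirect reading
    under the orthogonality assumption).  Empty steps yield NaN summaries.
    """
    if channels is None:
        channels = [c for c in table.channel_names
                    if table.channels[c].role != "truth"]
    out: list[RegionStats] = []
    for step in chain.steps:
        idx = step.indices if step.indices is not None else np.array([], dtype=int)
        count = len(idx)
        freq = count / chain.n_gated if (chain.n_gated and step.in_partition) else 0.0
        medians, lmeans, lcvs = {}, {}, {}
        for ch in channels:
            vals = table[ch][idx] if count else np.array([])
            medians[ch] = float(np.median(vals)) if count else float("nan")
            lm, lcv = _log_stats(vals) if count else (float("nan"), float("nan"))
            lmeans[ch], lcvs[ch] = lm, lcv
        out.append(RegionStats(step.id, step.role, count, freq,
                               medians, lmeans, lcvs))
    return out


# ---------------------------------------------------------------------------
# Mitosis chain
# ---------------------------------------------------------------------------

def build_mitosis_chain(table: EventTable, n_rise: int = 8, n_a2deg: int = 6,
                        n_b1deg: int = 3, n_done: int = 3,
                        a2: str = "cyca2", b1: str = "cycb1",
                        phh3: str = "phh3", min_events: int = 30,
                        handoff_tol: float = 0.35) -> RegionChain:
    """Segment the mitotic subset across three successive bivariate views.

    Stage 1 (pHH3 x cyclin A2): the pHH3 surge at mitotic entry, cyclin A2
    near peak.  Stage 2 (same view): cyclin A2 degradation at plateau pHH3.
    Stage 3 (cyclin A2 x cyclin B1): cyclin B1 degradation once A2 is gone.
    Stage 4 (cyclin B1 x pHH3): completion — partial pHH3 return with both
    cyclins below detection.  Within each stage events are ordered along
    the known direction of travel and split into equal-count segments.

    A hand-off consistency check warns when the marker shared between two
    consecutive views jumps by more than ``handoff_tol`` of its mitotic
    range across the view switch.
    """
    n = len(table)
    if n == 0:
        return RegionChain([], 0, meta={"empty": True})
    va, vb, vp = table[a2], table[b1], table[phh3]
    p_hi = 0.75 * np.percentile(vp, 90)
    a2_low = 0.15 * np.percentile(va, 95)
    b1_low = 0.15 * np.percentile(vb, 95)

    stage = np.full(n, 4, dtype=int)
    stage[(vb > b1_low) & (va <= a2_low)] = 3
    stage[(va > a2_low) & (vp >= p_hi)] = 2
    stage[(va > a2_low) & (vp < p_hi)] = 1

    specs = [
        (1, n_rise, vp, +1, (phh3, a2), "M-rise"),
        (2, n_a2deg, va, -1, (phh3, a2), "M-a2deg"),
        (3, n_b1deg, vb, -1, (a2, b1), "M-b1deg"),
        (4, n_done, vp, -1, (b1, phh3), "M-done"),
    ]
    idx_all = np.arange(n)
    steps: list[ChainStep] = []
    for stage_no, n_seg, key, direction, view, prefix in specs:
        sel = idx_all[stage == stage_no]
        if len(sel) == 0:
            continue
        order = np.argsort(direction * key[sel], kind="stable")
        # a region only carries information with a statistically effective
        # number of events; shrink the segment count on sparse stages
        n_eff = int(np.clip(len(sel) // min_events, 1, n_seg))
        parts = np.array_split(sel[order], n_eff)
        for k, part in enumerate(parts):
            steps.append(ChainStep(f"{prefix}-{k + 1}", view, "segment", indices=part))

    chain = RegionChain(steps, n, meta={"views": 3})
    chain.validate_partition()

    # hand-off consistency across view switches
    stats = chain_stats(table, chain, channels=[a2, b1, phh3])
    by_id = {s.step_id: s for s in stats}
    pairs = [("M-a2deg", "M-b1deg", b1), ("M-b1deg", "M-done", phh3)]
    ranges = {a2: np.ptp(va) or 1.0, b1: np.ptp(vb) or 1.0, phh3: np.ptp(vp) or 1.0}
    for pre, post, shared in pairs:
        last = [s for s in stats if s.step_id.startswith(pre)]
        first = [s for s in stats if s.step_id.startswith(post)]
        if last and first:
            gap = abs(last[-1].medians[shared] - first[0].medians[shared])
            if gap > handoff_tol * ranges[shared]:
                warnings.warn(
                    f"mitosis chain hand-off {pre}->{post}: {shared} median "
                    f"jumps by {gap:.3g}", stacklevel=2)
    return chain


def g2_exit_values(table: EventTable, chain: RegionChain, marker: str,
                   min_n: int = 100) -> np.ndarray:
    """Marker values at the G2/M boundary, read from early mitosis.

    For cyclin A2 the G2 exit level is held through the pHH3 rise (stage 1);
    cyclin B1 additionally stays at peak through A2 degradation (stages
    1-2).  When the rise window holds fewer than ``min_n`` events the
    sample is topped up with the highest-value events of the marker's own
    degradation track — i.e. the oval is widened along the traversal, as a
    hand-drawn boundary region would be.
    """
    prefixes = ("M-rise",) if marker != "cycb1" else ("M-rise", "M-a2deg")
    deg_prefix = "M-a2deg" if marker != "cycb1" else "M-b1deg"
    idx = [s.indices for s in chain.steps
           if any(s.id.startswith(p) for p in prefixes) and s.indices is not None]
    idx = np.concatenate(idx) if idx else np.array([], dtype=int)
    if len(idx) < min_n:
        deg = [s.indices for s in chain.steps
               if s.id.startswith(deg_prefix) and s.indices is not None]
        if deg:
            deg = np.concatenate(deg)
            order = np.argsort(table[marker][deg], kind="stable")[::-1]
            extra = deg[order[: min_n - len(idx)]]
            idx = np.concatenate([idx, extra])
    if len(idx) == 0:
        return np.array([])
    return table[marker][idx]
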