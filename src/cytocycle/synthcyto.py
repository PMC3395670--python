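"""Synthetic asynchronous-population cytometry data with known ground truth.

The generator emulates what a flow cytometer records from an exponentially
growing culture: cells occupy every cell-cycle position, with the steady-state
age density declining exponentially by a factor of two across the cycle
(one mitotic cell yields two newborns),

    phi(t) = 2 ln2 * 2**(-t),  t in [0, 1].

Each simulated event draws an age t from phi, evaluates per-marker
piecewise-linear truth profiles at that age (DNA replication through S,
cyclin A2/B1 accumulation and ordered mitotic degradation, the mitotic
phospho-histone-H3 surge), then passes the clean values through a
measurement model: per-assay channel gains, spectral spillover between two
fluorescence channels, additive background offsets and multiplicative
lognormal noise.  A configurable fraction of doublet (aggregate) and
low-DNA debris events is appended.  Ground-truth age and phase labels ride
along in reserved ``truth_``-prefixed columns so downstream oracles never
touch analysis channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .events_io import ChannelInfo, EventTable

__all__ = [
    "TruthProfiles",
    "NoiseModel",
    "sample_ages",
    "age_density",
    "age_cdf",
    "generate_population",
    "generate_assay_pair",
]


def age_density(t):
    """Steady-state age density phi(t) = 2 ln2 * 2**(-t) on [0, 1].

    Declines by exactly a factor of 2 across the cycle: one mitotic cell
    yields two newborn G1 cells.
    """
    t = np.asarray(t, dtype=float)
    return 2.0 * np.log(2.0) * 2.0 ** (-t)


def age_cdf(t):
    """CDF of the ideal asynchronous age distribution, F(t) = 2 - 2**(1-t)."""
    t = np.asarray(t, dtype=float)
    return 2.0 - 2.0 ** (1.0 - t)


def sample_ages(n: int, seed=None) -> np.ndarray:
    """Draw ``n`` cell-cycle ages from phi(t) = 2 ln2 2**(-t) on [0, 1].

    Uses exact inverse-CDF sampling: t = 1 - log2(2 - u) with u uniform on
    [0, 1).  Reproducible for a given ``seed`` (int or Generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(int(n))
    return 1.0 - np.log2(2.0 - u)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthProfiles:
    """Piecewise-linear ground-truth marker kinetics over one cell cycle.

    Phase boundaries are fractions of cycle time; the defaults put ~48% of
    an asynchronous population in G1, ~33% in S, ~15% in G2 and ~3.5% in M
    once weighted by the exponential age density.  Marker shapes:

    * ``dna`` — 2 C through G1, linear 2->4 C across S, 4 C through G2/M.
    * ``cyca2`` — absent in G1, accumulates through S and G2, peaks in early
      mitosis and is degraded to zero after nuclear-envelope breakdown,
      *before* cyclin B1.
    * ``cycb1`` — low but nonzero from late G1, accumulates to a late-G2/M
      peak, degraded to zero after cyclin A2.
    * ``phh3`` — basal interphase level that doubles linearly from G1 to the
      G2/M boundary, surges sharply at mitotic entry, and partially returns
      (residual phosphorylation) just before division.

    Basal interphase pHH3 defaults to 5% of the mitotic peak.
    """

    t_g1s: float = 0.40
    t_sg2: float = 0.75
    t_g2m: float = 0.95
    knots: dict = field(default_factory=dict)

    # internal mitotic waypoints (fractions of cycle time)
    t_phh3_top: float = 0.960      # end of the mitotic pHH3 surge
    t_a2_zero: float = 0.972       # cyclin A2 fully degraded
    t_b1_zero: float = 0.984       # cyclin B1 fully degraded
    t_phh3_drop: float = 0.990     # start of partial pHH3 dephosphorylation

    def __post_init__(self) -> None:
        if not (0.0 < self.t_g1s < self.t_sg2 < self.t_g2m < 1.0):
            raise ValueError("phase times must satisfy 0 < t_g1s < t_sg2 < t_g2m < 1")
        if not self.knots:
            self.knots = self._default_knots()
        self.validate()

    def _default_knots(self) -> dict:
        g1s, sg2, g2m = self.t_g1s, self.t_sg2, self.t_g2m
        top, a2z, b1z, drop = (self.t_phh3_top, self.t_a2_zero,
                               self.t_b1_zero, self.t_phh3_drop)
        peak = 100.0
        basal_phh3 = 0.05 * peak            # 5% of mitotic peak
        b1_basal = 4.0
        t_b1_rise = g1s - 0.125 * (g1s)     # late-G1 onset of cyclin B1 rise
        return {
            "dna": [(0.0, 2.0), (g1s, 2.0), (sg2, 4.0), (1.0, 4.0)],
            "cyca2": [
                (0.0, 0.0), (g1s, 0.0), (sg2, 60.0), (top, peak),
                (a2z, 0.0), (1.0, 0.0),
            ],
            # B1 reaches peak at mitotic entry and is held there by the
            # spindle checkpoint until after cyclin A2 is gone
            "cycb1": [
                (0.0, b1_basal), (t_b1_rise, b1_basal), (sg2, 55.0),
                (top, peak), (a2z, peak), (b1z, 0.0), (1.0, 0.0),
            ],
            "phh3": [
                (0.0, basal_phh3), (g2m, 2.0 * basal_phh3), (top, peak),
                (drop, peak), (1.0, 2.5 * basal_phh3),
            ],
        }

    # -- queries -----------------------------------------------------------
    @property
    def markers(self) -> list[str]:
        return list(self.knots)

    def evaluate(self, marker: str, t) -> np.ndarray:
        """Truth profile value of ``marker`` at age(s) ``t``."""
        pts = np.asarray(self.knots[marker], dtype=float)
        return np.interp(np.asarray(t, dtype=float), pts[:, 0], pts[:, 1])

    def phase_of(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        phase = np.full(t.shape, "g1", dtype=object)
        phase[t >= self.t_g1s] = "s"
        phase[t >= self.t_sg2] = "g2"
        phase[t >= self.t_g2m] = "m"
        return phase

    def phase_fraction(self, phase: str) -> float:
        """Closed-form event-frequency of a phase under the age density."""
        edges = {"g1": (0.0, self.t_g1s), "s": (self.t_g1s, self.t_sg2),
                 "g2": (self.t_sg2, self.t_g2m), "m": (self.t_g2m, 1.0)}
        lo, hi = edges[phase]
        return float(age_cdf(hi) - age_cdf(lo))

    def validate(self) -> None:
        for marker, pts in self.knots.items():
            pts = np.asarray(pts, dtype=float)
            if (pts[:, 1] < 0).any():
                raise ValueError(f"{marker} truth profile has negative values")
            if (np.diff(pts[:, 0]) <= 0).any():
                raise ValueError(f"{marker} truth knots must have increasing t")
        if "dna" in self.knots:
            if not np.isclose(self.evaluate("dna", 0.0), 2.0):
                raise ValueError("DNA truth must be 2 C at t = 0")
            if not np.isclose(self.evaluate("dna", self.t_sg2), 4.0):
                raise ValueError("DNA truth must be 4 C from t_sg2 on")
        if {"cyca2", "cycb1"} <= set(self.knots):
            grid = np.linspace(self.t_g2m, 1.0, 513)
            a2 = self.evaluate("cyca2", grid)
            b1 = self.evaluate("cycb1", grid)
            ta2 = grid[np.argmax(a2 <= 1e-9)] if (a2 <= 1e-9).any() else np.inf
            tb1 = grid[np.argmax(b1 <= 1e-9)] if (b1 <= 1e-9).any() else np.inf
            if not ta2 < tb1:
                raise ValueError("cyclin A2 must be degraded before cyclin B1 in M")
        if "phh3" in self.knots:
            lo = self.evaluate("phh3", 0.0)
            hi = self.evaluate("phh3", self.t_g2m)
            if not np.isclose(hi, 2.0 * lo, rtol=1e-6):
                raise ValueError("interphase pHH3 at t_g2m must be twice its t=0 level")

    # -- config ------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "t_g1s": self.t_g1s, "t_sg2": self.t_sg2, "t_g2m": self.t_g2m,
            "knots": {m: [list(p) for p in pts] for m, pts in self.knots.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthProfiles":
        return cls(**d)


# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------

_DEF_CV = {"dna": 0.03, "dna_h": 0.05, "cyca2": 0.10, "cycb1": 0.10, "phh3": 0.10}
_DEF_OFFSET = {"cyca2": 5.0, "cycb1": 5.0, "phh3": 5.0}


@dataclass
class NoiseModel:
    """Measurement-process configuration for one simulated assay.

    ``cv`` are per-channel lognormal coefficients of variation (fractions),
    ``spillover`` a list of (source, target, coefficient) fluorescence
    cross-talk terms, ``offset`` additive per-channel background (channel
    units, applied after gain), ``gain`` per-channel multiplicative assay
    gains.  ``doublet_frac``/``debris_frac`` are contamination fractions of
    the requested event count.  Identical seed => identical output.
    """

    n: int = 20000
    seed: int = 0
    cv: dict = field(default_factory=lambda: dict(_DEF_CV))
    spillover: list = field(default_factory=lambda: [("phh3", "cyca2", 0.08)])
    offset: dict = field(default_factory=lambda: dict(_DEF_OFFSET))
    gain: dict = field(default_factory=lambda: {"dna": 100.0})
    doublet_frac: float = 0.0
    debris_frac: float = 0.0
    channels: tuple = ("dna", "cyca2", "cycb1", "phh3")
    height_factor: float = 1.0          # singlet pulse height per unit integral
    doublet_height_factor: float = 0.6  # aggregates: lower height per integral

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("event count n must be >= 1")
        for ch, cv in self.cv.items():
            if not 0.0 <= cv < 0.5:
                raise ValueError(f"cv[{ch}] must lie in [0, 0.5)")
        for src, dst, coef in self.spillover:
            if src == dst:
                raise ValueError("spillover source and target must differ")
            if not 0.0 <= coef < 0.5:
                raise ValueError("spillover coefficients must lie in [0, 0.5)")
        for ch, g in self.gain.items():
            if g <= 0:
                raise ValueError(f"gain[{ch}] must be positive")
        for frac in (self.doublet_frac, self.debris_frac):
            if not 0.0 <= frac <= 0.2:
                raise ValueError("contamination fractions must lie in [0, 0.2]")

    def gain_of(self, channel: str) -> float:
        return float(self.gain.get(channel, 1.0))

    def cv_of(self, channel: str) -> float:
        return float(self.cv.get(channel, 0.0))

    def to_dict(self) -> dict:
        return {
            "n": self.n, "seed": self.seed, "cv": dict(self.cv),
            "spillover": [list(s) for s in self.spillover],
            "offset": dict(self.offset), "gain": dict(self.gain),
            "doublet_frac": self.doublet_frac, "debris_frac": self.debris_frac,
            "channels": list(self.channels),
            "height_factor": self.height_factor,
            "doublet_height_factor": self.doublet_height_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        if "spillover" in d:
            d["spillover"] = [tuple(s) for s in d["spillover"]]
        return cls(**d)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-1 multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


def _measure(clean: dict, noise: NoiseModel, rng: np.random.Generator) -> dict:
    """Gain -> spillover -> offset -> lognormal, per channel."""
    n = len(next(iter(clean.values())))
    meas = {ch: clean[ch] * noise.gain_of(ch) for ch in clean}
    for src, dst, coef in noise.spillover:
        if src in meas and dst in meas:
            meas[dst] = meas[dst] + coef * meas[src]
    for ch in meas:
        meas[ch] = meas[ch] + float(noise.offset.get(ch, 0.0))
    for ch in meas:
        meas[ch] = meas[ch] * _lognormal_factor(rng, noise.cv_of(ch), n)
    return meas


def generate_population(truth: TruthProfiles, noise: NoiseModel) -> EventTable:
    """Simulate one stained sample of an asynchronous population.

    Returns an :class:`EventTable` with the configured marker channels, a
    ``dna_h`` pulse-height channel, and truth columns ``truth_t`` (age) and
    ``truth_phase`` (g1/s/g2/m, or doublet/debris for contaminants).
    """
    markers = [ch for ch in noise.channels if ch in truth.knots]
    if not markers:
        raise ValueError("noise.channels shares no marker with the truth profiles")
    rng = np.random.default_rng(noise.seed)
    t = sample_ages(noise.n, rng)
    clean = {m: truth.evaluate(m, t) for m in markers}
    dna_gain = noise.gain_of("dna")
    meas = _measure(clean, noise, rng)
    # pulse height tracks the gained DNA integral so both live on one scale
    meas["dna_h"] = (truth.evaluate("dna", t) * noise.height_factor * dna_gain
                     * _lognormal_factor(rng, noise.cv_of("dna_h"), noise.n))
    frames = [pd.DataFrame({**meas, "truth_t": t,
                            "truth_phase": truth.phase_of(t)})]

    n_doublet = int(round(noise.doublet_frac * noise.n))
    if n_doublet:
        ta = sample_ages(n_doublet, rng)
        tb = sample_ages(n_doublet, rng)
        dclean = {m: truth.evaluate(m, ta) + truth.evaluate(m, tb) for m in markers}
        dmeas = _measure(dclean, noise, rng)
        dna_sum = truth.evaluate("dna", ta) + truth.evaluate("dna", tb)
        dmeas["dna_h"] = (dna_sum * noise.height_factor * noise.doublet_height_factor
                          * dna_gain * _lognormal_factor(rng, noise.cv_of("dna_h"), n_doublet))
        frames.append(pd.DataFrame({**dmeas, "truth_t": ta,
                                    "truth_phase": np.full(n_doublet, "doublet", dtype=object)}))

    n_debris = int(round(noise.debris_frac * noise.n))
    if n_debris:
        frac = rng.uniform(0.05, 0.55, n_debris)      # sub-G1 DNA, in C units of 2C
        dclean = {m: np.zeros(n_debris) for m in markers}
        dclean["dna"] = 2.0 * frac
        dmeas = _measure(dclean, noise, rng)
        dmeas["dna_h"] = (2.0 * frac * noise.height_factor * dna_gain
                          * _lognormal_factor(rng, noise.cv_of("dna_h"), n_debris))
        frames.append(pd.DataFrame({**dmeas, "truth_t": np.full(n_debris, np.nan),
                                    "truth_phase": np.full(n_debris, "debris", dtype=object)}))

    data = pd.concat(frames, ignore_index=True)
    perm = rng.permutation(len(data))
    data = data.iloc[perm].reset_index(drop=True)
    channels = {m: ChannelInfo(m, "dna_integral" if m == "dna" else "epitope")
                for m in markers}
    channels["dna_h"] = ChannelInfo("dna_h", "dna_height")
    channels["truth_t"] = ChannelInfo("truth_t", "truth")
    channels["truth_phase"] = ChannelInfo("truth_phase", "truth")
    data["truth_t"] = data["truth_t"].fillna(-1.0)
    table = EventTable(data, channels)
    table.log("synthcyto.generate_population", n=noise.n, seed=noise.seed)
    return table


def generate_assay_pair(truth: TruthProfiles, noise_multi: NoiseModel,
                        noise_single_a: NoiseModel, noise_single_b: NoiseModel
                        ) -> tuple[EventTable, EventTable, EventTable]:
    """Simulate one multi-color and two single-color stains of one culture.

    The two single-color assays model indirect staining with a *shared*
    secondary antibody, so their cyclin-channel gains must be equal; the
    multi-color assay carries independent per-cyclin gains (distinct
    direct conjugates).  Returns ``(multi, single_a2, single_b1)``.
    """
    ga = noise_single_a.gain_of("cyca2")
    gb = noise_single_b.gain_of("cycb1")
    if not np.isclose(ga, gb):
        raise ValueError(
            "single-color assays share one secondary antibody: cyclin gains "
            f"must match (got {ga} and {gb})"
        )
    multi = generate_population(truth, noise_multi)
    single_a = generate_population(
        truth, replace(noise_single_a, channels=("dna", "cyca2"), spillover=[]))
    single_b = generate_population(
        truth, replace(noise_single_b, channels=("dna", "cycb1"), spillover=[]))
    return multi, single_a, single_b


# ---------------------------------------------------------------------------
# Config file round-trip
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[TruthProfiles, NoiseModel]:
    """Load (truth, noise) from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    truth = TruthProfiles.from_dict(cfg.get("truth", {}))
    noise = NoiseModel.from_dict(cfg.get("noise", {}))
    return truth, noise


def dump_config(truth: TruthProfiles, noise: NoiseModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"truth": truth.to_dict(), "noise": noise.to_dict()}, fh)
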