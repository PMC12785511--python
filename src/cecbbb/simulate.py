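"""Seeded synthetic-data generators with known ground truth.

Three families of fixtures, each a pure function of (config, seed):

* electropherogram traces - fixed-length amplitude-vs-migration-time series
  with an injection artifact confined to the first ~100 samples, one
  dominant Gaussian analyte peak inside the analysis window, linear baseline
  drift and Gaussian noise, replicate groups per synthetic compound, and
  class-dependent peak statistics;
* cosolvent titration points generated from a known Yasuda-Shedlovsky line;
* regression datasets drawn from a known linear log BB model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidInputError
from .titration import CosolventPoint, PartitionTitration, ProtolyteKind, solvent_properties
from .titration import SOLVENT_TABLE, _WATER_EPS, _WATER_LOG_CONC


@dataclass(frozen=True)
class TraceSimConfig:
    """Electropherogram simulator settings.

    The trace spans ``length`` samples; with the default 512 samples mapped
    onto a 0-11.6 min run the analysis window (samples 150-460) corresponds
    to the 3-11 min band where analyte peaks elute. ``class_effect`` gives
    per-class (peak-position offset, peak-width offset) in samples relative
    to the window center; the defaults separate the three permeability
    classes cleanly, and an all-zero tuple yields label-free traces.
    """

    length: int = 512
    artifact_span: int = 100
    peak_time_range: tuple[float, float] = (150.0, 460.0)
    peak_width_range: tuple[float, float] = (8.0, 14.0)
    class_effect: tuple[tuple[float, float], ...] = (
        (-120.0, 0.0),
        (0.0, 0.0),
        (120.0, 0.0),
    )
    peak_loc_sd: float = 12.0
    replicate_loc_sd: float = 2.0
    peak_amp_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    drift_slope: float = 2e-4
    artifact_amp: float = 3.0
    replicates: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.artifact_span >= self.length:
            raise InvalidInputError("artifact_span must be smaller than length")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


def _gaussian(t: np.ndarray, loc: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - loc) / width) ** 2)


def _draw_peak(class_index: int, cfg: TraceSimConfig, rng: np.random.Generator):
    if not (0 <= class_index < len(cfg.class_effect)):
        raise InvalidInputError(
            f"class index {class_index} outside the configured "
            f"{len(cfg.class_effect)} classes"
        )
    loc_off, width_off = cfg.class_effect[class_index]
    center = 0.5 * (cfg.peak_time_range[0] + cfg.peak_time_range[1])
    loc = rng.normal(center + loc_off, cfg.peak_loc_sd)
    loc = float(np.clip(loc, *cfg.peak_time_range))
    width = float(rng.uniform(*cfg.peak_width_range) + width_off)
    amp = float(rng.uniform(*cfg.peak_amp_range))
    return loc, width, amp


def _render(loc, width, amp, cfg: TraceSimConfig, rng: np.random.Generator):
    t = np.arange(cfg.length, dtype=float)
    trace = cfg.drift_slope * t
    # injection spike entirely inside the artifact span so trimming removes it
    trace += _gaussian(t, 0.3 * cfg.artifact_span, 0.05 * cfg.artifact_span,
                       cfg.artifact_amp)
    trace += _gaussian(t, loc, width, amp)
    if cfg.noise_sd > 0:
        trace += rng.normal(0.0, cfg.noise_sd, cfg.length)
    return trace


def simulate_electropherogram(
    class_index: int, cfg: TraceSimConfig = TraceSimConfig(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One raw trace of the given permeability class. Deterministic given rng."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    loc, width, amp = _draw_peak(class_index, cfg, rng)
    return _render(loc, width, amp, cfg, rng)


def simulate_dataset(
    n_per_class: tuple[int, ...],
    cfg: TraceSimConfig = TraceSimConfig(),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """A labeled replicate-structured trace set.

    ``n_per_class`` counts traces per class; traces are grouped into
    synthetic compounds of ``cfg.replicates`` repeated measurements sharing a
    latent peak position (replicates jitter around it), mirroring repeated
    runs of the same drug. Returns (raw traces, labels, manifest); the
    manifest pairs every trace with its ground-truth class and latent peak
    parameters.
    """
    if any(n < 1 for n in n_per_class):
        raise InvalidInputError("each class needs at least one trace")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    traces, labels, rows = [], [], []
    compound_no = 0
    for ci, n in enumerate(n_per_class):
        made = 0
        while made < n:
            compound_no += 1
            loc, width, amp = _draw_peak(ci, cfg, rng)
            for rep in range(min(cfg.replicates, n - made)):
                rloc = loc + rng.normal(0.0, cfg.replicate_loc_sd)
                trace = _render(rloc, width, amp, cfg, rng)
                traces.append(trace)
                labels.append(ci)
                rows.append(
                    {"compound_id": f"SIM{compound_no:04d}", "replicate": rep,
                     "class": ci, "peak_loc": rloc, "peak_width": width,
                     "peak_amp": amp}
                )
                made += 1
    return (np.stack(traces), np.asarray(labels, dtype=int),
            pd.DataFrame(rows))


def ys_line_value(pka_aq: float, wt_percent: float, slope: float) -> float:
    """Noise-free apparent pKa on a Yasuda-Shedlovsky line through pka_aq."""
    eps, h2o = solvent_properties(wt_percent)
    x = 1.0 / eps
    x0 = 1.0 / _WATER_EPS
    y = (pka_aq + _WATER_LOG_CONC) + slope * (x - x0)
    return y - math.log10(h2o)


def simulate_titration(
    true_pka_aq: float,
    noise_sd: float = 0.0,
    wt_percents: tuple[float, ...] = (30.0, 40.0, 50.0),
    seed: int | None = None,
    slope: float = 150.0,
) -> list[CosolventPoint]:
    """Cosolvent titration points from a known Yasuda-Shedlovsky line.

    ``slope`` is the line's slope against 1/eps (a value of 150 gives the
    ~1 pKa-unit upward apparent shift at 50% methanol typical of acids).
    """
    if len(set(wt_percents)) < 2:
        raise InsufficientDataError(
            "extrapolation requires >= 2 distinct methanol compositions"
        )
    rng = np.random.default_rng(seed)
    pts = []
    for wt in wt_percents:
        pska = ys_line_value(true_pka_aq, wt, slope)
        if noise_sd > 0:
            pska += rng.normal(0.0, noise_sd)
        pts.append(CosolventPoint(methanol_wt_percent=wt, pska=pska))
    return pts


def simulate_partition_titration(
    pka_aq: float, logp: float, phase_ratio_r: float, kind: str | ProtolyteKind,
) -> PartitionTitration:
    """Noise-free dual-phase titration with a known log P (exact round trip)."""
    kind = ProtolyteKind(kind)
    shift = math.log10(1.0 + phase_ratio_r * 10.0**logp)
    if kind in (ProtolyteKind.MONOPROTIC_ACID, ProtolyteKind.DIPROTIC_ACID):
        poka = pka_aq + shift
    else:
        poka = pka_aq - shift
    return PartitionTitration(pka_aq=pka_aq, poka=poka, phase_ratio_r=phase_ratio_r)


DEFAULT_PREDICTOR_RANGES = {
    "k_prime": (-0.05, 0.35),
    "logd74": (-3.0, 6.0),
    "pka": (2.5, 10.5),
}


def simulate_regression_data(
    beta_true=(-2.45, 0.1, 0.3, 0.27),
    noise_sd: float = 0.5,
    n: int = 57,
    predictor_ranges: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compound records drawn from a known linear log BB model.

    Predictors are uniform over ranges spanning the experimental dataset;
    the response is the linear model plus Gaussian noise.
    """
    if n <= 4:
        raise InsufficientDataError("need n > 4 records to later fit 4 coefficients")
    ranges = DEFAULT_PREDICTOR_RANGES if predictor_ranges is None else predictor_ranges
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("k_prime", "logd74", "pka"):
        lo, hi = ranges[name]
        cols[name] = rng.uniform(lo, hi, n)
    beta = np.asarray(beta_true, dtype=float)
    X = np.column_stack([np.ones(n), cols["k_prime"], cols["logd74"], cols["pka"]])
    y = X @ beta
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(cols)
    df.insert(0, "compound_id", [f"SYN{i:04d}" for i in range(n)])
    df["logbb"] = y
    return df
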