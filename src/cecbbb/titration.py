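"""Physicochemical derivations from potentiometric titration endpoints.

Covers the downstream arithmetic of an automated pH-metric titration
workflow: Yasuda-Shedlovsky extrapolation of cosolvent apparent pKa values
to pure water, log P from the octanol-induced pKa shift of a dual-phase
titration, the distribution coefficient log D at arbitrary pH under a
neutral-species-only partition model, and forward simulation of Bjerrum
(mean bound protons vs pH) curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import InsufficientDataError, InvalidInputError, RangeError


class ProtolyteKind(str, Enum):
    MONOPROTIC_ACID = "monoprotic_acid"
    MONOPROTIC_BASE = "monoprotic_base"
    DIPROTIC_ACID = "diprotic_acid"
    DIPROTIC_BASE = "diprotic_base"
    AMPHOLYTE = "ampholyte"


_N_PROTONS = {
    ProtolyteKind.MONOPROTIC_ACID: 1,
    ProtolyteKind.MONOPROTIC_BASE: 1,
    ProtolyteKind.DIPROTIC_ACID: 2,
    ProtolyteKind.DIPROTIC_BASE: 2,
    ProtolyteKind.AMPHOLYTE: 2,
}


@dataclass(frozen=True)
class ProtolyteSpec:
    """Ionization model of a compound.

    ``pka_values`` are macroscopic pKa values in deprotonation order (the
    fully protonated species loses its first proton with pka_values[0]).
    For an ampholyte the convention is (acidic-group pKa, basic-group pKa).
    """

    compound_id: str
    kind: ProtolyteKind
    pka_values: tuple[float, ...]

    def __post_init__(self) -> None:
        kind = ProtolyteKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "pka_values", tuple(float(p) for p in self.pka_values))
        if len(self.pka_values) != _N_PROTONS[kind]:
            raise InvalidInputError(
                f"{kind.value} requires {_N_PROTONS[kind]} pKa value(s), "
                f"got {len(self.pka_values)}"
            )
        for p in self.pka_values:
            if not (0.0 < p < 14.0):
                raise InvalidInputError(f"pKa {p} outside the supported (0, 14) range")

    @property
    def n_protons(self) -> int:
        return _N_PROTONS[self.kind]


@dataclass(frozen=True)
class CosolventPoint:
    """Apparent pKa measured at one methanol weight fraction."""

    methanol_wt_percent: float
    pska: float

    def __post_init__(self) -> None:
        if not (0.0 < self.methanol_wt_percent < 100.0):
            raise InvalidInputError("methanol_wt_percent must lie in (0, 100)")


@dataclass(frozen=True)
class PartitionTitration:
    """Aqueous and octanol-shifted apparent pKa from a dual-phase titration."""

    pka_aq: float
    poka: float
    phase_ratio_r: float  # V(octanol)/V(water)

    def __post_init__(self) -> None:
        if self.phase_ratio_r <= 0:
            raise InvalidInputError("phase_ratio_r must be positive")


@dataclass(frozen=True)
class LipophilicityResult:
    logp: float
    logd: float
    ph: float


# Methanol-water mixture properties at 25 C (handbook values): weight percent
# methanol -> (dielectric constant, molar water concentration). Pure water is
# eps = 78.3 and [H2O] = 55.3 M. Intermediate compositions are linearly
# interpolated; compositions outside the tabulated range are rejected.
SOLVENT_TABLE: dict[float, tuple[float, float]] = {
    0.0: (78.3, 55.3),
    30.0: (64.3, 36.9),
    40.0: (59.2, 31.1),
    50.0: (54.3, 25.4),
}

_WATER_EPS = SOLVENT_TABLE[0.0][0]
_WATER_LOG_CONC = math.log10(SOLVENT_TABLE[0.0][1])


def solvent_properties(wt_percent: float) -> tuple[float, float]:
    """(dielectric constant, molar [H2O]) of a methanol-water mixture."""
    pts = sorted(SOLVENT_TABLE)
    if not (pts[0] <= wt_percent <= pts[-1]):
        raise RangeError(
            f"methanol wt% {wt_percent} outside tabulated range "
            f"[{pts[0]}, {pts[-1]}]"
        )
    eps = np.interp(wt_percent, pts, [SOLVENT_TABLE[p][0] for p in pts])
    h2o = np.interp(wt_percent, pts, [SOLVENT_TABLE[p][1] for p in pts])
    return float(eps), float(h2o)


def yasuda_shedlovsky(
    points: Iterable[CosolventPoint | tuple[float, float]],
) -> tuple[float, float]:
    """Extrapolate cosolvent apparent pKa values to pure water.

    Fits psKa + log10[H2O] against 1/eps by ordinary least squares and
    evaluates the line at pure water's 1/eps; the aqueous pKa is that value
    minus log10(55.3). Returns ``(pka_aq, stderr)`` where stderr is the
    standard error of the extrapolated mean (0.0 for an exactly determined
    two-point fit).
    """
    pts = [p if isinstance(p, CosolventPoint) else CosolventPoint(*p) for p in points]
    wt = np.array([p.methanol_wt_percent for p in pts])
    if len(pts) < 2 or np.unique(wt).size < 2:
        raise InsufficientDataError(
            "Yasuda-Shedlovsky extrapolation needs >= 2 points at distinct wt%"
        )
    x = np.empty(len(pts))
    y = np.empty(len(pts))
    for i, p in enumerate(pts):
        eps, h2o = solvent_properties(p.methanol_wt_percent)
        x[i] = 1.0 / eps
        y[i] = p.pska + math.log10(h2o)

    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    x0 = 1.0 / _WATER_EPS
    yhat0 = beta[0] + beta[1] * x0
    pka_aq = yhat0 - _WATER_LOG_CONC

    n = len(pts)
    resid = y - X @ beta
    if n > 2:
        s2 = float(resid @ resid) / (n - 2)
        xbar = x.mean()
        sxx = float(((x - xbar) ** 2).sum())
        se = math.sqrt(s2 * (1.0 / n + (x0 - xbar) ** 2 / sxx))
    else:
        se = 0.0
    return float(pka_aq), float(se)


def logp_from_shift(t: PartitionTitration, kind: str | ProtolyteKind) -> float:
    """log P from the octanol-induced apparent-pKa shift.

    For an acid the shift is upward (poKa > pKa) and
    log P = log10((10^(poKa - pKa) - 1)/r); for a base the shift is downward
    and log P = log10((10^(pKa - poKa) - 1)/r), with r the octanol/water
    volume ratio.
    """
    kind = ProtolyteKind(kind)
    if kind in (ProtolyteKind.MONOPROTIC_ACID, ProtolyteKind.DIPROTIC_ACID):
        shift = t.poka - t.pka_aq
    elif kind in (ProtolyteKind.MONOPROTIC_BASE, ProtolyteKind.DIPROTIC_BASE):
        shift = t.pka_aq - t.poka
    else:
        raise InvalidInputError("logp_from_shift requires an acid or base kind")
    ratio = 10.0**shift - 1.0
    if shift <= 0 or ratio <= 1e-12:
        raise InvalidInputError(
            "no partitioning detected: apparent pKa shift is zero or in the "
            "wrong direction for the stated acid/base kind"
        )
    return float(math.log10(ratio / t.phase_ratio_r))


def _log10_ion_ratios(spec: ProtolyteSpec, ph: float) -> list[float]:
    """log10 of each ionized-species-to-neutral concentration ratio."""
    k = spec.kind
    p = spec.pka_values
    if k is ProtolyteKind.MONOPROTIC_ACID:
        return [ph - p[0]]
    if k is ProtolyteKind.MONOPROTIC_BASE:
        return [p[0] - ph]
    if k is ProtolyteKind.DIPROTIC_ACID:
        # H2A neutral; HA- and A2- accumulate successive deprotonations
        return [ph - p[0], 2 * ph - p[0] - p[1]]
    if k is ProtolyteKind.DIPROTIC_BASE:
        # B neutral; BH+ and BH2++ accumulate successive protonations,
        # pka_values in deprotonation order (BH2++ loses first at p[0])
        return [p[1] - ph, p[0] + p[1] - 2 * ph]
    # ampholyte: (acid pKa, base pKa); anion, cation (zwitterion folded into
    # the two-site approximation)
    return [ph - p[0], p[1] - ph]


def logd_at_ph(spec: ProtolyteSpec, logp: float, ph: float) -> float:
    """Distribution coefficient log D at the given pH.

    Assumes only the neutral microspecies partitions into octanol, so
    log D = log P - log10(1 + sum of ionized/neutral ratios). log D <= log P
    always, with equality approached when every group is fully neutral.
    """
    ratios = _log10_ion_ratios(spec, float(ph))
    # log10(1 + sum 10^r) via logsumexp over [0, r...] in base e
    terms = np.array([0.0] + ratios) * math.log(10.0)
    correction = logsumexp(terms) / math.log(10.0)
    return float(logp - correction)


def bjerrum_curve(spec: ProtolyteSpec, ph_grid: Sequence[float]) -> np.ndarray:
    """Mean number of bound protons as a function of pH.

    Computed from the macroscopic pKa set via species fractions; the curve is
    monotone non-increasing in pH and bounded by [0, n_protons].
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise InvalidInputError("ph_grid must be non-empty")
    n = spec.n_protons
    pkas = spec.pka_values
    if spec.kind is ProtolyteKind.AMPHOLYTE:
        # deprotonation order for the Bjerrum count: acid group first
        pkas = tuple(sorted(pkas))
    # log-concentration of species with j protons bound relative to the fully
    # protonated form: logc_j = sum_{i=1..n-j} (pH - pKa_i)
    logc = np.zeros((n + 1, ph.size))
    for j in range(n - 1, -1, -1):
        logc[j] = logc[j + 1] + (ph - pkas[n - j - 1])
    ln10 = math.log(10.0)
    log_total = logsumexp(logc * ln10, axis=0)
    frac = np.exp(logc * ln10 - log_total)
    nbar = (np.arange(n + 1)[:, None] * frac).sum(axis=0)
    return nbar
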