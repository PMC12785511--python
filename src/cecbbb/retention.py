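"""CEC retention factors and electroosmotic-flow summaries.

In open-tubular capillary electrochromatography with a liposome-coated
capillary, an ionized analyte's migration is driven by the electroosmotic
flow, its own electrophoretic mobility, and its interaction with the
liposomal layer. The permeability retention factor k' isolates the last
contribution by combining migration times measured in the coated capillary
(analyte t_R, neutral EOF marker t_EOF) with the corresponding times in an
uncoated capillary (t_R', t_EOF'):

    k' = t_R * (1/t_EOF + 1/t_R' - 1/t_EOF') - 1

which is the classical (t_R - t0)/t0 retention factor with the unretained
time t0 reconstructed from the uncoated-run mobilities,
t0 = (1/t_EOF + 1/t_R' - 1/t_EOF')^-1. k' is dimensionless and may be
slightly negative for effectively unretained analytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class CapillaryGeometry:
    """Capillary dimensions and applied voltage.

    Defaults mirror a 59.1 cm x 50 um fused-silica capillary with a 49 cm
    effective (inlet-to-detector) length run at 20 kV.
    """

    total_length: float = 0.591  # m
    effective_length: float = 0.49  # m
    voltage: float = 20000.0  # V

    def __post_init__(self) -> None:
        if not (0 < self.effective_length < self.total_length):
            raise InvalidInputError(
                "effective_length must satisfy 0 < effective_length < total_length"
            )
        if self.voltage <= 0:
            raise InvalidInputError("voltage must be positive")


@dataclass(frozen=True)
class MigrationRecord:
    """One compound's migration times (seconds) in coated and uncoated runs."""

    compound_id: str
    t_r: float  # analyte, coated
    t_eof: float  # EOF marker, coated
    t_r_unc: float  # analyte, uncoated
    t_eof_unc: float  # EOF marker, uncoated

    def __post_init__(self) -> None:
        for name in ("t_r", "t_eof", "t_r_unc", "t_eof_unc"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InvalidInputError(
                    f"{name} must be a finite positive time in seconds, got {v!r}"
                )


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    rsd_percent: float
    n: int


@dataclass(frozen=True)
class RetentionResult:
    compound_id: str
    k_prime: float
    replicate_mean: float
    replicate_sd: float
    n_replicates: int


@dataclass(frozen=True)
class EofSuppressionReport:
    """Coated-vs-uncoated EOF mobility comparison."""

    table: pd.DataFrame  # rows: variant; cols: mean, rsd_percent, n
    suppressed: bool


def dead_time(rec: MigrationRecord) -> float:
    """Unretained migration time t0 reconstructed from uncoated-run mobilities."""
    inv = 1.0 / rec.t_eof + 1.0 / rec.t_r_unc - 1.0 / rec.t_eof_unc
    if inv <= 0:
        raise InvalidInputError(
            f"{rec.compound_id}: reconstructed dead time is non-positive "
            "(pathological uncoated mobility); k' is undefined"
        )
    return 1.0 / inv


def retention_factor(rec: MigrationRecord) -> float:
    """Permeability retention factor k' = (t_R - t0)/t0 for one replicate."""
    t0 = dead_time(rec)
    return rec.t_r / t0 - 1.0


def eof_mobility(t_eof: float, geom: CapillaryGeometry = CapillaryGeometry()) -> float:
    """Electroosmotic mobility from the neutral-marker migration time.

    mu_EOF = (L_eff * L_tot) / (V * t_EOF), in m^2 s^-1 V^-1.
    """
    if t_eof is None or not math.isfinite(t_eof) or t_eof <= 0:
        raise InvalidInputError(f"t_eof must be a finite positive time, got {t_eof!r}")
    return geom.effective_length * geom.total_length / (geom.voltage * t_eof)


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean, sample SD (n-1 denominator, 0 for a single value) and RSD%.

    RSD is 100*sd/|mean|; a zero mean with nonzero spread has no defined RSD.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("at least one replicate value is required")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("replicate values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if mean == 0.0:
        if sd == 0.0:
            rsd = 0.0
        else:
            raise InvalidInputError("RSD undefined: replicate mean is zero")
    else:
        rsd = 100.0 * sd / abs(mean)
    return ReplicateSummary(mean=mean, sd=sd, rsd_percent=rsd, n=int(arr.size))


def eof_suppression_report(
    uncoated: Iterable[float], coated: Iterable[float]
) -> EofSuppressionReport:
    """Compare EOF mobilities between capillary variants.

    Takes raw mobility replicates (m^2 s^-1 V^-1) per variant and flags
    suppression when the coated mean falls below the uncoated mean, the
    signature of a successful liposome coating.
    """
    rows = {}
    for name, vals in (("uncoated", uncoated), ("coated", coated)):
        s = summarize_replicates(list(vals))
        rows[name] = {"mean": s.mean, "rsd_percent": s.rsd_percent, "n": s.n}
    table = pd.DataFrame.from_dict(rows, orient="index")
    suppressed = bool(rows["coated"]["mean"] < rows["uncoated"]["mean"])
    return EofSuppressionReport(table=table, suppressed=suppressed)


def kprime_from_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run migration times into per-compound k' statistics.

    ``runs`` has one row per run: compound_id, variant {coated|uncoated},
    t_analyte, t_eof, unit {s|min}. Replicates are paired by order within each
    compound (i-th coated run with i-th uncoated run), so both variants must
    have the same replicate count per compound.

    Returns a frame with compound_id, k_prime_mean, k_prime_sd, n.
    """
    required = {"compound_id", "variant", "t_analyte", "t_eof"}
    missing = required - set(runs.columns)
    if missing:
        raise InvalidInputError(f"runs table missing columns: {sorted(missing)}")
    df = runs.copy()
    if "unit" in df.columns:
        factor = df["unit"].map({"s": 1.0, "min": 60.0})
        if factor.isna().any():
            bad = df.loc[factor.isna(), "unit"].unique()
            raise InvalidInputError(f"unknown time unit(s): {list(bad)}")
        df["t_analyte"] = df["t_analyte"] * factor
        df["t_eof"] = df["t_eof"] * factor

    out = []
    for cid, grp in df.groupby("compound_id", sort=True):
        coated = grp[grp["variant"] == "coated"]
        unc = grp[grp["variant"] == "uncoated"]
        if len(coated) == 0 or len(unc) == 0:
            raise InvalidInputError(f"{cid}: both capillary variants are required")
        if len(coated) != len(unc):
            raise InvalidInputError(
                f"{cid}: unequal replicate counts ({len(coated)} coated, "
                f"{len(unc)} uncoated); replicates are paired by order"
            )
        ks = [
            retention_factor(
                MigrationRecord(
                    compound_id=cid,
                    t_r=c.t_analyte,
                    t_eof=c.t_eof,
                    t_r_unc=u.t_analyte,
                    t_eof_unc=u.t_eof,
                )
            )
            for c, u in zip(coated.itertuples(), unc.itertuples())
        ]
        s = summarize_replicates(ks)
        out.append(
            {"compound_id": cid, "k_prime_mean": s.mean, "k_prime_sd": s.sd, "n": s.n}
        )
    return pd.DataFrame(out)
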