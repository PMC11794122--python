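"""Forward and inverse qPCR standard-curve machinery.

The assay quantifies DNA by real-time PCR against a dilution series of a
known template. The curve is the line Ct = slope·X + intercept with
X = −log10(dilution), so larger X means more dilute and the slope is
positive. The published C1C2 curve is Ct = 4.059·X + 8.144; a slope of
log2(10) ≈ 3.32 would correspond to perfect per-cycle doubling, so 4.059
implies a sub-ideal amplification efficiency of ~76%.

Forward simulation adds Gaussian cycle noise and censors at a maximum
cycle count: wells whose Ct would exceed ``max_cycles`` — and wells with
no template at all — come back *undetermined*, mirroring "no amplification
curve" instrument output. Undetermined wells are excluded (never imputed)
from fitting and quantification.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QPCRWell",
    "REFERENCE_CURVE",
    "DEFAULT_MAX_CYCLES",
    "DEFAULT_NOISE_SD",
    "simulate_ct",
    "fit_standard_curve",
    "invert_ct",
    "estimate_lod",
    "amplification_efficiency",
    "read_plate",
    "write_plate",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_CYCLES = 40.0
DEFAULT_NOISE_SD = 0.2  # cycles, typical replicate scatter


@dataclass(frozen=True)
class StandardCurve:
    """Ct = slope·X + intercept with X = −log10(dilution)."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    x_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope == 0:
            raise ValueError(f"slope must be finite and nonzero, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "x_range": list(self.x_range) if self.x_range else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardCurve":
        d = json.loads(Path(path).read_text())
        xr = tuple(d["x_range"]) if d.get("x_range") else None
        return cls(slope=d["slope"], intercept=d["intercept"], r_squared=d.get("r_squared", 1.0), x_range=xr)


REFERENCE_CURVE = StandardCurve(slope=4.059, intercept=8.144)


@dataclass(frozen=True)
class QPCRWell:
    """One well: ``ct is None`` encodes an undetermined (censored) well."""

    well_id: str
    target: str
    ct: float | None
    dilution_x: float | None = None

    @property
    def determined(self) -> bool:
        return self.ct is not None


def simulate_ct(
    x: float,
    curve: StandardCurve,
    noise_sd: float = DEFAULT_NOISE_SD,
    max_cycles: float = DEFAULT_MAX_CYCLES,
    seed: int | np.random.Generator | None = None,
    well_id: str = "A1",
    target: str = "C1C2",
) -> QPCRWell:
    """Draw one well's Ct at dilution exponent ``x``.

    ``x = inf`` represents a zero-template well and is always undetermined.
    Otherwise ct = slope·x + intercept + N(0, noise_sd²), censored to
    undetermined above ``max_cycles``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if math.isinf(x):
        return QPCRWell(well_id=well_id, target=target, ct=None, dilution_x=None)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ct = curve.slope * x + curve.intercept
    if noise_sd > 0:
        ct += rng.normal(0.0, noise_sd)
    if ct > max_cycles or ct <= 0:
        return QPCRWell(well_id=well_id, target=target, ct=None, dilution_x=x)
    return QPCRWell(well_id=well_id, target=target, ct=float(ct), dilution_x=x)


def _as_points(series: Iterable) -> list[tuple[float, float | None]]:
    pts = []
    for item in series:
        if isinstance(item, QPCRWell):
            pts.append((item.dilution_x, item.ct))
        else:
            x, ct = item
            pts.append((float(x), None if ct is None or (isinstance(ct, float) and math.isnan(ct)) else float(ct)))
    return pts


def fit_standard_curve(series: Iterable) -> StandardCurve:
    """Ordinary least squares fit of Ct against X over a dilution series.

    Accepts ``(x, ct)`` pairs or :class:`QPCRWell` objects; undetermined
    wells are dropped with a logged count. Requires at least two distinct
    x values with determined Ct.
    """
    pts = _as_points(series)
    n_undet = sum(1 for _, ct in pts if ct is None)
    if n_undet:
        logger.info("fit_standard_curve: excluding %d undetermined well(s)", n_undet)
    xs = np.array([x for x, ct in pts if ct is not None], dtype=float)
    ys = np.array([ct for _, ct in pts if ct is not None], dtype=float)
    if len(xs) < 2 or np.unique(xs).size < 2:
        raise ValueError(
            f"standard-curve fit needs >= 2 determined wells at distinct dilutions; "
            f"got {len(xs)} determined point(s) at {np.unique(xs).size} dilution(s)"
        )
    res = stats.linregress(xs, ys)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_range=(float(xs.min()), float(xs.max())),
    )


def invert_ct(ct: float, curve: StandardCurve) -> float:
    """Dilution exponent X = (Ct − intercept)/slope for a determined well.

    Logs a warning when the result extrapolates beyond the fitted range.
    """
    if ct is None:
        raise ValueError("cannot invert an undetermined Ct")
    x = (ct - curve.intercept) / curve.slope
    if curve.x_range is not None and not (curve.x_range[0] <= x <= curve.x_range[1]):
        logger.warning("invert_ct: x = %.4g extrapolates outside fitted range %s", x, curve.x_range)
    return x


def estimate_lod(
    levels: Mapping[float, Sequence[QPCRWell]],
    descending_concentration: bool = True,
) -> float | None:
    """Limit of detection: the most dilute level where every replicate amplified.

    Keys are concentrations by default (smaller = more dilute); pass
    ``descending_concentration=False`` for keys that are dilution exponents
    (larger = more dilute). Returns ``None`` when no level qualifies.
    """
    if not levels:
        raise ValueError("estimate_lod requires at least one dilution level")
    qualified = [
        level
        for level, wells in levels.items()
        if wells and all(w.determined for w in wells)
    ]
    if not qualified:
        return None
    return min(qualified) if descending_concentration else max(qualified)


def amplification_efficiency(curve: StandardCurve) -> float:
    """Per-cycle efficiency E = 10^(1/|slope|) − 1 (1.0 = perfect doubling)."""
    if curve.slope == 0:
        raise ZeroDivisionError("efficiency undefined for zero slope")
    return 10.0 ** (1.0 / abs(curve.slope)) - 1.0


def write_plate(wells: Iterable[QPCRWell], path: str | Path) -> None:
    """Persist wells as CSV (columns well,target,ct,dilution_x; NA = undetermined)."""
    df = pd.DataFrame(
        {
            "well": [w.well_id for w in wells],
            "target": [w.target for w in wells],
            "ct": [w.ct for w in wells],
            "dilution_x": [w.dilution_x for w in wells],
        }
    )
    df.to_csv(path, index=False, na_rep="NA")


def read_plate(path: str | Path) -> list[QPCRWell]:
    """Read a plate CSV written by :func:`write_plate`."""
    df = pd.read_csv(path, na_values=["NA"])
    wells = []
    for row in df.itertuples(index=False):
        ct = None if pd.isna(row.ct) else float(row.ct)
        dx = None if pd.isna(row.dilution_x) else float(row.dilution_x)
        wells.append(QPCRWell(well_id=str(row.well), target=str(row.target), ct=ct, dilution_x=dx))
    return wells
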