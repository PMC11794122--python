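"""Synthetic generator for EV labeling experiments.

Emulates the wet-lab chain the assay quantifies: a vesicle population with
a tumor/normal mixture and heterogeneous surface-antigen copy numbers,
stochastic labeling with antibody-DNA conjugates (three DNA reporters per
bound conjugate by default), and bead capture → wash → elution with
independent per-vesicle losses. The output carries the exact ground-truth
DNA concentration in the eluate, which downstream stages are tested
against.

Populations are held as pandas DataFrames, one row per vesicle:

* population frame — ``is_tumor``, ``antigen_copies``
* labeled frame   — adds ``bound_1``, ``bound_2``, ``dna_strands``

All randomness flows through a single ``numpy.random.Generator``; equal
seeds give bit-identical output. Concentrations are nM internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "EVPopulationParams",
    "AssaySample",
    "simulate_population",
    "label_population",
    "capture_wash_elute",
    "strands_to_nM",
]

AVOGADRO = 6.02214076e23

POPULATION_COLUMNS = ["is_tumor", "antigen_copies"]
LABELED_COLUMNS = POPULATION_COLUMNS + ["bound_1", "bound_2", "dna_strands"]


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EVPopulationParams:
    """Parameters of a simulated vesicle population.

    ``antigen_mean`` and ``antigen_dispersion`` parameterize a negative
    binomial (mean / size) for antigen copies on tumor vesicles; normal
    vesicles carry none. ``antigen_fixed`` replaces the negative binomial
    with a constant copy number (deterministic scenarios).
    """

    n_ev: int = 10_000
    tumor_fraction: float = 0.3
    antigen_mean: float = 50.0
    antigen_dispersion: float = 5.0
    nonspecific_rate: float = 0.05
    seed: int | None = None
    antigen_fixed: bool = False

    def __post_init__(self) -> None:
        if self.n_ev < 0:
            raise ValueError(f"n_ev must be >= 0, got {self.n_ev}")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError(f"tumor_fraction must be in [0, 1], got {self.tumor_fraction}")
        if self.antigen_mean < 0:
            raise ValueError(f"antigen_mean must be >= 0, got {self.antigen_mean}")
        if self.antigen_dispersion <= 0:
            raise ValueError(f"antigen_dispersion must be > 0, got {self.antigen_dispersion}")
        if self.nonspecific_rate < 0:
            raise ValueError(f"nonspecific_rate must be >= 0, got {self.nonspecific_rate}")


@dataclass(frozen=True)
class AssaySample:
    """Eluate after capture/wash: surviving vesicles plus ground truth."""

    ev_records: pd.DataFrame
    eluate_volume: float  # µL
    dna_conc_true: float = field(init=False)  # nM

    def __post_init__(self) -> None:
        if self.eluate_volume <= 0:
            raise ValueError(f"eluate_volume must be > 0 µL, got {self.eluate_volume}")
        total = float(self.ev_records["dna_strands"].sum()) if len(self.ev_records) else 0.0
        object.__setattr__(self, "dna_conc_true", strands_to_nM(total, self.eluate_volume))


def strands_to_nM(n_strands: float, volume_ul: float) -> float:
    """Concentration (nM) of ``n_strands`` molecules in ``volume_ul`` µL."""
    if volume_ul <= 0:
        raise ValueError(f"volume must be > 0 µL, got {volume_ul}")
    moles = n_strands / AVOGADRO
    litres = volume_ul * 1e-6
    return moles / litres * 1e9


def simulate_population(params: EVPopulationParams) -> pd.DataFrame:
    """Draw a vesicle population: tumor flags and antigen copy numbers.

    Tumor vesicles draw copies from NegativeBinomial(mean, size) — the
    over-dispersed distribution typical of surface-marker counts — or carry
    exactly ``antigen_mean`` copies when ``antigen_fixed``. Normal vesicles
    have zero copies.
    """
    rng = _as_rng(params.seed)
    n = params.n_ev
    is_tumor = rng.random(n) < params.tumor_fraction
    copies = np.zeros(n, dtype=np.int64)
    n_tumor = int(is_tumor.sum())
    if n_tumor and params.antigen_mean > 0:
        if params.antigen_fixed:
            copies[is_tumor] = int(round(params.antigen_mean))
        else:
            m, r = params.antigen_mean, params.antigen_dispersion
            copies[is_tumor] = rng.negative_binomial(n=r, p=r / (r + m), size=n_tumor)
    return pd.DataFrame({"is_tumor": is_tumor, "antigen_copies": copies})


def label_population(
    pop: pd.DataFrame,
    p_bind: float,
    dual_label: bool = False,
    nonspecific_rate: float = 0.0,
    dna_per_conjugate: int = 3,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach antibody-DNA conjugates to a vesicle population.

    Each antigen copy is bound with probability ``p_bind``; bound conjugates
    split evenly between the two conjugate types when ``dual_label`` (the
    proximity-ligation configuration), otherwise all are type 1. On top,
    each vesicle picks up Poisson(``nonspecific_rate``) spurious conjugates.
    Every bound conjugate carries ``dna_per_conjugate`` DNA reporters
    (3 for the one-antibody/three-DNA design).
    """
    if not 0.0 <= p_bind <= 1.0:
        raise ValueError(f"p_bind must be in [0, 1], got {p_bind}")
    if nonspecific_rate < 0:
        raise ValueError(f"nonspecific_rate must be >= 0, got {nonspecific_rate}")
    if dna_per_conjugate < 0:
        raise ValueError(f"dna_per_conjugate must be >= 0, got {dna_per_conjugate}")
    rng = _as_rng(seed)
    copies = pop["antigen_copies"].to_numpy()
    specific = rng.binomial(copies, p_bind)
    spurious = rng.poisson(nonspecific_rate, size=len(pop))
    total = specific + spurious
    if dual_label:
        bound_1 = rng.binomial(total, 0.5)
        bound_2 = total - bound_1
    else:
        bound_1, bound_2 = total, np.zeros_like(total)
    out = pop.copy()
    out["bound_1"] = bound_1
    out["bound_2"] = bound_2
    out["dna_strands"] = dna_per_conjugate * total
    return out


def capture_wash_elute(
    labeled: pd.DataFrame,
    capture_eff: float = 0.7,
    wash_retention: float = 0.9,
    eluate_volume: float = 100.0,
    seed: int | np.random.Generator | None = None,
) -> AssaySample:
    """Thin the labeled population through bead capture and washing.

    Each vesicle independently survives with probability
    ``capture_eff × wash_retention`` (independent Bernoulli thinning);
    survivors are eluted into ``eluate_volume`` µL, from which the
    ground-truth DNA concentration is computed.
    """
    for name, p in (("capture_eff", capture_eff), ("wash_retention", wash_retention)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = _as_rng(seed)
    keep = rng.random(len(labeled)) < capture_eff * wash_retention
    survivors = labeled.loc[keep].reset_index(drop=True)
    return AssaySample(ev_records=survivors, eluate_volume=eluate_volume)
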