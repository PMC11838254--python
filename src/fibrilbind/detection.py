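"""PET detection-limit calculations for radioligand-labeled fibrils.

A scanner voxel registers a fibril-containing region when the emission rate
from that region reaches the detector limit M (counts per unit time per unit
volume).  Fibrils at tissue concentration [F], each with n_L bound
radioligands decaying at rate lambda, emit lambda * n_L * [F]; detection
therefore requires n_L >= n_C = M / (lambda [F]).  Because every fibril
offers N >> n_C sites, the free-ligand concentration needed for detection
can sit far below the per-site KD even without cooperativity — PET is a
labeling problem, not an occupancy problem.

Two criteria are exposed: the time-averaged mean criterion <n_L> >= n_C
(measurement slower than binding equilibration) and the instantaneous tail
probability P(n_L >= n_C) from the exact bound-count distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import FibrilConfig, LatticeModel, occupancy_distribution

__all__ = [
    "DetectionSpec",
    "DetectionReport",
    "decay_rate_from_half_life",
    "half_life_from_decay_rate",
    "critical_occupancy",
    "min_detectable_conc",
    "detection_probability",
]


def decay_rate_from_half_life(t_half: float) -> float:
    """``lambda = ln 2 / t_half`` (same time units)."""
    if not (t_half > 0):
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def half_life_from_decay_rate(decay_rate: float) -> float:
    if not (decay_rate > 0):
        raise ValueError(f"decay rate must be positive, got {decay_rate}")
    return math.log(2.0) / decay_rate


@dataclass(frozen=True)
class DetectionSpec:
    """Scanner threshold, tracer decay, and fibril load defining a detection problem.

    Units must be mutually consistent: ``detector_limit`` in counts per unit
    time per unit volume, ``decay_rate`` per unit time, ``fibril_conc`` in
    fibrils per unit volume (molar works if M is per-mole-of-voxel-volume;
    only ratios matter).
    """

    detector_limit: float
    decay_rate: float
    fibril_conc: float
    n_sites: int

    def __post_init__(self) -> None:
        for name in ("detector_limit", "decay_rate", "fibril_conc"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (isinstance(self.n_sites, (int, np.integer)) and self.n_sites >= 1):
            raise ValueError("n_sites must be a positive integer")

    @classmethod
    def from_half_life(cls, detector_limit: float, t_half: float,
                       fibril_conc: float, n_sites: int) -> "DetectionSpec":
        return cls(detector_limit, decay_rate_from_half_life(t_half),
                   fibril_conc, n_sites)


@dataclass
class DetectionReport:
    """Tail probability plus the time-averaged (mean) criterion."""

    probability: float
    mean_count: float
    critical_count: float
    mean_criterion: bool


def critical_occupancy(spec: DetectionSpec) -> float:
    """Critical bound-site count ``n_C = M / (lambda [F])``."""
    return spec.detector_limit / (spec.decay_rate * spec.fibril_conc)


def min_detectable_conc(kd: float, n_c: float, n_sites: int) -> float:
    """Minimum free-ligand concentration for mean-criterion detection,
    non-cooperative case: ``[L]_min = KD n_C / (N - n_C)``.

    Always below KD when ``n_C < N/2``; diverges as ``n_C -> N``.
    """
    if not (kd > 0):
        raise ValueError(f"kd must be positive, got {kd}")
    if not (0 < n_c < n_sites):
        raise ValueError(
            f"need 0 < n_c < n_sites; got n_c={n_c}, N={n_sites} "
            "(the fibril cannot emit enough counts)"
        )
    return kd * n_c / (n_sites - n_c)


def detection_probability(
    model: LatticeModel, config: FibrilConfig, n_c: float, species: str = "L"
) -> DetectionReport:
    """Probability that a single fibril clears the detection threshold now.

    ``P(n_L >= n_C)`` from the exact bound-count distribution of the lattice
    model; for a non-cooperative 2-state model this is the binomial survival
    function with ``p = [L]/(KD + [L])``.  Infeasible thresholds
    (``n_C > N``) give probability 0.
    """
    if n_c < 0:
        raise ValueError(f"n_c must be non-negative, got {n_c}")
    dist = occupancy_distribution(model, config, species=species)
    counts = np.arange(len(dist))
    mean_count = float(counts @ dist)
    k_min = int(math.ceil(n_c))
    prob = float(dist[k_min:].sum()) if k_min <= config.n_sites else 0.0
    return DetectionReport(
        probability=prob,
        mean_count=mean_count,
        critical_count=float(n_c),
        mean_criterion=bool(mean_count >= n_c),
    )
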