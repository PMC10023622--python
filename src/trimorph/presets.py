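"""Packaged default cohort calibration targets.

``COHORT_TARGETS`` holds the fresh/defrosted mean and SD of every reported
index of the ex-vivo porcine cohort (n = 10) that the synthetic replica is
calibrated against.  ``CONTROLLABLE_METRICS`` are the ones the generators
can dial in directly; cardiac output is derived from the imposed stroke
volume and the tricuspid regurgitant fraction and is therefore reported but
not independently calibrated.
"""

from __future__ import annotations

from .synth_valve import CohortConfig, MetricTarget

__all__ = [
    "COHORT_TARGETS",
    "CONTROLLABLE_METRICS",
    "default_cohort_config",
]

COHORT_TARGETS: dict[str, MetricTarget] = {
    # fluid dynamics
    "BF15": MetricTarget(0.4, 0.3, 1.7, 0.9),  # L/min at 15 mmHg
    "BF30": MetricTarget(1.0, 0.5, 3.5, 1.6),  # L/min at 30 mmHg
    "TRF": MetricTarget(67.1, 8.5, 84.0, 4.0),  # %
    "CO": MetricTarget(1.7, 0.9, 0.9, 0.9),  # L/min (derived, see module docstring)
    "PRV": MetricTarget(7.9, 2.1, 8.3, 2.6),  # mL
    # morphometrics
    "Dmax": MetricTarget(50.2, 3.6, 51.7, 2.4),  # mm
    "Dmin": MetricTarget(43.1, 3.5, 45.1, 3.6),  # mm
    "L2D": MetricTarget(149.2, 10.0, 153.7, 8.1),  # mm
    "L3D": MetricTarget(152.8, 10.1, 156.9, 7.6),  # mm
    "A2D": MetricTarget(1735.9, 234.1, 1861.5, 210.7),  # mm^2
    "A3D": MetricTarget(1808.0, 238.0, 1919.7, 197.9),  # mm^2
    "Tvol": MetricTarget(6.0, 0.8, 13.3, 4.5),  # mL
    "RV_volume": MetricTarget(185.8, 40.8, 202.0, 36.4),  # mL
}

# metrics the synthetic generators can prescribe directly
CONTROLLABLE_METRICS = (
    "BF15",
    "BF30",
    "TRF",
    "PRV",
    "Dmax",
    "Dmin",
    "Tvol",
    "RV_volume",
)


def default_cohort_config(
    seed: int = 0,
    n_samples: int = 10,
    paired_correlation: float = 0.8,
    match_moments: bool = True,
    metrics: tuple[str, ...] = CONTROLLABLE_METRICS,
) -> CohortConfig:
    """Cohort configuration carrying the packaged calibration targets."""
    return CohortConfig(
        targets={m: COHORT_TARGETS[m] for m in metrics},
        n_samples=n_samples,
        paired_correlation=paired_correlation,
        seed=seed,
        match_moments=match_moments,
    )
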