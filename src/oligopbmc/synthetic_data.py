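"""Synthetic plate-data generator with the study's hierarchical structure.

The raw ELISA plate data behind the published condition estimates were never
deposited, so this module generates datasets with the same statistical
anatomy: per-horse random intercepts and random slopes (LPS, GOS, FOS, AOS),
log-normal well noise, triplicate wells, and left-censoring at the assay
detection limits.  The default condition means are anchored to the published
per-condition point estimates (blank TNF-alpha around 12.6 pg/ml, LPS-alone
around 1749.4 pg/ml, the non-monotone GOS/FOS/AOS dose response, flat IL-10
in unchallenged cells) so simulated datasets look like the study, but they
are synthetic calibration targets, not recovered ground truth.

Reproducibility contract: one master seed per dataset; each (horse, analyte)
pair gets a deterministic substream keyed by its identifier, so adding a horse
leaves existing horses' wells unchanged.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .hier_model import N_RANEFF, z_vector
from .study_data import DETECTION_LIMITS, StudyDesign, WellMeasurement

__all__ = [
    "GenerativeParams",
    "default_generative_params",
    "simulate_dataset",
    "simulate_viability",
]

_PSD_TOL = 1e-10


@dataclass
class GenerativeParams:
    """Ground-truth parameters for the synthetic generator.

    ``beta`` maps (condition label, analyte) to the mean log response
    (natural log of pg/ml for cytokines, of relative absorbance for
    viability).  ``sigma`` is the well-level log-scale SD and ``Sigma_b`` the
    5x5 covariance of per-horse random effects for the cytokine models; the
    viability model has its own, smaller noise scales.
    """

    beta: dict[tuple[str, str], float]
    sigma: float = 0.4
    Sigma_b: np.ndarray = field(
        default_factory=lambda: np.diag([0.25, 0.30, 0.10, 0.30, 0.20]) ** 2
    )
    replicates: int = 3
    seed: int = 0
    viability_sigma: float = 0.10
    viability_Sigma_b: np.ndarray = field(
        default_factory=lambda: np.diag([0.05, 0.0, 0.02, 0.05, 0.05]) ** 2
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.viability_sigma <= 0:
            raise ValueError("well-level sigma must be > 0")
        if self.replicates not in (3, 4):
            raise ValueError("replicates per (horse, condition) must be 3 or 4")
        for name in ("Sigma_b", "viability_Sigma_b"):
            _check_psd(getattr(self, name), name)


def _check_psd(cov: np.ndarray, name: str) -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (N_RANEFF, N_RANEFF):
        raise ValueError(f"{name} must be {N_RANEFF}x{N_RANEFF}")
    if not np.allclose(cov, cov.T):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
        raise ValueError(f"{name} must be positive semi-definite")


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    return v * np.sqrt(np.clip(w, 0.0, None))


def _horse_rng(seed: int, horse_id: str, analyte: str) -> np.random.Generator:
    key = zlib.crc32(f"{horse_id}:{analyte}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# anchor condition means (response scale).  Cytokine anchors follow the
# published per-condition point estimates; sugar-control cytokine anchors and
# all viability anchors follow the published relative effects (percent changes
# vs blank / LPS-alone / next-lower dose).
_TNF_UNCHALLENGED = {
    "blank": 12.6,
    "GOS 0.5%": 19.7, "GOS 1.0%": 24.9, "GOS 2.0%": 35.5,
    "GOS/FOS 0.5%": 30.2, "GOS/FOS 1.0%": 63.4, "GOS/FOS 2.0%": 127.5,
    "GOS/FOS/AOS 0.5%": 73.6, "GOS/FOS/AOS 1.0%": 133.5, "GOS/FOS/AOS 2.0%": 61.4,
    # +53% / +97% / +84% vs blank
    "glucose/lactose 0.5%": 12.6 * 1.53,
    "glucose/lactose 1.0%": 12.6 * 1.97,
    "glucose/lactose 2.0%": 12.6 * 1.84,
}
_TNF_LPS = {
    "LPS": 1749.4,
    "LPS + GOS 0.5%": 3655.5, "LPS + GOS 1.0%": 4989.0, "LPS + GOS 2.0%": 7754.3,
    "LPS + GOS/FOS 0.5%": 3601.1, "LPS + GOS/FOS 1.0%": 5530.3,
    "LPS + GOS/FOS 2.0%": 6721.1,
    "LPS + GOS/FOS/AOS 0.5%": 4242.9, "LPS + GOS/FOS/AOS 1.0%": 3317.6,
    "LPS + GOS/FOS/AOS 2.0%": 1029.7,
    # 0.5% indistinguishable from LPS alone; then +24% and +42% dose steps
    "LPS + glucose/lactose 0.5%": 1749.4 * 1.15,
    "LPS + glucose/lactose 1.0%": 1749.4 * 1.15 * 1.24,
    "LPS + glucose/lactose 2.0%": 1749.4 * 1.15 * 1.24 * 1.42,
}
_IL10_UNCHALLENGED = {
    "blank": 187.2,
    "GOS 0.5%": 183.1, "GOS 1.0%": 184.2, "GOS 2.0%": 179.8,
    "GOS/FOS 0.5%": 185.5, "GOS/FOS 1.0%": 190.2, "GOS/FOS 2.0%": 186.0,
    "GOS/FOS/AOS 0.5%": 205.2, "GOS/FOS/AOS 1.0%": 214.2, "GOS/FOS/AOS 2.0%": 186.8,
}
_IL10_LPS = {
    "LPS": 278.1,
    "LPS + GOS 0.5%": 293.8, "LPS + GOS 1.0%": 268.8, "LPS + GOS 2.0%": 265.6,
    "LPS + GOS/FOS 0.5%": 344.1, "LPS + GOS/FOS 1.0%": 307.4,
    "LPS + GOS/FOS 2.0%": 264.0,
    "LPS + GOS/FOS/AOS 0.5%": 374.3, "LPS + GOS/FOS/AOS 1.0%": 269.6,
    "LPS + GOS/FOS/AOS 2.0%": 180.7,
}
# sugar-control IL-10 sat mostly below the 156.25 pg/ml detection limit
_IL10_SUGAR_MEAN = 120.0
# viability multipliers relative to blank: the triple blend raises apparent
# viability 38-61%, glucose/lactose at the middle dose a mild 14%
_VIABILITY = {
    "blank": 1.0,
    "GOS 0.5%": 1.0, "GOS 1.0%": 1.0, "GOS 2.0%": 1.0,
    "GOS/FOS 0.5%": 1.0, "GOS/FOS 1.0%": 1.0, "GOS/FOS 2.0%": 1.0,
    "GOS/FOS/AOS 0.5%": 1.38, "GOS/FOS/AOS 1.0%": 1.50, "GOS/FOS/AOS 2.0%": 1.61,
    "glucose/lactose 0.5%": 1.0, "glucose/lactose 1.0%": 1.14,
    "glucose/lactose 2.0%": 1.0,
}


def default_generative_params(seed: int = 0) -> GenerativeParams:
    """Generator defaults anchored to the published condition estimates."""
    beta: dict[tuple[str, str], float] = {}
    for table, analyte in (
        (_TNF_UNCHALLENGED, "TNFa"), (_TNF_LPS, "TNFa"),
        (_IL10_UNCHALLENGED, "IL10"), (_IL10_LPS, "IL10"),
    ):
        for label, mean in table.items():
            beta[(label, analyte)] = math.log(mean)
    for conc in ("0.5", "1.0", "2.0"):
        beta[(f"glucose/lactose {conc}%", "IL10")] = math.log(_IL10_SUGAR_MEAN)
        beta[(f"LPS + glucose/lactose {conc}%", "IL10")] = math.log(_IL10_SUGAR_MEAN)
    for label, mult in _VIABILITY.items():
        beta[(label, "viability")] = math.log(mult)
    return GenerativeParams(beta=beta, seed=seed)


def _simulate_arms(
    design: StudyDesign,
    params: GenerativeParams,
    arms: list[str],
    analytes: list[str],
    sigma: float,
    Sigma_b: np.ndarray,
) -> list[WellMeasurement]:
    _check_psd(Sigma_b, "Sigma_b")
    sqrt_cov = _psd_sqrt(Sigma_b)
    wells: list[WellMeasurement] = []
    for arm in arms:
        conditions = design.conditions_for_arm(arm)
        for horse in design.horses_in_arm(arm):
            for analyte in analytes:
                rng = _horse_rng(params.seed, horse, analyte)
                b_h = sqrt_cov @ rng.standard_normal(N_RANEFF)
                limit = design.detection_limits.get(analyte)
                for cond in conditions:
                    key = (cond.label, analyte)
                    if key not in params.beta:
                        raise KeyError(f"no generative mean for {key}")
                    mu = params.beta[key] + float(z_vector(cond) @ b_h)
                    for rep in range(1, params.replicates + 1):
                        value = math.exp(mu + sigma * rng.standard_normal())
                        censored = limit is not None and value < limit
                        wells.append(
                            WellMeasurement(
                                horse_id=horse,
                                condition=cond.label,
                                analyte=analyte,
                                replicate=rep,
                                value=limit if censored else value,
                                below_detection=censored,
                            )
                        )
    return wells


def simulate_dataset(
    design: StudyDesign, params: GenerativeParams
) -> list[WellMeasurement]:
    """Simulate the cytokine plates (both cytokine arms, TNF-alpha and IL-10).

    For each horse h draw b_h ~ MVN(0, Sigma_b); each well's log value is
    beta[condition, analyte] + z(condition) . b_h + Normal(0, sigma).  Values
    below the analyte detection limit are truncated to the limit and flagged.
    """
    return _simulate_arms(
        design, params,
        arms=["oligosaccharide", "sugar_control"],
        analytes=["TNFa", "IL10"],
        sigma=params.sigma, Sigma_b=params.Sigma_b,
    )


def simulate_viability(
    design: StudyDesign, params: GenerativeParams
) -> list[WellMeasurement]:
    """Simulate the viability plates (relative absorbance, blank mean 1.0)."""
    if not design.horses_in_arm("viability"):
        raise ValueError("study design has no viability-arm horses")
    return _simulate_arms(
        design, params,
        arms=["viability"],
        analytes=["viability"],
        sigma=params.viability_sigma, Sigma_b=params.viability_Sigma_b,
    )
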