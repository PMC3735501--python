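"""Bayesian hierarchical linear regression for log-scale plate data.

Model (per analyte, natural-log scale):

    log y_i | beta, b, sigma2  ~  Normal( x_i' beta + z_i' b_{h(i)}, sigma2 )
    b_h                        ~  MVN( 0, Sigma_b ),   h = 1..H horses
    beta_j                     ~  Normal( 0, 100^2 )
    sigma2                     ~  Inverse-Gamma with mean 1, variance 10,000
    Sigma_b                    ~  scaled inverse-Wishart

with a cell-means fixed-effect design (x_i selects the well's condition) and a
5-column random-effect design z_i = (1, LPS indicator, GOS %, FOS %, AOS %):
a random intercept for overall PBMC reactivity and random slopes for the
reactivity to each named exposure.  The scaled inverse-Wishart is the
parameter-expanded construction Sigma_b = diag(xi) Omega diag(xi) with
Omega ~ Inverse-Wishart(I_5, df 6) and independent mean-zero normal priors on
the expansion scales xi (so |xi_k| is half-normal); it keeps every conditional
conjugate while breaking the inverse-Wishart's prior tie between scale and
correlation.

Wells below the assay detection limit enter via data augmentation: their
latent log concentration is a model parameter bounded above by the log limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .study_data import (
    DETECTION_LIMITS,
    IncubationCondition,
    WellMeasurement,
    condition_by_label,
)

__all__ = [
    "RANDOM_EFFECT_NAMES",
    "DesignMatrices",
    "ObservedData",
    "PriorSpec",
    "ModelState",
    "z_vector",
    "build_design",
    "extract_observations",
    "derive_invgamma_hyperparams",
    "log_posterior",
]

#: Random-effect columns, in order.
RANDOM_EFFECT_NAMES = ("intercept", "LPS", "GOS", "FOS", "AOS")
N_RANEFF = len(RANDOM_EFFECT_NAMES)


def z_vector(cond: IncubationCondition) -> np.ndarray:
    """Random-effect design row: (1, LPS present, GOS %, FOS %, AOS %).

    LPS enters as a presence indicator (only 0 and 1 ug/ml occur); the
    oligosaccharide columns are component doses in % w/v, so sugar-control
    conditions share the structure with zero oligosaccharide entries.
    """
    return np.array(
        [1.0, 1.0 if cond.has_lps else 0.0, cond.gos_pct, cond.fos_pct, cond.aos_pct]
    )


@dataclass
class DesignMatrices:
    """Design matrices for one analyte's model.

    ``X`` is wells x conditions (cell means: exactly one 1 per row), ``Z``
    wells x 5, ``horse_index`` maps wells to 0-based horse slots.
    """

    X: np.ndarray
    Z: np.ndarray
    horse_index: np.ndarray
    condition_labels: list[str]
    horse_ids: list[str]
    analyte: str

    @property
    def n_wells(self) -> int:
        return self.X.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.X.shape[1]

    @property
    def n_horses(self) -> int:
        return len(self.horse_ids)

    @property
    def condition_index(self) -> np.ndarray:
        """Per-well condition column (the argmax of each indicator row)."""
        return self.X.argmax(axis=1)


@dataclass
class ObservedData:
    """Aligned observation arrays for one analyte's model.

    ``y_log`` holds the observed log value; for censored wells it holds the
    log detection limit, which is the upper bound for the latent value.
    """

    y_log: np.ndarray
    is_censored: np.ndarray
    analyte: str

    @property
    def n_wells(self) -> int:
        return self.y_log.shape[0]


def build_design(
    measurements: list[WellMeasurement],
    catalogue: list[IncubationCondition],
    analyte: str | None = None,
) -> DesignMatrices:
    """Build cell-means and random-effect design matrices for one analyte.

    Analytes are modelled separately; pass ``analyte`` to select, or leave
    ``None`` when the measurement list already holds a single analyte.
    Conditions absent from the data get no column.
    """
    analytes = {m.analyte for m in measurements}
    if analyte is None:
        if len(analytes) != 1:
            raise ValueError(
                f"measurements mix analytes {sorted(analytes)}; pass analyte="
            )
        analyte = analytes.pop()
    wells = [m for m in measurements if m.analyte == analyte]
    if not wells:
        raise ValueError(f"no measurements for analyte {analyte!r}")
    known = {c.label for c in catalogue}
    unknown = sorted({m.condition for m in wells} - known)
    if unknown:
        raise ValueError(f"conditions not in catalogue: {unknown}")
    labels = sorted({m.condition for m in wells},
                    key=[c.label for c in catalogue].index)
    label_col = {lab: j for j, lab in enumerate(labels)}
    horse_ids = sorted({m.horse_id for m in wells})
    horse_slot = {h: i for i, h in enumerate(horse_ids)}
    n = len(wells)
    X = np.zeros((n, len(labels)))
    Z = np.zeros((n, N_RANEFF))
    horse_index = np.zeros(n, dtype=np.intp)
    for i, m in enumerate(wells):
        X[i, label_col[m.condition]] = 1.0
        Z[i] = z_vector(condition_by_label(catalogue, m.condition))
        horse_index[i] = horse_slot[m.horse_id]
    return DesignMatrices(
        X=X, Z=Z, horse_index=horse_index,
        condition_labels=labels, horse_ids=horse_ids, analyte=analyte,
    )


def extract_observations(
    measurements: list[WellMeasurement],
    analyte: str,
    detection_limits: dict[str, float] | None = None,
) -> ObservedData:
    """Log-transform one analyte's values, keeping censoring bounds."""
    if detection_limits is None:
        detection_limits = DETECTION_LIMITS
    wells = [m for m in measurements if m.analyte == analyte]
    if not wells:
        raise ValueError(f"no measurements for analyte {analyte!r}")
    limit = detection_limits.get(analyte)
    y = np.empty(len(wells))
    cens = np.zeros(len(wells), dtype=bool)
    for i, m in enumerate(wells):
        if m.below_detection:
            if limit is None:
                raise ValueError(f"analyte {analyte!r} has no detection limit")
            y[i] = np.log(limit)
            cens[i] = True
        else:
            y[i] = np.log(m.value)
    return ObservedData(y_log=y, is_censored=cens, analyte=analyte)


def derive_invgamma_hyperparams(mean: float, variance: float) -> tuple[float, float]:
    """Inverse-gamma (shape, scale) with the requested first two moments.

    From mean = scale/(shape-1) and variance = mean^2/(shape-2):
    shape = 2 + mean^2/variance, scale = mean * (shape - 1).
    """
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be > 0")
    shape = 2.0 + mean * mean / variance
    scale = mean * (shape - 1.0)
    return shape, scale


@dataclass
class PriorSpec:
    """Prior constants for the hierarchical model (broad, weakly informative)."""

    beta_mean: float = 0.0
    beta_sd: float = 100.0
    sigma2_mean: float = 1.0
    sigma2_variance: float = 10_000.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(N_RANEFF))
    wishart_df: float = float(N_RANEFF + 1)
    xi_sd: float = 100.0

    def __post_init__(self) -> None:
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        if self.wishart_df <= N_RANEFF - 1:
            raise ValueError("Wishart degrees of freedom must exceed dim - 1")
        if self.beta_sd <= 0 or self.xi_sd <= 0:
            raise ValueError("prior scales must be > 0")

    @property
    def sigma2_shape_scale(self) -> tuple[float, float]:
        return derive_invgamma_hyperparams(self.sigma2_mean, self.sigma2_variance)


@dataclass
class ModelState:
    """One point in parameter space (one Gibbs iteration's state)."""

    beta: np.ndarray
    b: np.ndarray           # horses x 5 random effects (= diag(xi) @ eta rows)
    sigma2: float
    xi: np.ndarray          # 5 expansion scales
    omega: np.ndarray       # 5x5 unscaled covariance, Sigma_b = D xi Omega D xi
    imputed: np.ndarray     # latent log values for censored wells (aligned, NaN elsewhere)

    @property
    def Sigma_b(self) -> np.ndarray:
        d = np.diag(self.xi)
        return d @ self.omega @ d

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


def log_posterior(
    state: ModelState,
    design: DesignMatrices,
    data: ObservedData,
    priors: PriorSpec,
) -> float:
    """Log joint density of data and parameters (up to nothing: fully normalised
    in each named factor).

    Censored wells contribute through their imputed latent log values, which
    must respect the bound ``imputed <= log limit`` stored in ``data.y_log``.
    """
    if data.n_wells != design.n_wells:
        raise ValueError("data and design have different numbers of wells")
    y = data.y_log.copy()
    if data.is_censored.any():
        imp = state.imputed[data.is_censored]
        if np.any(imp > data.y_log[data.is_censored] + 1e-12):
            raise ValueError("imputed censored values exceed the detection bound")
        y[data.is_censored] = imp
    if not (
        np.all(np.isfinite(state.beta))
        and np.all(np.isfinite(state.b))
        and np.isfinite(state.sigma2)
    ):
        raise ValueError("non-finite model state")
    mu = design.X @ state.beta + np.einsum(
        "ij,ij->i", design.Z, state.b[design.horse_index]
    )
    lp = stats.norm.logpdf(y, loc=mu, scale=np.sqrt(state.sigma2)).sum()
    if design.n_horses > 0:
        lp += stats.multivariate_normal.logpdf(
            state.b, mean=np.zeros(N_RANEFF), cov=state.Sigma_b
        ).sum()
    lp += stats.norm.logpdf(state.beta, priors.beta_mean, priors.beta_sd).sum()
    shape, scale = priors.sigma2_shape_scale
    lp += stats.invgamma.logpdf(state.sigma2, shape, scale=scale)
    lp += stats.invwishart.logpdf(state.omega, priors.wishart_df, priors.wishart_scale)
    lp += stats.norm.logpdf(state.xi, 0.0, priors.xi_sd).sum()
    return float(lp)
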