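"""Gibbs sampler for the hierarchical log-normal plate model.

Every full conditional in the model is available in closed form, so the
sampler is a pure Gibbs cycle with no accept/reject step:

* ``beta | rest`` — independent normals (the cell-means design makes X'X
  diagonal);
* ``eta_h | rest`` — one 5-dimensional multivariate normal per horse, where
  ``b_h = diag(xi) eta_h`` is the parameter-expanded random effect;
* ``xi_k | rest`` — scalar normals (each expansion scale enters the mean
  linearly given eta);
* ``sigma2 | rest`` — inverse gamma;
* ``Omega | eta`` — inverse Wishart (sampled by Bartlett decomposition);
* censored latents — upper-truncated normals at the log detection limit.

Chains are run from overdispersed starts with deterministic per-chain
substreams of a single master seed, burn-in is discarded and the remainder
thinned, and convergence is assessed with the Gelman–Rubin potential scale
reduction factor computed on the saved draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .hier_model import (
    N_RANEFF,
    RANDOM_EFFECT_NAMES,
    DesignMatrices,
    ObservedData,
    PriorSpec,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "run_chains",
    "psrf",
    "check_convergence",
]

#: Sampling protocol of the original analysis: four chains of one million
#: iterations, every 50th kept, first half discarded.
FULL_PROTOCOL_ITERATIONS = 1_000_000
FULL_PROTOCOL_THIN = 50
#: Desk-scale profile used by default in tests and examples.
SCALED_DOWN_ITERATIONS = 20_000
SCALED_DOWN_THIN = 10


@dataclass
class MCMCConfig:
    """Chain layout.  Leave ``n_iterations``/``thin`` unset to get the full
    protocol, or set ``scaled_down=True`` for the 4 x 20,000 desk profile."""

    n_chains: int = 4
    n_iterations: int | None = None
    thin: int | None = None
    burn_in_fraction: float = 0.5
    seed: int = 0
    scaled_down: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations is None:
            self.n_iterations = SCALED_DOWN_ITERATIONS if self.scaled_down else FULL_PROTOCOL_ITERATIONS
        if self.thin is None:
            self.thin = SCALED_DOWN_THIN if self.scaled_down else FULL_PROTOCOL_THIN
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_saved_per_chain < 1:
            raise ValueError(
                "no draws remain after burn-in and thinning; "
                "increase n_iterations or reduce thin"
            )

    @property
    def n_burn(self) -> int:
        return int(self.n_iterations * self.burn_in_fraction)

    @property
    def n_saved_per_chain(self) -> int:
        n_burn = int(self.n_iterations * self.burn_in_fraction)
        return (self.n_iterations - n_burn + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Saved posterior draws, per parameter, chains x saved iterations."""

    beta: np.ndarray                    # chains x saved x conditions
    sigma2: np.ndarray                  # chains x saved
    Sigma_b: np.ndarray | None          # chains x saved x 5 x 5 (None without raneff)
    condition_labels: list[str]
    analyte: str
    config: MCMCConfig
    sigma2_fixed: bool = False

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_saved(self) -> int:
        return self.beta.shape[1]

    def parameter_names(self) -> list[str]:
        """Registry of monitored scalar parameters."""
        names = [f"beta[{lab}]" for lab in self.condition_labels]
        if not self.sigma2_fixed:
            names.append("sigma2")
        if self.Sigma_b is not None:
            names += [f"Sigma_b[{n},{n}]" for n in RANDOM_EFFECT_NAMES]
        return names

    def get(self, name: str) -> np.ndarray:
        """Chains x saved array for one monitored scalar parameter."""
        if name.startswith("beta[") and name.endswith("]"):
            label = name[5:-1]
            try:
                j = self.condition_labels.index(label)
            except ValueError:
                raise KeyError(f"no condition {label!r} in draws") from None
            return self.beta[:, :, j]
        if name == "sigma2":
            return self.sigma2
        if name.startswith("Sigma_b[") and name.endswith("]"):
            row, col = name[8:-1].split(",")
            i = RANDOM_EFFECT_NAMES.index(row)
            j = RANDOM_EFFECT_NAMES.index(col)
            if self.Sigma_b is None:
                raise KeyError("model was fitted without random effects")
            return self.Sigma_b[:, :, i, j]
        raise KeyError(f"unknown parameter {name!r}")

    def beta_draws(self, condition: str) -> np.ndarray:
        """Pooled (flattened across chains) draws of one condition's log mean."""
        return self.get(f"beta[{condition}]").reshape(-1)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            beta=self.beta,
            sigma2=self.sigma2,
            Sigma_b=self.Sigma_b if self.Sigma_b is not None else np.empty(0),
            condition_labels=np.array(self.condition_labels),
            analyte=self.analyte,
            seed=self.config.seed,
            n_chains=self.config.n_chains,
            n_iterations=self.config.n_iterations,
            thin=self.config.thin,
            burn_in_fraction=self.config.burn_in_fraction,
            sigma2_fixed=self.sigma2_fixed,
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            config = MCMCConfig(
                n_chains=int(z["n_chains"]),
                n_iterations=int(z["n_iterations"]),
                thin=int(z["thin"]),
                burn_in_fraction=float(z["burn_in_fraction"]),
                seed=int(z["seed"]),
            )
            sig = z["Sigma_b"]
            return cls(
                beta=z["beta"],
                sigma2=z["sigma2"],
                Sigma_b=None if sig.size == 0 else sig,
                condition_labels=[str(s) for s in z["condition_labels"]],
                analyte=str(z["analyte"]),
                config=config,
                sigma2_fixed=bool(z["sigma2_fixed"]),
            )


@dataclass
class ConvergenceReport:
    """Potential scale reduction factors for every monitored parameter."""

    psrf: dict[str, float]
    threshold: float = 1.1

    @property
    def passed(self) -> bool:
        return all(r <= self.threshold for r in self.psrf.values())

    def failing(self) -> list[str]:
        return [p for p, r in self.psrf.items() if r > self.threshold]


def psrf(draws: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``draws`` is chains x n.  R-hat = sqrt( ((n-1)/n * W + B/n) / W ) with W
    the mean within-chain sample variance and B = n * variance of the chain
    means (both with the n-1 denominator).  The classical (non-split)
    diagnostic, computed on the saved post-thinning draws.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("psrf needs >= 2 chains with >= 2 draws each")
    m, n = draws.shape
    within = draws.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("degenerate chains: zero within-chain variance")
    between = n * draws.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * within + between / n) / within))


def check_convergence(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """PSRF for every monitored parameter; pass iff all are <= threshold."""
    if draws.n_chains < 2:
        raise ValueError("convergence assessment needs >= 2 chains")
    report = {name: psrf(draws.get(name)) for name in draws.parameter_names()}
    return ConvergenceReport(psrf=report, threshold=threshold)


# ---------------------------------------------------------------------------
# sampler internals


_TRIL = {p: np.tril_indices(p, -1) for p in (N_RANEFF,)}


def _bartlett_wishart(rng: np.random.Generator, df: float, p: int) -> np.ndarray:
    """Lower-triangular Bartlett factor A with W = A A' ~ Wishart(df, I_p)."""
    A = np.zeros((p, p))
    np.fill_diagonal(A, np.sqrt(rng.chisquare(df - np.arange(p))))
    tril = _TRIL.get(p) or np.tril_indices(p, -1)
    A[tril] = rng.standard_normal(len(tril[0]))
    return A


def _sample_inv_wishart(
    rng: np.random.Generator, df: float, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Omega ~ Inverse-Wishart(df, S); returns (Omega, Omega^-1).

    Omega^-1 ~ Wishart(df, S^-1) by Bartlett decomposition; the precision is
    returned alongside because the Gibbs cycle needs it on the next sweep.
    """
    p = S.shape[0]
    S_inv = np.linalg.inv(S)
    S_inv = 0.5 * (S_inv + S_inv.T)
    Lv = np.linalg.cholesky(S_inv)
    A = _bartlett_wishart(rng, df, p)
    F = Lv @ A
    W = F @ F.T
    omega = np.linalg.inv(W)
    return 0.5 * (omega + omega.T), W


class _ChainWorkspace:
    """Precomputed structures shared by all iterations of one model fit."""

    def __init__(self, design: DesignMatrices, data: ObservedData):
        if data.n_wells != design.n_wells:
            raise ValueError("data and design have different numbers of wells")
        self.n = design.n_wells
        self.p = design.n_conditions
        self.cond_idx = design.condition_index
        self.counts = np.bincount(self.cond_idx, minlength=self.p).astype(float)
        self.Z = design.Z
        self.H = design.n_horses
        self.horse_idx = design.horse_index
        # wells sorted by horse, for fast per-horse reductions
        self.order = np.argsort(self.horse_idx, kind="stable")
        sorted_h = self.horse_idx[self.order]
        self.horse_starts = np.searchsorted(sorted_h, np.arange(self.H))
        self.Z_sorted = self.Z[self.order]
        self.ZtZ = np.stack([
            self.Z_sorted[self.horse_starts[h]:self._stop(h)].T
            @ self.Z_sorted[self.horse_starts[h]:self._stop(h)]
            for h in range(self.H)
        ]) if self.H else np.empty((0, N_RANEFF, N_RANEFF))
        self.y_obs = data.y_log.copy()
        self.cens = np.flatnonzero(data.is_censored)
        self.bounds = data.y_log[data.is_censored]

    def _stop(self, h: int) -> int:
        return self.horse_starts[h + 1] if h + 1 < self.H else self.n

    def horse_sums(self, values: np.ndarray) -> np.ndarray:
        """Per-horse column sums of a wells x 5 array (sorted-order reduceat)."""
        if self.H == 0:
            return np.empty((0, N_RANEFF))
        return np.add.reduceat(values[self.order], self.horse_starts, axis=0)


def _run_single_chain(
    ws: _ChainWorkspace,
    priors: PriorSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
    random_effects: bool,
    sigma2_fixed: float | None,
):
    n, p, H = ws.n, ws.p, ws.H
    beta_prec0 = priors.beta_sd ** -2
    beta_mean0 = priors.beta_mean
    a0, b0 = priors.sigma2_shape_scale
    xi_prec0 = priors.xi_sd ** -2
    nu0 = priors.wishart_df
    S0 = priors.wishart_scale

    # --- overdispersed initialisation -------------------------------------
    y = ws.y_obs.copy()
    if ws.cens.size:
        y[ws.cens] = ws.bounds - rng.exponential(0.5, size=ws.cens.size)
    sums = np.bincount(ws.cond_idx, weights=y, minlength=p)
    cell_means = np.where(ws.counts > 0, sums / np.maximum(ws.counts, 1), beta_mean0)
    beta = cell_means + rng.normal(0.0, 1.0, size=p)
    resid0 = y - cell_means[ws.cond_idx] if n else np.empty(0)
    base_var = float(resid0 @ resid0) / max(n - p, 1) if n > p else 1.0
    sigma2 = sigma2_fixed if sigma2_fixed is not None else max(
        base_var * np.exp(rng.normal(0.0, 1.0)), 1e-4
    )
    eta = rng.standard_normal((H, N_RANEFF))
    xi = rng.normal(1.0, 0.5, size=N_RANEFF)
    omega = np.eye(N_RANEFF)
    omega_inv = np.eye(N_RANEFF)

    n_burn = config.n_burn
    n_saved = config.n_saved_per_chain
    beta_out = np.empty((n_saved, p))
    sigma2_out = np.empty(n_saved)
    sigma_b_out = np.empty((n_saved, N_RANEFF, N_RANEFF)) if random_effects else None
    save_i = 0
    eye = np.eye(N_RANEFF)

    for t in range(config.n_iterations):
        sigma = np.sqrt(sigma2)
        if random_effects and H:
            U = ws.Z * xi                      # wells x 5
            re = np.einsum("ij,ij->i", U, eta[ws.horse_idx])
        else:
            re = 0.0

        # censored latents: upper-truncated normal at the log detection limit
        if ws.cens.size:
            mu_c = beta[ws.cond_idx[ws.cens]] + (
                re[ws.cens] if np.ndim(re) else 0.0
            )
            alpha = (ws.bounds - mu_c) / sigma
            pr = ndtr(alpha)
            u = rng.random(ws.cens.size) * pr
            ok = u > 1e-250
            draw = np.where(ok, ndtri(np.maximum(u, 1e-250)), 0.0)
            y_new = mu_c + sigma * draw
            # far-tail fallback: exponential approximation hugging the bound
            far = ~ok
            if far.any():
                rate = np.maximum(-alpha[far], 1.0) / sigma
                y_new[far] = ws.bounds[far] - rng.exponential(1.0 / rate)
            y[ws.cens] = y_new

        # beta | rest: independent normals (diagonal cell-means precision)
        part = y - re if np.ndim(re) else y
        s = np.bincount(ws.cond_idx, weights=part, minlength=p)
        prec = ws.counts / sigma2 + beta_prec0
        mean = (s / sigma2 + beta_prec0 * beta_mean0) / prec
        beta = mean + rng.standard_normal(p) / np.sqrt(prec)

        if random_effects and H:
            r = y - beta[ws.cond_idx]
            # eta_h | rest: MVN per horse, batched across horses
            Zr = ws.horse_sums(ws.Z * r[:, None])          # H x 5
            xixi = np.outer(xi, xi)
            A = xixi * ws.ZtZ / sigma2 + omega_inv          # H x 5 x 5
            rhs = xi * Zr / sigma2                          # H x 5
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    f"non-positive-definite conditional covariance "
                    f"at iteration {t}"
                ) from exc
            Lt = np.transpose(L, (0, 2, 1))
            w = np.linalg.solve(L, rhs[:, :, None])
            mean_all = np.linalg.solve(Lt, w)
            noise = np.linalg.solve(Lt, rng.standard_normal((H, N_RANEFF, 1)))
            eta = (mean_all + noise)[:, :, 0]

            # xi_k | rest: scalar normals, running residual update
            C = ws.Z * eta[ws.horse_idx]                   # wells x 5
            resid = r - C @ xi
            for k in range(N_RANEFF):
                ck = C[:, k]
                resid_k = resid + xi[k] * ck
                prec_k = ck @ ck / sigma2 + xi_prec0
                mean_k = (ck @ resid_k) / sigma2 / prec_k
                xi_k = mean_k + rng.standard_normal() / np.sqrt(prec_k)
                resid = resid_k - xi_k * ck
                xi[k] = xi_k
        else:
            resid = y - beta[ws.cond_idx] if n else np.empty(0)

        # sigma2 | rest: inverse gamma
        if sigma2_fixed is None:
            a_post = a0 + 0.5 * n
            b_post = b0 + 0.5 * float(resid @ resid)
            sigma2 = b_post / rng.gamma(a_post)
        if not np.isfinite(sigma2) or sigma2 <= 0:
            raise RuntimeError(f"invalid sigma2 at iteration {t}")

        # Omega | eta: inverse Wishart
        if random_effects and H:
            S_post = S0 + eta.T @ eta
            omega, omega_inv = _sample_inv_wishart(rng, nu0 + H, S_post)

        if t >= n_burn and (t - n_burn) % config.thin == 0:
            beta_out[save_i] = beta
            sigma2_out[save_i] = sigma2
            if sigma_b_out is not None:
                d = np.diag(xi)
                sigma_b_out[save_i] = d @ omega @ d
            save_i += 1

    if not (np.all(np.isfinite(beta_out)) and np.all(np.isfinite(sigma2_out))):
        raise RuntimeError("non-finite draws produced")
    return beta_out, sigma2_out, sigma_b_out


def run_chains(
    design: DesignMatrices,
    data: ObservedData,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    random_effects: bool = True,
    sigma2_fixed: float | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler: several chains, burn-in discarded, thinned.

    Chains differ only in their seed substream and overdispersed start
    (cell-mean initial values jittered, variance parameters log-jittered).
    Set ``random_effects=False`` for a fixed-effects-only model and
    ``sigma2_fixed`` to condition on a known well-level variance.
    """
    if priors is None:
        priors = PriorSpec()
    if config is None:
        config = MCMCConfig(scaled_down=True)
    if random_effects and design.n_horses == 0:
        raise ValueError("random effects requested but design has no horses")
    ws = _ChainWorkspace(design, data)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    betas, sigma2s, sigmabs = [], [], []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        b, s2, sb = _run_single_chain(
            ws, priors, config, rng, random_effects, sigma2_fixed
        )
        betas.append(b)
        sigma2s.append(s2)
        sigmabs.append(sb)
    return PosteriorDraws(
        beta=np.stack(betas),
        sigma2=np.stack(sigma2s),
        Sigma_b=np.stack(sigmabs) if random_effects else None,
        condition_labels=list(design.condition_labels),
        analyte=design.analyte,
        config=config,
        sigma2_fixed=sigma2_fixed is not None,
    )
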