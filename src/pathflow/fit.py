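"""Box-constrained least-squares fitting of the pathway-activity model.

The objective sums squared residuals over every observed (sample, drug)
pair:

    SSE(theta) = sum_{s,d} ( sum_j (m_sj A_m[j] + v_sj A_v[j])
                             * (1 - rho[j,d] alpha[d])
                             - sens[s,d] - b[d] )^2

with A_m, A_v in [-5, 5], rho in [0, 1], b in [-20, 20], and alpha in
[0, 1] (the drug effect is a fractional inhibition; the source model
states no explicit bound, so the natural fraction range is adopted).
The global link scale k is fixed at 1 and does not enter the objective.

The objective is a smooth quartic and non-convex, so it is minimized by
multi-start L-BFGS-B with analytic gradients; the lowest-SSE restart wins.

Identifiability
---------------
theta enters the objective only through the per-(gene, drug) products
A_m[j]*(1 - rho[j,d] alpha[d]) and A_v[j]*(1 - rho[j,d] alpha[d]) plus the
intercepts b.  Two degeneracies follow: (i) rho[j,d] and alpha[d] appear
only as the product rho*alpha, and (ii) each gene carries a scale freedom
t_j > 0 mapping A -> t*A, (1 - rho*alpha) -> (1 - rho*alpha)/t without
changing any residual (while bounds permit).  ``canonical_products``
removes both by reporting, per gene, the unique representative on the
optimum manifold whose least-influenced drug has rho*alpha = 0 — the
natural convention when every gene has at least one drug whose targets it
cannot reach.  Recovery experiments compare canonicalized products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import AlterationProfile, ModelParameters, ResponseTable

__all__ = [
    "BOUNDS",
    "FitConfig",
    "FitResult",
    "count_free_parameters",
    "pack_parameters",
    "unpack_parameters",
    "objective",
    "fit",
    "rmse_from_sse",
    "canonical_products",
]

#: box constraints per parameter block: (low, high)
BOUNDS = {
    "A": (-5.0, 5.0),
    "rho": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "b": (-20.0, 20.0),
}


@dataclass
class FitConfig:
    """Optimizer settings.

    ``rho_init`` selects how the influence coefficients are initialized:
    uniform random in [0, 1] (default), the constant 1/2, or a topology
    prior matrix supplied via ``rho_prior``.  Restart r uses RNG seed
    ``seed + r``.
    """

    bounds: dict = field(default_factory=lambda: dict(BOUNDS))
    n_restarts: int = 10
    seed: int = 0
    max_iterations: int = 5000
    tolerance: float = 1e-12
    rho_init: str = "uniform_random"
    rho_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.rho_init not in ("uniform_random", "topology_prior", "constant_half"):
            raise ValueError(f"unknown rho_init {self.rho_init!r}")
        if self.rho_init == "topology_prior" and self.rho_prior is None:
            raise ValueError("rho_init='topology_prior' needs rho_prior")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")


@dataclass
class FitResult:
    """Best-of-restarts fit with provenance.

    ``rmse = sqrt(sse / n_terms)`` is the per-observation error on the
    sensitivity scale.  ``per_restart_sse`` and ``converged`` are aligned
    with restart index; ``residuals`` is the (samples x drugs) residual
    matrix, NaN at unobserved cells.
    """

    params: ModelParameters
    sse: float
    rmse: float
    n_terms: int
    per_restart_sse: list[float]
    converged: list[bool]
    seed: int
    residuals: np.ndarray | None = None


def count_free_parameters(n_genes: int, n_drugs: int) -> int:
    """Number of free model parameters: 2*G + G*D + D.

    Per-gene mutation and copy-number contributions (2*G), per-(gene, drug)
    influence products (G*D) and per-drug intercepts (D).  The raw
    optimizer vector carries 2*G + G*D + 2*D entries because rho and alpha
    are kept separate for interpretability, but the D drug effects are
    redundant with the influence coefficients (only the products rho*alpha
    are constrained), so they do not add to the free-parameter count.
    """
    if n_genes < 0 or n_drugs < 0:
        raise ValueError("counts must be non-negative")
    return 2 * n_genes + n_genes * n_drugs + n_drugs


def rmse_from_sse(sse: float, n_terms: int) -> float:
    """Per-observation (root-mean-square) error, sqrt(SSE / N)."""
    if n_terms <= 0:
        raise ValueError("n_terms must be positive")
    return sqrt(sse / n_terms)


# ---------------------------------------------------------------------------
# parameter vector layout: [A_m (G) | A_v (G) | rho gene-major (G*D) |
#                           alpha (D) | b (D)]
# ---------------------------------------------------------------------------


def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten ModelParameters into the optimizer vector (layout above)."""
    return np.concatenate(
        [params.A_m, params.A_v, params.rho.ravel(), params.alpha, params.b]
    )


def unpack_parameters(
    vector: np.ndarray, genes: Sequence[str], drugs: Sequence[str], k: float = 1.0
) -> ModelParameters:
    """Inverse of :func:`pack_parameters`."""
    vector = np.asarray(vector, dtype=float).ravel()
    G, D = len(genes), len(drugs)
    expected = 2 * G + G * D + 2 * D
    if vector.shape[0] != expected:
        raise ValueError(
            f"vector length {vector.shape[0]} != expected {expected} "
            f"for {G} genes, {D} drugs"
        )
    A_m = vector[:G]
    A_v = vector[G : 2 * G]
    rho = vector[2 * G : 2 * G + G * D].reshape(G, D)
    alpha = vector[2 * G + G * D : 2 * G + G * D + D]
    b = vector[2 * G + G * D + D :]
    return ModelParameters(tuple(genes), tuple(drugs), A_m, A_v, rho, alpha, b, k)


def _aligned_arrays(profile: AlterationProfile, responses: ResponseTable):
    if profile.samples != responses.samples:
        common = [s for s in profile.samples if s in set(responses.samples)]
        if not common:
            raise ValueError("profile and responses share no samples")
        pidx = [profile.samples.index(s) for s in common]
        ridx = [responses.samples.index(s) for s in common]
        M = profile.m[pidx].astype(float)
        V = profile.v[pidx].astype(float)
        sens = responses.sens[ridx]
        mask = responses.observed[ridx]
    else:
        M = profile.m.astype(float)
        V = profile.v.astype(float)
        sens = responses.sens
        mask = responses.observed
    if not mask.any(axis=0).all():
        bad = [responses.drugs[d] for d in np.flatnonzero(~mask.any(axis=0))]
        raise ValueError(f"drug(s) with no observed sensitivity: {bad}")
    return M, V, np.where(mask, sens, 0.0), mask.astype(float)


def _make_objective(M, V, sens, mask, G, D) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Vectorized SSE and analytic gradient over the flat vector."""

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        A_m = x[:G]
        A_v = x[G : 2 * G]
        rho = x[2 * G : 2 * G + G * D].reshape(G, D)
        alpha = x[2 * G + G * D : 2 * G + G * D + D]
        b = x[2 * G + G * D + D :]

        B = M * A_m[None, :] + V * A_v[None, :]          # (S, G) per-gene terms
        W = 1.0 - rho * alpha[None, :]                   # (G, D) attenuation
        R = (B @ W - sens - b[None, :]) * mask           # residuals, masked
        sse = float((R * R).sum())

        MtR = M.T @ R                                    # (G, D)
        VtR = V.T @ R
        BtR = B.T @ R
        g_Am = 2.0 * (MtR * W).sum(axis=1)
        g_Av = 2.0 * (VtR * W).sum(axis=1)
        g_rho = -2.0 * BtR * alpha[None, :]
        g_alpha = -2.0 * (BtR * rho).sum(axis=0)
        g_b = -2.0 * R.sum(axis=0)
        grad = np.concatenate([g_Am, g_Av, g_rho.ravel(), g_alpha, g_b])
        return sse, grad

    return fun


def objective(
    vector: np.ndarray, profile: AlterationProfile, responses: ResponseTable
) -> float:
    """SSE of the model at a flat parameter vector (observed pairs only)."""
    G = profile.n_genes
    D = len(responses.drugs)
    vector = np.asarray(vector, dtype=float).ravel()
    expected = 2 * G + G * D + 2 * D
    if vector.shape[0] != expected:
        raise ValueError(f"vector length {vector.shape[0]} != {expected}")
    M, V, sens, mask = _aligned_arrays(profile, responses)
    return _make_objective(M, V, sens, mask, G, D)(vector)[0]


def objective_gradient(
    vector: np.ndarray, profile: AlterationProfile, responses: ResponseTable
) -> np.ndarray:
    """Analytic gradient of :func:`objective` (same layout as the vector)."""
    G = profile.n_genes
    D = len(responses.drugs)
    M, V, sens, mask = _aligned_arrays(profile, responses)
    return _make_objective(M, V, sens, mask, G, D)(np.asarray(vector, float))[1]


def _bounds_vector(config: FitConfig, G: int, D: int):
    lo_A, hi_A = config.bounds["A"]
    lo_r, hi_r = config.bounds["rho"]
    lo_a, hi_a = config.bounds["alpha"]
    lo_b, hi_b = config.bounds["b"]
    return (
        [(lo_A, hi_A)] * (2 * G)
        + [(lo_r, hi_r)] * (G * D)
        + [(lo_a, hi_a)] * D
        + [(lo_b, hi_b)] * D
    )


def _initial_point(
    rng: np.random.Generator, config: FitConfig, G: int, D: int, b0: np.ndarray
) -> np.ndarray:
    A = rng.uniform(-1.0, 1.0, size=2 * G)
    if config.rho_init == "uniform_random":
        rho = rng.uniform(0.0, 1.0, size=G * D)
    elif config.rho_init == "constant_half":
        rho = np.full(G * D, 0.5)
    else:
        rho = np.clip(np.asarray(config.rho_prior, float).reshape(G, D), 0, 1).ravel()
    alpha = rng.uniform(0.0, 1.0, size=D)
    return np.concatenate([A, rho, alpha, b0])


def fit(
    profile: AlterationProfile,
    responses: ResponseTable,
    config: FitConfig | None = None,
) -> FitResult:
    """Multi-start box-constrained fit; returns the lowest-SSE restart.

    Each restart r draws its starting point from a generator seeded with
    ``config.seed + r``: A_m, A_v ~ U(-1, 1), alpha ~ U(0, 1), rho per
    ``rho_init``, and b[d] at its unconditional optimum -mean(sens_d)
    (clipped to bounds), which removes a large nuisance mode.
    """
    if config is None:
        config = FitConfig()
    G = profile.n_genes
    D = len(responses.drugs)
    M, V, sens, mask = _aligned_arrays(profile, responses)
    n_terms = int(mask.sum())
    fun = _make_objective(M, V, sens, mask, G, D)
    bounds = _bounds_vector(config, G, D)
    lo_b, hi_b = config.bounds["b"]
    with np.errstate(invalid="ignore"):
        b0 = np.clip(-mask_mean(sens, mask), lo_b, hi_b)

    best_x = None
    best_sse = np.inf
    per_restart_sse: list[float] = []
    converged: list[bool] = []
    failures: list[str] = []
    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + r)
        x0 = _initial_point(rng, config, G, D, b0)
        try:
            res = minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": config.max_iterations,
                    "ftol": config.tolerance,
                    "gtol": 1e-10,
                },
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            failures.append(f"restart {r}: {exc}")
            per_restart_sse.append(np.nan)
            converged.append(False)
            continue
        sse_r = float(res.fun)
        if not np.isfinite(sse_r):
            failures.append(f"restart {r}: non-finite objective")
            per_restart_sse.append(np.nan)
            converged.append(False)
            continue
        per_restart_sse.append(sse_r)
        converged.append(bool(res.success))
        if sse_r < best_sse:
            best_sse = sse_r
            best_x = res.x
    if best_x is None:
        raise RuntimeError(
            "optimizer failed on every restart: " + "; ".join(failures)
        )
    if failures:
        warnings.warn(
            f"{len(failures)} of {config.n_restarts} restarts failed; "
            "keeping successful ones",
            stacklevel=2,
        )
    params = unpack_parameters(best_x, profile.genes, responses.drugs)
    # residual matrix at the optimum, NaN where unobserved
    B = M * params.A_m[None, :] + V * params.A_v[None, :]
    W = 1.0 - params.rho * params.alpha[None, :]
    R = B @ W - sens - params.b[None, :]
    residuals = np.where(mask.astype(bool), R, np.nan)
    return FitResult(
        params=params,
        sse=best_sse,
        rmse=rmse_from_sse(best_sse, n_terms),
        n_terms=n_terms,
        per_restart_sse=per_restart_sse,
        converged=converged,
        seed=config.seed,
        residuals=residuals,
    )


def mask_mean(sens: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column means of ``sens`` over masked-in entries."""
    counts = mask.sum(axis=0)
    return (sens * mask).sum(axis=0) / np.where(counts > 0, counts, 1)


def canonical_products(params: ModelParameters) -> np.ndarray:
    """Canonical representative of the rho*alpha products.

    Moves along the per-gene scale freedom of the optimum manifold to the
    point where each gene's smallest product is exactly 0 (its
    least-influenced drug does not reach it at all).  For gene j with
    products P_jd = rho[j,d]*alpha[d], the representative is

        P'_jd = 1 - (1 - P_jd) / (1 - min_d P_jd).

    Genes with min_d P_jd = 1 (every drug fully blocks; scale fully
    degenerate) are returned unchanged.
    """
    P = params.products()
    t = 1.0 - P.min(axis=1, keepdims=True)
    safe = t > 1e-12
    return np.where(safe, 1.0 - (1.0 - P) / np.where(safe, t, 1.0), P)
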