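"""Synthetic alteration / response data drawn from the model itself.

The generator emulates the structure of a cancer-cell-line pharmacogenomic
screen restricted to one signaling pathway: a sparse binary mutation
matrix and copy-number matrix over ~13 driver genes and ~450 cell lines,
IC50-scale sensitivities for 10 drugs with ~15% of (line, drug) cells
unscreened, and ground-truth parameters within the fitting bounds.
Sensitivities follow the generative link exactly,

    sens[s, d] = dA[s, d](theta*) - b*[d] + N(0, noise_sd^2),

so at noise_sd = 0 the true parameters attain objective 0.  The default
noise level (1.7753) matches the residual scale of the real MAPK-pathway
fit, so synthetic difficulty mirrors the real problem's.

Alterations are independent Bernoulli per (sample, gene): co-occurrence
structure such as BRAF/RAS mutual exclusivity is deliberately not
modelled (the model itself assumes independent per-gene contributions);
an optional exclusivity flag exists for stress-testing collinearity.

Identifiability by construction: the truth's influence matrix rho* is
sparse, with each gene guaranteed at least one drug of influence 0 —
realistic (most drugs cannot reach most genes) and exactly the convention
under which canonicalized products are comparable to the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import (
    AlterationProfile,
    DrugPanel,
    DrugRecord,
    ModelParameters,
    PathwayGraph,
    ResponseTable,
)

__all__ = ["SimConfig", "default_param_sampler", "generate", "fixture_mapk"]


def default_param_sampler(
    rng: np.random.Generator, genes, drugs
) -> ModelParameters:
    """Draw ground-truth parameters within the fitting bounds.

    Activity contributions get magnitude U(0.5, 3) with random sign (a
    driver gene's alteration has a non-negligible, possibly protective,
    effect); influence is sparse — rho = 0 with probability 0.35, else
    U(0.2, 1), and each gene is guaranteed one zero-influence drug; drug
    effects alpha ~ U(0.3, 1); intercepts b ~ U(-3, 3).
    """
    G, D = len(genes), len(drugs)
    A_m = rng.uniform(0.5, 3.0, G) * rng.choice([-1.0, 1.0], G)
    A_v = rng.uniform(0.5, 3.0, G) * rng.choice([-1.0, 1.0], G)
    rho = np.where(
        rng.random((G, D)) < 0.35, 0.0, rng.uniform(0.2, 1.0, (G, D))
    )
    for j in range(G):  # pin the per-gene scale: >=1 unreachable drug
        if (rho[j] > 0).all():
            rho[j, rng.integers(D)] = 0.0
    alpha = rng.uniform(0.3, 1.0, D)
    b = rng.uniform(-3.0, 3.0, D)
    return ModelParameters(tuple(genes), tuple(drugs), A_m, A_v, rho, alpha, b, 1.0)


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults mirror the MAPK scale:
    13 driver genes, 10 drugs, ~400 screened lines per drug)."""

    n_genes: int = 13
    n_drugs: int = 10
    n_samples: int = 450
    mutation_rate: float = 0.08
    cnv_rate: float = 0.05
    missing_rate: float = 0.15
    noise_sd: float = 1.7753
    exclusive_pairs: tuple[tuple[int, int], ...] = ()
    param_sampler: Callable = default_param_sampler
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "cnv_rate", "missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(
    config: SimConfig | None = None,
) -> tuple[AlterationProfile, ResponseTable, ModelParameters]:
    """Generate (profile, responses, ground-truth parameters).

    Fully deterministic given ``config.seed``.  m and v are independent
    Bernoulli; sensitivities follow the generative link at observed cells;
    the missingness mask is Bernoulli(missing_rate), re-dealt per drug if
    it would leave a drug with no observation.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    samples = tuple(f"CL{i + 1:04d}" for i in range(config.n_samples))
    genes = tuple(f"G{j + 1:02d}" for j in range(config.n_genes))
    drugs = tuple(f"D{d + 1:02d}" for d in range(config.n_drugs))

    if config.mutation_rate == 0 and config.cnv_rate == 0 and config.noise_sd == 0:
        warnings.warn("degenerate config: no alterations and no noise "
                      "(model unidentifiable)", stacklevel=2)

    m = (rng.random((config.n_samples, config.n_genes)) < config.mutation_rate)
    v = (rng.random((config.n_samples, config.n_genes)) < config.cnv_rate)
    m = m.astype(np.int8)
    v = v.astype(np.int8)
    for j1, j2 in config.exclusive_pairs:  # optional mutual exclusivity
        both = (m[:, j1] == 1) & (m[:, j2] == 1)
        m[both, j2] = 0

    params = config.param_sampler(rng, genes, drugs)
    B = m * params.A_m[None, :] + v * params.A_v[None, :]
    dA = B @ (1.0 - params.rho * params.alpha[None, :])
    noise = rng.normal(0.0, config.noise_sd, size=dA.shape) if config.noise_sd > 0 else 0.0
    sens = dA - params.b[None, :] + noise

    observed = rng.random(dA.shape) >= config.missing_rate
    for d in range(config.n_drugs):  # every drug needs >=1 observation
        if not observed[:, d].any():
            observed[rng.integers(config.n_samples), d] = True
    sens = np.where(observed, sens, np.nan)

    profile = AlterationProfile(samples, genes, m, v)
    responses = ResponseTable(samples, drugs, sens, observed)
    return profile, responses, params


# ---------------------------------------------------------------------------
# deterministic MAPK-flavoured fixture
# ---------------------------------------------------------------------------

_MAPK_GENES = (
    "BRAF", "KRAS", "NRAS", "HRAS", "EGFR", "FGFR2", "FGFR3",
    "PDGFRA", "NF1", "TP53", "MAP2K4", "AKT2", "MYC",
)

# (drug_id, name, targets) for the 10 MAPK-pathway drugs
_MAPK_PANEL = (
    ("29", "AZ628", ("BRAF",)),
    ("64", "CMK", ("RPS6KA1",)),
    ("166", "FTI-277", ("FNTA",)),
    ("204", "Tipifarnib", ("FNTA",)),
    ("1014", "RDEA119", ("MAP2K1", "MAP2K2")),
    ("1015", "CI-1040", ("MAP2K1", "MAP2K2")),
    ("1036", "PLX4720", ("BRAF",)),
    ("1060", "PD-0325901", ("MAP2K1", "MAP2K2")),
    ("1061", "SB590885", ("BRAF",)),
    ("1062", "AZD6244", ("MAP2K1", "MAP2K2")),
)

# hand-built MAPK sketch: receptors -> RAS -> BRAF -> MEK -> ERK -> effectors,
# with the stress arm MAP2K4 -> JNK and the farnesyl-transferase gene FNTA
# upstream of RAS membrane anchoring.  BRAF lies upstream of the MEK genes,
# and every path from BRAF passes through them.
_MAPK_EDGES = (
    ("EGFR", "HRAS"), ("EGFR", "KRAS"), ("EGFR", "NRAS"),
    ("FGFR2", "KRAS"), ("FGFR3", "KRAS"), ("PDGFRA", "KRAS"),
    ("NF1", "HRAS"), ("NF1", "KRAS"), ("NF1", "NRAS"),
    ("FNTA", "HRAS"), ("FNTA", "KRAS"), ("FNTA", "NRAS"),
    ("HRAS", "BRAF"), ("KRAS", "BRAF"), ("NRAS", "BRAF"),
    ("KRAS", "AKT2"),
    ("BRAF", "MAP2K1"), ("BRAF", "MAP2K2"),
    ("MAP2K1", "MAPK1"), ("MAP2K2", "MAPK1"),
    ("MAPK1", "RPS6KA1"), ("MAPK1", "MYC"),
    ("MAP2K4", "MAPK8"), ("MAPK8", "TP53"),
)

#: fixed seed of the deterministic fixture
_FIXTURE_SEED = 20150518


def fixture_mapk() -> tuple[AlterationProfile, ResponseTable, DrugPanel, PathwayGraph]:
    """Deterministic small MAPK-flavoured fixture for tests and examples.

    13 named driver genes (including BRAF, KRAS, NRAS, TP53, MAP2K4), the
    10-drug MAPK panel (3 BRAF inhibitors, 4 MEK inhibitors, one RSK
    inhibitor, two farnesyl-transferase inhibitors) and a small directed
    pathway sketch with BRAF upstream of the MEK genes.  Identical output
    on every call.
    """
    cfg = SimConfig(seed=_FIXTURE_SEED)
    profile, responses, _ = generate(cfg)
    profile = AlterationProfile(profile.samples, _MAPK_GENES, profile.m, profile.v)
    names = tuple(name for _, name, _ in _MAPK_PANEL)
    responses = ResponseTable(responses.samples, names, responses.sens, responses.observed)
    panel = DrugPanel(tuple(
        DrugRecord(did, name, frozenset(targets)) for did, name, targets in _MAPK_PANEL
    ))
    nodes: list[str] = []
    for u, w in _MAPK_EDGES:
        for n in (u, w):
            if n not in nodes:
                nodes.append(n)
    graph = PathwayGraph(tuple(nodes), _MAPK_EDGES)
    return profile, responses, panel, graph
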