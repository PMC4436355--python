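"""Forward computations of the pathway-activity model.

A cell line's genetic alterations are assumed to increase the activity of
the cancer pathways it belongs to.  For gene j with mutation indicator m_j
and copy-number indicator v_j, the per-gene activity term is

    a_j = m_j * A_m[j] + v_j * A_v[j].

Baseline (pre-treatment) increased activity is A_I = sum_j a_j.  A drug d
attenuates the fraction rho[j, d] of each gene's activity that flows
through its targets by the drug effect alpha[d], leaving

    A_T = sum_j a_j * rho[j, d] * alpha[d].

The activity difference dA = A_I - A_T is linearly linked to the observed
sensitivity, dA = k * sens + b[d].  Two drugs applied in turn, with
independent effects, leave a_j * (rho1 * alpha1) * (rho2 * alpha2), so the
combination activity reduction is

    dA(d1, d2) = sum_j a_j * (1 - rho[j,d1] alpha[d1] rho[j,d2] alpha[d2]),

which is the quantity used to rank candidate drug pairs (most negative
first: a negative reduction tracks low IC50, i.e. high sensitivity).

Genes appearing in several pathways contribute once: pathway membership is
metadata, not multiplicity, so the nominal double sum over pathways and
genes collapses to a flat sum over the union gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .data import DrugPanel, ModelParameters

__all__ = [
    "ActivityBreakdown",
    "activity_terms",
    "baseline_activity",
    "treated_activity",
    "delta_activity",
    "predicted_sensitivity",
    "combination_delta",
    "rank_combinations",
]


@dataclass(frozen=True)
class ActivityBreakdown:
    """Baseline / treated / difference activity of one sample under one drug.

    ``per_gene`` lists each gene's baseline contribution a_j; the
    contributions sum to ``baseline`` and ``delta == baseline - treated``.
    """

    baseline: float
    treated: float
    delta: float
    per_gene: tuple[tuple[str, float], ...]


def _check_row(vec: np.ndarray, params: ModelParameters, what: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float).ravel()
    if arr.shape[0] != params.n_genes:
        raise ValueError(
            f"{what} vector length {arr.shape[0]} does not match "
            f"{params.n_genes} genes of the parameter set"
        )
    return arr


def activity_terms(m: np.ndarray, v: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Per-gene activity terms a_j = m_j A_m[j] + v_j A_v[j]."""
    m = _check_row(m, params, "mutation")
    v = _check_row(v, params, "copy-number")
    return m * params.A_m + v * params.A_v


def baseline_activity(m: np.ndarray, v: np.ndarray, params: ModelParameters) -> float:
    """Increased pathway activity before treatment, A_I = sum_j a_j."""
    return float(activity_terms(m, v, params).sum())


def treated_activity(
    m: np.ndarray, v: np.ndarray, params: ModelParameters, drug: str
) -> float:
    """Increased pathway activity left after treatment with ``drug``."""
    d = params.drug_index(drug)
    a = activity_terms(m, v, params)
    return float((a * params.rho[:, d] * params.alpha[d]).sum())


def delta_activity(
    m: np.ndarray, v: np.ndarray, params: ModelParameters, drug: str
) -> ActivityBreakdown:
    """Activity difference dA = A_I - A_T with its per-gene breakdown."""
    d = params.drug_index(drug)
    a = activity_terms(m, v, params)
    baseline = float(a.sum())
    treated = float((a * params.rho[:, d] * params.alpha[d]).sum())
    delta = float((a * (1.0 - params.rho[:, d] * params.alpha[d])).sum())
    return ActivityBreakdown(
        baseline=baseline,
        treated=treated,
        delta=delta,
        per_gene=tuple(zip(params.genes, a.tolist())),
    )


def predicted_sensitivity(
    m: np.ndarray, v: np.ndarray, params: ModelParameters, drug: str
) -> float:
    """Predicted sensitivity from the linear link: sens = (dA - b[d]) / k."""
    d = params.drug_index(drug)
    return (delta_activity(m, v, params, drug).delta - params.b[d]) / params.k


def combination_delta(
    m: np.ndarray, v: np.ndarray, params: ModelParameters, drug1: str, drug2: str
) -> float:
    """Activity reduction after treating with two drugs in turn.

    The attenuations multiply under the independence assumption, so the
    result is symmetric in (drug1, drug2).  ``drug1 == drug2`` is allowed
    (the self-pair squares the single-drug attenuation).
    """
    d1 = params.drug_index(drug1)
    d2 = params.drug_index(drug2)
    a = activity_terms(m, v, params)
    atten = (
        params.rho[:, d1] * params.alpha[d1] * params.rho[:, d2] * params.alpha[d2]
    )
    return float((a * (1.0 - atten)).sum())


def rank_combinations(
    m: np.ndarray,
    v: np.ndarray,
    params: ModelParameters,
    exclude: Iterable[str] = (),
    include_self: bool = False,
) -> list[tuple[str, str, float]]:
    """Score and rank all drug pairs for one sample.

    Returns each unordered pair once as (drug1, drug2, effect) with
    drug1 < drug2 lexicographically, sorted ascending by effect (most
    negative, i.e. most effective, first); ties break lexicographically.
    Self-pairs are omitted unless ``include_self``.
    """
    excluded = set(exclude)
    unknown = excluded - set(params.drugs)
    if unknown:
        raise KeyError(f"unknown drug(s) in exclusion list: {sorted(unknown)}")
    drugs = [d for d in params.drugs if d not in excluded]
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs after exclusion")
    pairs: list[tuple[str, str, float]] = []
    for d1, d2 in combinations(drugs, 2):
        lo, hi = sorted((d1, d2))
        pairs.append((lo, hi, combination_delta(m, v, params, lo, hi)))
    if include_self:
        for d in drugs:
            pairs.append((d, d, combination_delta(m, v, params, d, d)))
    pairs.sort(key=lambda t: (t[2], t[0], t[1]))
    return pairs
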