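"""Cross-validation and mutation-sensitivity association screening.

Cross-validation is per drug over observed (cell line, drug) pairs: one
cell line treated with different drugs counts as different samples, so a
line may be training data for one drug and test data for another.  Each
drug's observed pairs are dealt round-robin from a seeded shuffle into k
folds (sizes differ by at most one); every fold's model is refit jointly
on all drugs' training pairs, held-out pairs are predicted through the
linear link, and one Pearson r per drug is computed over the pooled
predictions from all folds.

The association screen splits each drug's screened cell lines by a gene's
mutation status and compares the two sensitivity groups with the two-sided
Wilcoxon rank-sum test; genes with no mutant among the screened lines are
reported missing.  Raw p-values are the primary output (log10 alongside,
for heatmaps); a Benjamini-Hochberg column is emitted for convenience but
drives no decision here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AlterationProfile, ModelParameters, ResponseTable
from .fit import FitConfig, fit as _fit_model

__all__ = [
    "CvReport",
    "AssociationMatrix",
    "make_folds",
    "cross_validate",
    "pearson",
    "wilcoxon_rank_sum",
    "association_matrix",
    "compare_drug_effect_profiles",
]

#: exact Wilcoxon enumeration is used when min group size <= this and no ties
EXACT_WILCOXON_MAX_N = 10


@dataclass
class CvReport:
    """Per-drug pooled-prediction Pearson r with fold bookkeeping.

    ``per_drug`` maps drug -> (pearson_r, n_test_pairs); r is NaN when
    undefined (constant predictions or < 3 test pairs).
    ``fold_assignments`` is a (samples x drugs) integer matrix of fold
    indices in 0..k-1, -1 at unobserved cells.  ``predictions`` holds the
    pooled out-of-fold predictions (NaN where unobserved).
    """

    per_drug: dict[str, tuple[float, int]]
    fold_assignments: np.ndarray
    seed: int
    predictions: np.ndarray | None = None


@dataclass
class AssociationMatrix:
    """Two-sided Wilcoxon p-values per (gene, drug), with derived views."""

    p: pd.DataFrame
    log10p: pd.DataFrame
    bh: pd.DataFrame
    missing: pd.DataFrame


def make_folds(responses: ResponseTable, k: int, seed: int) -> np.ndarray:
    """Deal each drug's observed pairs into k folds, round-robin.

    Returns a (samples x drugs) array of fold indices (0..k-1), -1 where
    unobserved.  Deterministic given ``seed``.  Drugs with fewer than k
    observed pairs get folds of size >= 1 (some folds empty) with a
    warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(responses.observed.shape, -1, dtype=int)
    for d, drug in enumerate(responses.drugs):
        idx = np.flatnonzero(responses.observed[:, d])
        if idx.size < k:
            warnings.warn(
                f"drug {drug!r} has only {idx.size} observed pairs for "
                f"{k}-fold CV",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        folds[perm, d] = np.arange(perm.size) % k
    return folds


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN for constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def cross_validate(
    profile: AlterationProfile,
    responses: ResponseTable,
    fit_config: FitConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CvReport:
    """k-fold per-drug cross-validation of the jointly fitted model.

    For each fold, the model is refit on all training pairs (the held-out
    pairs are removed from the observation mask, so their sensitivities
    are invisible to the fit) and held-out pairs are predicted as
    (dA - b[d]) / k.  Pearson r per drug is computed over the pooled
    out-of-fold predictions.
    """
    if fit_config is None:
        fit_config = FitConfig()
    if profile.samples != responses.samples:
        raise ValueError("profile and responses must share the sample list")
    folds = make_folds(responses, k, seed)
    sens = responses.sens
    M = profile.m.astype(float)
    V = profile.v.astype(float)
    predictions = np.full(sens.shape, np.nan)
    for fold in range(k):
        test_mask = folds == fold
        train_observed = responses.observed & ~test_mask
        train_sens = np.where(train_observed, sens, np.nan)
        train_responses = ResponseTable(
            responses.samples, responses.drugs, train_sens, train_observed
        )
        result = _fit_model(profile, train_responses, fit_config)
        p = result.params
        B = M * p.A_m[None, :] + V * p.A_v[None, :]
        dA = B @ (1.0 - p.rho * p.alpha[None, :])
        pred = (dA - p.b[None, :]) / p.k
        predictions[test_mask] = pred[test_mask]

    per_drug: dict[str, tuple[float, int]] = {}
    for d, drug in enumerate(responses.drugs):
        held = responses.observed[:, d]
        yhat = predictions[held, d]
        yobs = sens[held, d]
        n_test = int(held.sum())
        if n_test < 3:
            warnings.warn(f"drug {drug!r}: fewer than 3 test predictions", stacklevel=2)
            per_drug[drug] = (float("nan"), n_test)
            continue
        per_drug[drug] = (pearson(yhat, yobs), n_test)
    return CvReport(per_drug=per_drug, fold_assignments=folds, seed=seed, predictions=predictions)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the smaller group has <= 10 observations
    and there are no ties across the pooled sample; otherwise the normal
    approximation with tie and continuity corrections.  NaN if either
    group is empty.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if min(a.size, b.size) <= EXACT_WILCOXON_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
        if np.ptp(pooled) == 0:
            return 1.0  # identical constants: zero-variance normal limit
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def association_matrix(
    profile: AlterationProfile, responses: ResponseTable
) -> AssociationMatrix:
    """Screen every (gene, drug) for a mutation-sensitivity association.

    Splits each drug's screened cell lines into mutant vs wild type by the
    gene's mutation indicator and applies the two-sided rank-sum test.
    Cells where the gene has no mutant among that drug's screened lines
    are missing (NaN p).
    """
    if profile.samples != responses.samples:
        raise ValueError("profile and responses must share the sample list")
    genes = list(profile.genes)
    drugs = list(responses.drugs)
    p = np.full((len(genes), len(drugs)), np.nan)
    for d in range(len(drugs)):
        screened = responses.observed[:, d]
        sens_d = responses.sens[screened, d]
        m_scr = profile.m[screened]
        for j in range(len(genes)):
            mut = m_scr[:, j] == 1
            if not mut.any() or mut.all():
                continue
            p[j, d] = wilcoxon_rank_sum(sens_d[mut], sens_d[~mut])
    pdf = pd.DataFrame(p, index=genes, columns=drugs)
    missing = pdf.isna()
    with np.errstate(divide="ignore"):
        log10p = np.log10(pdf)
    flat = pdf.to_numpy().ravel()
    ok = np.isfinite(flat)
    bh = np.full_like(flat, np.nan)
    if ok.any():
        bh[ok] = stats.false_discovery_control(flat[ok], method="bh")
    bhdf = pd.DataFrame(bh.reshape(pdf.shape), index=genes, columns=drugs)
    return AssociationMatrix(p=pdf, log10p=log10p, bh=bhdf, missing=missing)


def compare_drug_effect_profiles(
    params: ModelParameters, drug1: str, drug2: str
) -> float:
    """Paired t-test p-value between two drugs' fitted influence products.

    Pairs the rho*alpha columns of the two drugs across genes — a
    convenience contrast for asking whether two inhibitors of the same
    target act through detectably different per-gene effect profiles.
    """
    P = params.products()
    d1 = params.drug_index(drug1)
    d2 = params.drug_index(drug2)
    return float(stats.ttest_rel(P[:, d1], P[:, d2]).pvalue)
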