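"""Per-gene Gaussian class models, log-likelihood ratios, and t-scores.

Each gene's expression is modelled with one Gaussian per phenotype
class.  The per-sample log-likelihood ratio (LLR)

    lambda_i(x) = log f_pos(x) - log f_neg(x)

is the evidence the expression value x of gene g_i lends to the positive
(metastatic) class.  Discriminative power of a gene — or of a gene pair,
via the element-wise sum of the two LLR vectors — is the two-sample
t-statistic of the LLR values between the classes.  The Welch
(unequal-variance) t is the default; a pooled-variance variant is
available through ``variant="pooled"``.

Class standard deviations are floored at a small fraction of the global
dataset SD so near-constant genes cannot produce unbounded LLRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateClassError
from .io_network import ExpressionDataset

#: sigma floor as a fraction of the global SD of the dataset
SIGMA_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class GeneClassModel:
    """Gaussian expression model of one gene under the two classes."""

    gene_id: str
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float


@dataclass(frozen=True)
class GeneScore:
    """t-statistic of a single gene's LLR vector between classes."""

    gene_id: str
    t: float

    @property
    def abs_t(self) -> float:
        return abs(self.t)


@dataclass(frozen=True)
class PairScore:
    """t-statistic of the summed LLR vectors of an (ordered) gene pair."""

    gene_pair: tuple
    t_combined: float

    @property
    def abs_t(self) -> float:
        return abs(self.t_combined)


def sigma_floor_for(dataset: ExpressionDataset) -> float:
    """Default SD floor: a tiny fraction of the dataset's global SD."""
    global_sd = float(np.std(dataset.values))
    if global_sd <= 0.0:
        global_sd = 1.0
    return SIGMA_FLOOR_FRACTION * global_sd


def fit_class_models(
    dataset: ExpressionDataset, sigma_floor: float | None = None
) -> list:
    """Fit one two-class Gaussian model per gene (sample mean/SD, ddof=1)."""
    pos = dataset.pos_mask
    neg = ~pos
    if pos.sum() < 2 or neg.sum() < 2:
        raise DegenerateClassError("each class needs >= 2 samples to fit models")
    if sigma_floor is None:
        sigma_floor = sigma_floor_for(dataset)
    mu_p = dataset.values[:, pos].mean(axis=1)
    mu_n = dataset.values[:, neg].mean(axis=1)
    sd_p = np.maximum(dataset.values[:, pos].std(axis=1, ddof=1), sigma_floor)
    sd_n = np.maximum(dataset.values[:, neg].std(axis=1, ddof=1), sigma_floor)
    return [
        GeneClassModel(g, float(mu_p[i]), float(sd_p[i]), float(mu_n[i]), float(sd_n[i]))
        for i, g in enumerate(dataset.gene_ids)
    ]


def llr_vector(model: GeneClassModel, expression_row) -> np.ndarray:
    """Element-wise Gaussian log-likelihood ratio, computed in log space."""
    x = np.asarray(expression_row, dtype=float)
    sp, sn = model.sigma_pos, model.sigma_neg
    lp = -np.log(sp) - 0.5 * ((x - model.mu_pos) / sp) ** 2
    ln = -np.log(sn) - 0.5 * ((x - model.mu_neg) / sn) ** 2
    return lp - ln


def llr_matrix(models, values: np.ndarray) -> np.ndarray:
    """Stacked LLR vectors for aligned models/rows (genes x samples)."""
    mu_p = np.array([m.mu_pos for m in models])[:, None]
    mu_n = np.array([m.mu_neg for m in models])[:, None]
    sd_p = np.array([m.sigma_pos for m in models])[:, None]
    sd_n = np.array([m.sigma_neg for m in models])[:, None]
    lp = -np.log(sd_p) - 0.5 * ((values - mu_p) / sd_p) ** 2
    ln = -np.log(sd_n) - 0.5 * ((values - mu_n) / sd_n) ** 2
    return lp - ln


def t_statistic(pos_values, neg_values, variant: str = "welch") -> float:
    """Two-sample t between the groups; 0.0 when both groups are constant."""
    pos_values = np.asarray(pos_values, dtype=float)
    neg_values = np.asarray(neg_values, dtype=float)
    return float(
        _t_from_moments(
            pos_values.mean(),
            pos_values.var(ddof=1),
            len(pos_values),
            neg_values.mean(),
            neg_values.var(ddof=1),
            len(neg_values),
            variant,
        )
    )


def _t_from_moments(m_p, v_p, n_p, m_n, v_n, n_n, variant):
    """Vectorised t from per-class moments (arrays or scalars)."""
    if variant == "welch":
        denom = np.sqrt(v_p / n_p + v_n / n_n)
    elif variant == "pooled":
        sp2 = ((n_p - 1) * v_p + (n_n - 1) * v_n) / (n_p + n_n - 2)
        denom = np.sqrt(sp2 * (1.0 / n_p + 1.0 / n_n))
    else:
        raise ValueError(f"unknown t-statistic variant {variant!r}")
    diff = m_p - m_n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0.0, diff / np.where(denom > 0.0, denom, 1.0), 0.0)
    return t


def t_array(matrix: np.ndarray, pos_mask: np.ndarray, variant: str = "welch") -> np.ndarray:
    """Row-wise two-sample t of a (features x samples) matrix."""
    pos = matrix[:, pos_mask]
    neg = matrix[:, ~pos_mask]
    return _t_from_moments(
        pos.mean(axis=1),
        pos.var(axis=1, ddof=1),
        pos.shape[1],
        neg.mean(axis=1),
        neg.var(axis=1, ddof=1),
        neg.shape[1],
        variant,
    )


def gene_t_scores(
    dataset: ExpressionDataset, models, variant: str = "welch"
) -> list:
    """t-score of every gene's LLR vector between the two classes."""
    by_gene = {m.gene_id: m for m in models}
    missing = [g for g in dataset.gene_ids if g not in by_gene]
    if missing:
        raise KeyError(f"models missing for genes: {missing[:5]}")
    ordered = [by_gene[g] for g in dataset.gene_ids]
    llr = llr_matrix(ordered, dataset.values)
    t = t_array(llr, dataset.pos_mask, variant)
    return [GeneScore(g, float(t[i])) for i, g in enumerate(dataset.gene_ids)]


def pair_t_score(
    dataset: ExpressionDataset,
    model_i: GeneClassModel,
    model_k: GeneClassModel,
    variant: str = "welch",
) -> PairScore:
    """t-score of the summed LLR vectors of two genes."""
    combined = llr_vector(model_i, dataset.row(model_i.gene_id)) + llr_vector(
        model_k, dataset.row(model_k.gene_id)
    )
    t = t_statistic(combined[dataset.pos_mask], combined[~dataset.pos_mask], variant)
    return PairScore((model_i.gene_id, model_k.gene_id), t)


def pair_t_values(
    llr: np.ndarray,
    pos_mask: np.ndarray,
    pair_i: np.ndarray,
    pair_k: np.ndarray,
    variant: str = "welch",
) -> np.ndarray:
    """t of summed LLRs for many index pairs at once.

    Uses per-class moments of the summed vectors: the variance of a sum
    is var_i + var_k + 2 cov_ik, with covariances computed per class by
    an einsum over centred rows, so no pair's vector is materialised.
    """
    out = np.empty(len(pair_i))
    masks = (pos_mask, ~pos_mask)
    means, variances, covs, ns = [], [], [], []
    for mask in masks:
        block = llr[:, mask]
        n = block.shape[1]
        mu = block.mean(axis=1)
        var = block.var(axis=1, ddof=1)
        centred = block - mu[:, None]
        cov = np.einsum("ij,ij->i", centred[pair_i], centred[pair_k]) / (n - 1)
        means.append(mu)
        variances.append(var)
        covs.append(cov)
        ns.append(n)
    m_p = means[0][pair_i] + means[0][pair_k]
    m_n = means[1][pair_i] + means[1][pair_k]
    v_p = variances[0][pair_i] + variances[0][pair_k] + 2.0 * covs[0]
    v_n = variances[1][pair_i] + variances[1][pair_k] + 2.0 * covs[1]
    v_p = np.maximum(v_p, 0.0)  # guard tiny negative from rounding
    v_n = np.maximum(v_n, 0.0)
    out[:] = _t_from_moments(m_p, v_p, ns[0], m_n, v_n, ns[1], variant)
    return out


def export_scores_tsv(scores, path) -> None:
    """Write (gene id, t, abs_t) rows for inspection."""
    with open(path, "w") as fh:
        fh.write("gene_id\tt\tabs_t\n")
        for s in scores:
            fh.write(f"{s.gene_id}\t{s.t:.10g}\t{s.abs_t:.10g}\n")
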