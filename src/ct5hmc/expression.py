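"""Differential expression and integration with differential modification.

Differential expression uses a gamma-Poisson (negative binomial) GLM with a
log link fit per gene by iteratively reweighted least squares: counts are
offset by median-of-ratios size factors, per-gene dispersions come from a
degrees-of-freedom-corrected moment estimator with optional shrinkage toward
a parametric mean-dispersion trend (alpha(mu) = a0 + a1/mu), and the group
contrast is tested with a Wald statistic referred to a t distribution on the
residual degrees of freedom. This is a deliberately self-contained core: no
independent filtering, no fold-change shrinkage.

Integration utilities pair differentially modified CpGs with gene-level fold
changes (Pearson correlation overall and among significant genes), test
promoter/gene-body membership against the direction of expression change
(Woolf CI, Haldane-Anscombe correction, Fisher exact p), and compute
binned-control module scores on normalized single-cell-style matrices.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._errors import ValidationError
from ._utils import bh_adjust

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    Uses genes with positive counts in every sample; raises if none exist.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in all samples; use a pseudo-reference "
            "(filter genes or add a pseudo-count) before size-factor estimation"
        )
    log_ref = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_ref[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor")


def normalize_log1p(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Depth-normalize columns to ``scale`` and log1p (module-score input)."""
    depth = counts.sum(axis=0).replace(0, np.nan)
    return np.log1p(counts.div(depth, axis=1) * scale).fillna(0.0)


# ---------------------------------------------------------------------------
# negative-binomial GLM


def _irls_nb(y, x, offset, alpha, max_iter=50, tol=1e-8):
    """IRLS for NB(mu, alpha) with log link; returns (beta, cov, converged)."""
    beta = np.linalg.lstsq(x, np.log((y + 0.5)) - offset, rcond=None)[0]
    converged = False
    for _ in range(max_iter):
        eta = x @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, None, False
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = x @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    cov = np.linalg.pinv((x.T * w) @ x)
    return beta, cov, converged


def _moment_dispersion(y, mu, n_params):
    """df-corrected moment estimate of the NB dispersion alpha."""
    n = y.size
    df = max(n - n_params, 1)
    num = np.sum((y - mu) ** 2 * (n / df) - mu)
    den = np.sum(mu**2)
    return max(num / den, 0.0) if den > 0 else 0.0


class NegativeBinomialDE(BaseEstimator):
    """Per-gene NB GLM differential expression for one group contrast.

    Parameters
    ----------
    covariates : sequence of str
        Sample-sheet covariates (default age, sex, matching the bulk model
        "adjusting for age at diagnosis and sex").
    cell_types : sequence of str
        Composition columns added as covariates (the cell-type-adjusted
        model uses NEU, NSC, RGC, OPC, UBC).
    dispersion : float or None
        Fixed dispersion for every gene (0 gives the Poisson limit); None
        estimates per-gene moment dispersions.
    trend_shrinkage : float in [0, 1]
        Weight pulling per-gene dispersions toward the fitted parametric
        trend alpha(mu) = a0 + a1/mu.
    """

    def __init__(
        self,
        covariates: Sequence[str] = ("age", "sex"),
        cell_types: Sequence[str] = (),
        dispersion: float | None = None,
        trend_shrinkage: float = 0.25,
        min_dispersion: float = 1e-8,
    ):
        self.covariates = covariates
        self.cell_types = cell_types
        self.dispersion = dispersion
        self.trend_shrinkage = trend_shrinkage
        self.min_dispersion = min_dispersion

    def _design(self, sheet, composition, group, nontumor_group):
        keep = sheet.index[(sheet["group"] == group) | (sheet["group"] == nontumor_group)]
        sub = sheet.loc[keep]
        cols = {"intercept": np.ones(len(sub)), "group": (sub["group"] == group).astype(float)}
        for cov in self.covariates:
            if cov == "sex":
                cols["sex"] = (sub["sex"] == "M").astype(float)
            elif cov == "age":
                age = sub["age"].astype(float)
                cols["age"] = age - age.mean()
            else:
                cols[cov] = sub[cov].astype(float)
        for ct in self.cell_types:
            cols[ct] = composition.loc[keep, ct].astype(float)
        design = pd.DataFrame(cols, index=keep)
        constant = [c for c in design.columns if c != "intercept" and design[c].nunique() <= 1]
        return design.drop(columns=constant)

    def fit(
        self,
        counts: pd.DataFrame,
        sheet: pd.DataFrame,
        group: str,
        composition: pd.DataFrame | None = None,
        nontumor_group: str = "NonTumor",
        size_factors: pd.Series | None = None,
    ) -> "NegativeBinomialDE":
        mat_all = counts.to_numpy()
        if not np.issubdtype(mat_all.dtype, np.integer):
            if not np.allclose(mat_all, np.round(mat_all)):
                raise ValidationError("counts must be non-negative integers")
        if (mat_all < 0).any():
            raise ValidationError("counts must be non-negative integers")

        design = self._design(sheet, composition, group, nontumor_group)
        x = design.to_numpy(dtype=float)
        n, p = x.shape
        if n <= p:
            raise ValidationError(f"n_samples ({n}) must exceed n_coefficients ({p})")
        j = list(design.columns).index("group")
        sub = counts[design.index]
        if size_factors is None:
            size_factors = estimate_size_factors(sub)
        offset = np.log(size_factors.loc[design.index].to_numpy(dtype=float))
        y_all = sub.to_numpy(dtype=float)

        n_genes = y_all.shape[0]
        beta_j = np.full(n_genes, np.nan)
        se_j = np.full(n_genes, np.nan)
        disp = np.full(n_genes, np.nan)
        mean_norm = np.full(n_genes, np.nan)
        conv = np.zeros(n_genes, dtype=bool)
        nonzero = y_all.sum(axis=1) > 0

        # pass 1: Poisson fit for means + moment dispersions
        mus = {}
        for i in np.nonzero(nonzero)[0]:
            y = y_all[i]
            b, cov, ok = _irls_nb(y, x, offset, alpha=0.0)
            if cov is None:
                continue
            mu = np.exp(np.clip(x @ b + offset, -30, 30))
            mus[i] = mu
            mean_norm[i] = float(np.mean(y / np.exp(offset)))
            if self.dispersion is not None:
                disp[i] = self.dispersion
            else:
                disp[i] = _moment_dispersion(y, mu, p)

        if self.dispersion is None and self.trend_shrinkage > 0:
            ok = np.isfinite(disp) & np.isfinite(mean_norm) & (mean_norm > 0)
            if ok.sum() >= 10:
                a = np.vstack([np.ones(ok.sum()), 1.0 / mean_norm[ok]]).T
                coef, *_ = np.linalg.lstsq(a, disp[ok], rcond=None)
                trend = np.maximum(coef[0] + coef[1] / np.maximum(mean_norm, 1e-8), 0.0)
                w = self.trend_shrinkage
                disp = np.where(ok, (1 - w) * disp + w * trend, disp)
        disp = np.maximum(disp, self.min_dispersion)

        # pass 2: NB fit at the final dispersions
        for i, mu in mus.items():
            b, cov, ok = _irls_nb(y_all[i], x, offset, alpha=float(disp[i]))
            if cov is None:
                continue
            beta_j[i] = b[j]
            se_j[i] = np.sqrt(cov[j, j])
            conv[i] = ok

        with np.errstate(invalid="ignore", divide="ignore"):
            wald = beta_j / se_j
        df_resid = n - p
        p_val = 2.0 * stats.t.sf(np.abs(wald), df_resid)
        p_val[~np.isfinite(wald)] = np.nan

        self.design_ = design
        self.size_factors_ = size_factors
        self.results_ = pd.DataFrame(
            {
                "gene_id": counts.index,
                "log2fc": beta_j / LN2,
                "se_log2fc": se_j / LN2,
                "wald": wald,
                "wald_p": p_val,
                "p_adj": bh_adjust(p_val),
                "mean_expression": mean_norm,
                "dispersion": disp,
                "converged": conv,
            }
        )
        return self


def fit_nb_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    group: str,
    composition: pd.DataFrame | None = None,
    nontumor_group: str = "NonTumor",
    size_factors: pd.Series | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper over :class:`NegativeBinomialDE`."""
    model = NegativeBinomialDE(**kwargs)
    return model.fit(
        counts, sheet, group, composition=composition,
        nontumor_group=nontumor_group, size_factors=size_factors,
    ).results_


# ---------------------------------------------------------------------------
# modification / expression integration


def hm_expression_correlation(
    dm_hits: pd.DataFrame,
    de_fits: pd.DataFrame,
    annotation: pd.DataFrame,
    p_adj_threshold: float = 0.05,
) -> dict:
    """Pair dhmCpG effect sizes with gene log2 fold changes.

    One row per (CpG, mapped gene) pair; Pearson r over all pairs and over
    the subset whose gene is significant at ``p_adj_threshold``.
    """
    effect_col = "coefficient" if "coefficient" in dm_hits.columns else "b"
    de = de_fits.set_index("gene_id")
    rows = []
    for rec in dm_hits.itertuples(index=False):
        probe = rec.probe_id
        if probe not in annotation.index:
            continue
        genes = annotation.at[probe, "genes"]
        if not isinstance(genes, str) or not genes:
            continue
        for gene in genes.split(";"):
            if gene in de.index and np.isfinite(de.at[gene, "log2fc"]):
                rows.append(
                    {
                        "probe_id": probe,
                        "gene_id": gene,
                        "dm_effect": getattr(rec, effect_col),
                        "log2fc": de.at[gene, "log2fc"],
                        "p_adj": de.at[gene, "p_adj"],
                    }
                )
    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "dm_effect", "log2fc", "p_adj"])

    def _pearson(df):
        if len(df) < 3:
            return {"r": np.nan, "p": np.nan, "n": len(df), "defined": False}
        if df["dm_effect"].nunique() == 1 or df["log2fc"].nunique() == 1:
            return {"r": np.nan, "p": np.nan, "n": len(df), "defined": False,
                    "reason": "zero variance"}
        r, p = stats.pearsonr(df["dm_effect"], df["log2fc"])
        return {"r": float(r), "p": float(p), "n": len(df), "defined": True}

    return {
        "pairs": pairs,
        "all": _pearson(pairs),
        "significant": _pearson(pairs[pairs["p_adj"] < p_adj_threshold]),
    }


def promoter_genebody_odds(
    hits: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_flags: Sequence[str] = ("TSS200", "TSS1500"),
    body_flag: str = "gene_body",
) -> dict:
    """Odds of context membership for increased- vs decreased-expression CpGs.

    ``hits`` needs columns probe_id and expression_direction in
    {"increased", "decreased"}. For each of promoter (union of TSS flags)
    and gene body: OR = (a d)/(b c) on the 2x2 of direction x membership,
    Woolf 95% CI with Haldane-Anscombe 0.5 correction when a cell is zero,
    Fisher exact p on the uncorrected table.
    """
    for direction in ("increased", "decreased"):
        if (hits["expression_direction"] == direction).sum() == 0:
            raise ValidationError(f"no hits with expression_direction {direction!r}")
    ann = annotation.loc[annotation.index.intersection(pd.Index(hits["probe_id"].unique()))]
    hits = hits[hits["probe_id"].isin(ann.index)]
    membership = {
        "promoter": ann[list(promoter_flags)].astype(bool).any(axis=1),
        "gene_body": ann[body_flag].astype(bool),
    }
    out = {}
    for name, member in membership.items():
        inc = hits["expression_direction"] == "increased"
        in_ctx = hits["probe_id"].map(member).to_numpy(dtype=bool)
        a = int((inc & in_ctx).sum())
        b = int((inc & ~in_ctx).sum())
        c = int(((~inc) & in_ctx).sum())
        d = int(((~inc) & ~in_ctx).sum())
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        or_val = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        z = stats.norm.ppf(0.975)
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]])
        out[name] = {
            "odds_ratio": float(or_val),
            "ci95": (float(or_val * np.exp(-z * se)), float(or_val * np.exp(z * se))),
            "p": float(fisher_p),
            "table": (a, b, c, d),
        }
    return out


# ---------------------------------------------------------------------------
# module scores


class ModuleScorer(BaseEstimator):
    """Binned-control gene-set expression scores on a cells x genes matrix.

    Genes are binned by average expression; each set gene draws ``n_ctrl``
    control genes from its own bin (excluding set genes), and the per-cell
    score is mean(set expression) - mean(control expression).
    """

    def __init__(self, n_bins: int = 24, n_ctrl: int = 100, random_state: int = 0):
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.random_state = random_state

    def fit(self, expression: pd.DataFrame) -> "ModuleScorer":
        """``expression``: cells x genes normalized matrix."""
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.n_ctrl < 1:
            raise ValidationError("n_ctrl must be >= 1 (control-free scores are degenerate)")
        self.expression_ = expression
        avg = expression.mean(axis=0)
        ranks = avg.rank(method="first")
        self.bins_ = pd.cut(ranks, bins=self.n_bins, labels=False)
        return self

    def score(self, gene_set: Sequence[str]) -> pd.Series:
        expr = self.expression_
        genes = [g for g in gene_set if g in expr.columns]
        if not genes:
            raise ValidationError("gene set has no expressed genes")
        rng = np.random.default_rng(self.random_state)
        gene_set_set = set(genes)
        controls: list[str] = []
        # iterate in sorted order so scores do not depend on gene-set ordering
        for gene in sorted(gene_set_set):
            b = self.bins_[gene]
            pool = [g for g in self.bins_.index[self.bins_ == b] if g not in gene_set_set]
            if not pool:
                continue
            take = rng.choice(pool, size=min(self.n_ctrl, len(pool)), replace=False)
            controls.extend(take)
        if not controls:
            raise ValidationError("no control genes available outside the gene set")
        ctrl = sorted(set(controls))
        return expr[genes].mean(axis=1) - expr[ctrl].mean(axis=1)


def module_score(
    expression: pd.DataFrame,
    gene_set: Sequence[str],
    cell_meta: pd.DataFrame | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> dict:
    """Scores per cell plus per-cell-type group comparisons (Wilcoxon).

    ``cell_meta`` (optional) is indexed by cell id with columns cell_type and
    group; when given, each cell type's score distribution is compared
    between groups with the Wilcoxon rank-sum test.
    """
    scorer = ModuleScorer(n_bins=n_bins, n_ctrl=n_ctrl, random_state=seed).fit(expression)
    scores = scorer.score(gene_set)
    out: dict = {"scores": scores}
    if cell_meta is not None:
        comparisons = {}
        for ct in cell_meta["cell_type"].unique():
            cells = cell_meta.index[cell_meta["cell_type"] == ct]
            groups = cell_meta.loc[cells, "group"].unique()
            if len(groups) != 2:
                continue
            s0 = scores[cells[cell_meta.loc[cells, "group"] == groups[0]]]
            s1 = scores[cells[cell_meta.loc[cells, "group"] == groups[1]]]
            if len(s0) == 0 or len(s1) == 0:
                continue
            w = stats.ranksums(s0, s1)
            comparisons[ct] = {
                "groups": tuple(groups),
                "mean_diff": float(s0.mean() - s1.mean()),
                "statistic": float(w.statistic),
                "p": float(w.pvalue),
            }
        out["group_comparisons"] = comparisons
    return out
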