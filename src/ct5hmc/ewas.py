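"""Covariate-adjusted epigenome-wide association testing with moderated t.

Each tumor group is contrasted against non-tumor tissue in its own model on
beta values, adjusting for sex, mean-centered age, tumor purity and an
ordered subset of cell-type proportions (the "stepwise" series k = 0..5).
Per-probe residual variances are shrunk toward a common prior by empirical
Bayes on a scaled inverse-chi-square model: the prior degrees of freedom d0
and prior variance s0^2 are estimated by method of moments on the log
residual variances (the classical limma squeezeVar scheme), the posterior
variance is (d0 s0^2 + d s^2)/(d0 + d), and the moderated t statistic is
referred to a t distribution on d + d0 degrees of freedom. Discoveries are
declared at q < 0.05 by Benjamini-Hochberg (Storey fixed-lambda pi0
rescaling available as an option).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from ._errors import ValidationError
from ._utils import bh_adjust, check_beta_matrix, storey_pi0

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPE_ORDER = ("NEU", "NSC", "OPC", "RGC", "UBC")


# ---------------------------------------------------------------------------
# design construction


def build_design(
    sheet: pd.DataFrame,
    composition: pd.DataFrame | None,
    group: str,
    nontumor_group: str = "NonTumor",
    covariates: Sequence[str] = ("sex", "age", "purity"),
    cell_types: Sequence[str] = (),
    condition_threshold: float = 1e10,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix for one tumor-vs-non-tumor contrast.

    Samples are restricted to the contrast group plus non-tumor tissue.
    Columns: intercept, group indicator (non-tumor = 0), sex indicator
    (F = 0), mean-centered age, purity, then the included cell-type
    fractions in order. Constant columns are dropped with a warning;
    a condition number above ``condition_threshold`` raises, naming the
    closest-to-aliased columns.
    """
    keep = sheet.index[(sheet["group"] == group) | (sheet["group"] == nontumor_group)]
    if (sheet.loc[keep, "group"] == group).sum() == 0:
        raise ValidationError(f"contrast group {group!r} has no samples")
    if (sheet.loc[keep, "group"] == nontumor_group).sum() == 0:
        raise ValidationError(f"non-tumor group {nontumor_group!r} has no samples")
    sub = sheet.loc[keep]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    cols["group"] = (sub["group"] == group).to_numpy(dtype=float)
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (sub["sex"] == "M").to_numpy(dtype=float)
        elif cov == "age":
            age = sub["age"].to_numpy(dtype=float)
            cols["age"] = age - age.mean()
        elif cov == "purity":
            cols["purity"] = sub["purity"].to_numpy(dtype=float)
        else:
            cols[cov] = sub[cov].to_numpy(dtype=float)
    for ct in cell_types:
        if composition is None or ct not in composition.columns:
            raise ValidationError(f"cell type {ct!r} absent from composition matrix")
        cols[ct] = composition.loc[keep, ct].to_numpy(dtype=float)

    design = pd.DataFrame(cols, index=keep)
    constant = [c for c in design.columns if c != "intercept" and design[c].nunique() <= 1]
    if constant:
        logger.warning("build_design: dropping constant columns %s", constant)
        design = design.drop(columns=constant)

    x = design.to_numpy()
    cond = np.linalg.cond(x)
    if cond > condition_threshold:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        worst = [design.columns[j] for j in np.argsort(diag)[:2]]
        raise ValidationError(
            f"design is near-collinear (condition number {cond:.3g}); "
            f"columns closest to aliased: {worst}"
        )
    column_map = {name: j for j, name in enumerate(design.columns)}
    return design, column_map


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (limma squeezeVar scheme)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment estimates of (d0, s0^2) for the scaled inverse-chi-square prior.

    Matches the moments of log residual variances against the theoretical
    log-F distribution; d0 = inf (complete pooling) when the observed spread
    of log variances is no larger than chi-square sampling noise alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def squeeze_var(s2: np.ndarray, df: np.ndarray, prior_df: float | None = None):
    """Posterior variances (d0 s0^2 + d s^2)/(d0 + d); returns (post, d0, s0^2)."""
    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_f_dist(s2, df)
    if not np.isfinite(d0):
        post = np.full_like(s2, s0_sq, dtype=float)
    elif d0 == 0:
        post = s2.astype(float)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


# ---------------------------------------------------------------------------
# per-probe OLS, vectorized with complete-case fallback


def _ols_stats(y: np.ndarray, x: np.ndarray, j: int):
    """Coefficient j, its unscaled SE factor, residual variance and df."""
    n, p = x.shape
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - rank
    s2 = float(resid @ resid / df) if df > 0 else np.nan
    xtx_inv = np.linalg.pinv(x.T @ x)
    return float(coef[j]), float(np.sqrt(xtx_inv[j, j])), s2, df


class ModeratedEWAS(BaseEstimator):
    """Per-probe moderated linear-model EWAS for one group contrast.

    Parameters
    ----------
    covariates : sequence of str
        Sample-sheet covariates to adjust for (default sex, age, purity).
    cell_types : sequence of str
        Cell-type proportion columns added as covariates (the stepwise k).
    q_method : "bh" or "storey"
        FDR adjustment; "storey" rescales BH by the fixed-lambda pi0.
    prior_df : float or None
        Override the estimated prior degrees of freedom (0 disables
        moderation entirely; None estimates d0 from the data).
    """

    def __init__(
        self,
        covariates: Sequence[str] = ("sex", "age", "purity"),
        cell_types: Sequence[str] = (),
        q_method: str = "bh",
        prior_df: float | None = None,
        condition_threshold: float = 1e10,
    ):
        self.covariates = covariates
        self.cell_types = cell_types
        self.q_method = q_method
        self.prior_df = prior_df
        self.condition_threshold = condition_threshold

    def fit(
        self,
        betas: pd.DataFrame,
        sheet: pd.DataFrame,
        composition: pd.DataFrame | None = None,
        group: str = None,
        nontumor_group: str = "NonTumor",
    ) -> "ModeratedEWAS":
        if group is None:
            raise ValidationError("group must be specified")
        check_beta_matrix(betas)
        design, column_map = build_design(
            sheet,
            composition,
            group,
            nontumor_group=nontumor_group,
            covariates=self.covariates,
            cell_types=self.cell_types,
            condition_threshold=self.condition_threshold,
        )
        x = design.to_numpy()
        n, p = x.shape
        if n <= p:
            raise ValidationError(f"n_samples ({n}) must exceed n_columns ({p})")
        j = column_map["group"]
        y_all = betas[design.index].to_numpy(dtype=float)

        n_probes = y_all.shape[0]
        coef = np.full(n_probes, np.nan)
        se_unscaled = np.full(n_probes, np.nan)
        s2 = np.full(n_probes, np.nan)
        dfs = np.full(n_probes, np.nan)
        flagged = np.zeros(n_probes, dtype=bool)

        complete = np.isfinite(y_all).all(axis=1)
        if complete.any():
            pinv = np.linalg.pinv(x)
            b = y_all[complete] @ pinv.T
            resid = y_all[complete] - b @ x.T
            df_c = n - np.linalg.matrix_rank(x)
            xtx_inv_jj = float(np.linalg.pinv(x.T @ x)[j, j])
            coef[complete] = b[:, j]
            se_unscaled[complete] = np.sqrt(xtx_inv_jj)
            s2[complete] = (resid**2).sum(axis=1) / df_c
            dfs[complete] = df_c
        for i in np.nonzero(~complete)[0]:
            ok = np.isfinite(y_all[i])
            if ok.sum() <= p:
                flagged[i] = True
                continue
            coef[i], se_unscaled[i], s2[i], dfs[i] = _ols_stats(y_all[i][ok], x[ok], j)

        post_var, d0, s0_sq = squeeze_var(s2, dfs, prior_df=self.prior_df)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_mod = se_unscaled * np.sqrt(post_var)
            t_mod = coef / se_mod
        df_total = dfs + (d0 if np.isfinite(d0) else np.inf)
        df_eff = np.where(np.isfinite(df_total), df_total, 1e12)
        p_val = 2.0 * stats.t.sf(np.abs(t_mod), df_eff)
        p_val[~np.isfinite(t_mod)] = np.nan

        pi0 = storey_pi0(p_val) if self.q_method == "storey" else 1.0
        q = bh_adjust(p_val, pi0=pi0)

        self.design_ = design
        self.column_map_ = column_map
        self.d0_ = d0
        self.s0_sq_ = s0_sq
        self.group_ = group
        self.results_ = pd.DataFrame(
            {
                "probe_id": betas.index,
                "coefficient": coef,
                "se": se_unscaled * np.sqrt(s2),
                "se_moderated": se_mod,
                "t_mod": t_mod,
                "df_total": df_total,
                "p": p_val,
                "q": q,
                "direction": np.where(coef > 0, "hyper", "hypo"),
                "flagged_missing": flagged,
            }
        )
        return self

    def hits(self, q_threshold: float = 0.05) -> set[str]:
        res = self.results_
        return set(res.loc[res["q"] < q_threshold, "probe_id"])


def fit_moderated(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    group: str,
    composition: pd.DataFrame | None = None,
    **kwargs,
) -> ModeratedEWAS:
    """Functional wrapper over :class:`ModeratedEWAS`."""
    return ModeratedEWAS(**kwargs).fit(betas, sheet, composition=composition, group=group)


def stepwise_series(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    composition: pd.DataFrame,
    group: str,
    cell_type_order: Sequence[str] = DEFAULT_CELL_TYPE_ORDER,
    covariates: Sequence[str] = ("sex", "age", "purity"),
    nontumor_group: str = "NonTumor",
    q_threshold: float = 0.05,
    q_method: str = "bh",
) -> dict[int, dict]:
    """Fit the cumulative stepwise models k = 0..len(order).

    k = 0 adjusts only for the base covariates; each further k adds the next
    cell-type proportion in ``cell_type_order``. Returns per-k results and
    hit counts at the q threshold.
    """
    out = {}
    for k in range(len(cell_type_order) + 1):
        model = ModeratedEWAS(
            covariates=covariates,
            cell_types=tuple(cell_type_order[:k]),
            q_method=q_method,
        ).fit(betas, sheet, composition=composition, group=group, nontumor_group=nontumor_group)
        hits = model.hits(q_threshold)
        out[k] = {
            "results": model.results_,
            "n_hits": len(hits),
            "hits": hits,
            "cell_types": tuple(cell_type_order[:k]),
        }
    return out


def summarize_hits(
    hit_sets: Mapping[str, set[str]],
    annotation: pd.DataFrame | None = None,
    contexts: Sequence[str] = (),
) -> dict:
    """Sharing structure of per-group hit sets and per-context proportions.

    Proportions are relative to the union of all hits; shared-across-all is
    the intersection over every group.
    """
    if len(hit_sets) < 2:
        raise ValidationError("summarize_hits: need >= 2 groups")
    names = list(hit_sets)
    union = set().union(*hit_sets.values())
    shared_all = set.intersection(*(set(s) for s in hit_sets.values()))
    n_groups_per_probe = {
        p: sum(p in hit_sets[g] for g in names) for p in union
    }
    specific = {
        g: {p for p in hit_sets[g] if n_groups_per_probe[p] == 1} for g in names
    }
    shared_2_or_3 = {p for p, c in n_groups_per_probe.items() if 2 <= c < len(names)}
    out = {
        "per_group_counts": {g: len(hit_sets[g]) for g in names},
        "union_size": len(union),
        "shared_all": shared_all,
        "shared_all_fraction": (len(shared_all) / len(union)) if union else 0.0,
        "shared_2_or_3": shared_2_or_3,
        "shared_2_or_3_fraction": (len(shared_2_or_3) / len(union)) if union else 0.0,
        "group_specific": specific,
        "group_specific_fraction": {
            g: (len(specific[g]) / len(hit_sets[g])) if hit_sets[g] else 0.0 for g in names
        },
    }
    if annotation is not None and contexts:
        per_context = {}
        for g in names:
            hits = hit_sets[g]
            if not hits:
                per_context[g] = {c: 0.0 for c in contexts}
                continue
            sub = annotation.loc[annotation.index.intersection(pd.Index(list(hits)))]
            per_context[g] = {
                c: float(sub[c].astype(bool).mean()) if len(sub) else 0.0 for c in contexts
            }
        out["context_proportions"] = per_context
    return out
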