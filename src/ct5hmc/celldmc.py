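"""Cell-type-specific differential modification via interaction models.

The interaction (CellDMC-style) model regresses each probe's bulk beta value
on cell-type fractions and on fraction-by-phenotype interaction terms:

    beta_i = sum_k w_ik a_k + sum_k (w_ik x_i) b_k + gamma' z_i + eps_i

with no global intercept (the composition block spans it on the simplex),
x_i the 0/1 tumor indicator and z_i optional additive covariates. b_k is the
change in cell type k's modification level in tumors; a per-cell-type t-test
of b_k = 0 attributes differential modification to specific cell types.

To limit model size at small n, granular cell types are first aggregated
into super-types: NEU as neuronal-like and NSC + RGC + OPC + UBC as
progenitor-like, plus a remainder column when fractions do not sum to one.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._errors import ValidationError
from ._utils import bh_adjust, check_beta_matrix

DEFAULT_SCHEME: dict[str, str] = {
    "NEU": "neuronal_like",
    "NSC": "progenitor_like",
    "RGC": "progenitor_like",
    "OPC": "progenitor_like",
    "UBC": "progenitor_like",
    "other": "other",
}


def aggregate_celltypes(
    composition: pd.DataFrame, scheme: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Sum granular cell-type fractions into super-types; simplex preserved."""
    scheme = dict(scheme if scheme is not None else DEFAULT_SCHEME)
    unmapped = [c for c in composition.columns if c not in scheme]
    if unmapped:
        raise ValidationError(f"aggregate_celltypes: unmapped cell types {unmapped}")
    groups: dict[str, list[str]] = {}
    for ct in composition.columns:
        groups.setdefault(scheme[ct], []).append(ct)
    out = pd.DataFrame(
        {super_t: composition[members].sum(axis=1) for super_t, members in groups.items()},
        index=composition.index,
    )
    return out


class CellDMC(BaseEstimator):
    """Interaction-model estimator of per-cell-type differential modification.

    Parameters
    ----------
    covariates : sequence of str
        Sample-sheet columns added additively (default sex, age, purity).
        Pass ``()`` to fit the bare two-block interaction model.
    remainder_tol : float
        If composition rows sum to less than 1 - tol, a remainder column is
        appended so the composition block stays on the simplex.
    min_fraction_var : float
        A super-type whose fraction variance falls below this raises, naming
        the cell type (its interaction would be unidentifiable).
    """

    def __init__(
        self,
        covariates: Sequence[str] = ("sex", "age", "purity"),
        remainder_tol: float = 1e-6,
        min_fraction_var: float = 1e-8,
    ):
        self.covariates = covariates
        self.remainder_tol = remainder_tol
        self.min_fraction_var = min_fraction_var

    def _build_design(self, composition, phenotype, sheet):
        w = composition.copy()
        short = 1.0 - w.sum(axis=1)
        if (short > self.remainder_tol).any():
            w["remainder"] = np.clip(short, 0.0, 1.0)
        for ct in w.columns:
            if w[ct].var(ddof=0) < self.min_fraction_var and len(w.columns) > 1:
                raise ValidationError(
                    f"cell type {ct!r}: fraction variance below tolerance; "
                    "interaction term unidentifiable"
                )
        x = phenotype.to_numpy(dtype=float)
        blocks = [w.to_numpy()]
        names = [f"frac:{c}" for c in w.columns]
        blocks.append(w.to_numpy() * x[:, None])
        names += [f"int:{c}" for c in w.columns]
        for cov in self.covariates:
            if cov == "sex":
                blocks.append((sheet["sex"] == "M").to_numpy(dtype=float)[:, None])
            elif cov == "age":
                age = sheet["age"].to_numpy(dtype=float)
                blocks.append((age - age.mean())[:, None])
            else:
                blocks.append(sheet[cov].to_numpy(dtype=float)[:, None])
            names.append(f"cov:{cov}")
        return np.hstack(blocks), names, list(w.columns)

    def fit(
        self,
        betas: pd.DataFrame,
        composition: pd.DataFrame,
        phenotype: pd.Series,
        sheet: pd.DataFrame | None = None,
    ) -> "CellDMC":
        """Fit per-probe interaction models.

        ``phenotype`` is the 0/1 tumor indicator aligned with samples;
        ``sheet`` supplies covariates (required unless covariates=()).
        """
        check_beta_matrix(betas)
        if self.covariates and sheet is None:
            raise ValidationError("sheet required when covariates are requested")
        samples = composition.index
        x, names, cell_types = self._build_design(
            composition, phenotype.loc[samples], sheet.loc[samples] if sheet is not None else None
        )
        n, p = x.shape
        if n <= p:
            raise ValidationError(f"n_samples ({n}) must exceed n_parameters ({p})")

        y_all = betas[samples].to_numpy(dtype=float)
        pinv = np.linalg.pinv(x)
        xtx_inv = np.linalg.pinv(x.T @ x)
        df = n - np.linalg.matrix_rank(x)

        complete = np.isfinite(y_all).all(axis=1)
        rows = []
        int_cols = {ct: names.index(f"int:{ct}") for ct in cell_types}

        def one_fit(y, xx, pinv_, xtx_inv_, df_):
            b = pinv_ @ y
            resid = y - xx @ b
            s2 = resid @ resid / df_ if df_ > 0 else np.nan
            return b, s2

        for i, probe in enumerate(betas.index):
            y = y_all[i]
            if complete[i]:
                b, s2 = one_fit(y, x, pinv, xtx_inv, df)
                xtx_i, df_i = xtx_inv, df
            else:
                ok = np.isfinite(y)
                if ok.sum() <= p:
                    for ct in cell_types:
                        rows.append((probe, ct, np.nan, np.nan, np.nan, np.nan))
                    continue
                x_i = x[ok]
                df_i = ok.sum() - np.linalg.matrix_rank(x_i)
                xtx_i = np.linalg.pinv(x_i.T @ x_i)
                b, s2 = one_fit(y[ok], x_i, np.linalg.pinv(x_i), xtx_i, df_i)
            for ct in cell_types:
                jj = int_cols[ct]
                se = np.sqrt(s2 * xtx_i[jj, jj])
                t = b[jj] / se if se > 0 else np.nan
                pval = 2.0 * stats.t.sf(abs(t), df_i) if np.isfinite(t) else np.nan
                rows.append((probe, ct, b[jj], se, t, pval))

        res = pd.DataFrame(rows, columns=["probe_id", "cell_type", "b", "se", "t", "p"])
        res["q"] = np.nan
        for ct in cell_types:
            mask = res["cell_type"] == ct
            res.loc[mask, "q"] = bh_adjust(res.loc[mask, "p"].to_numpy())
        res["direction"] = np.where(res["b"] > 0, "hyper", "hypo")

        self.cell_types_ = cell_types
        self.column_names_ = names
        self.df_residual_ = df
        self.results_ = res
        return self

    def hits(self, q_threshold: float = 0.05) -> dict[str, set[str]]:
        res = self.results_
        return {
            ct: set(res.loc[(res["cell_type"] == ct) & (res["q"] < q_threshold), "probe_id"])
            for ct in self.cell_types_
        }


def fit_dmct(
    betas: pd.DataFrame,
    composition: pd.DataFrame,
    phenotype: pd.Series,
    sheet: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CellDMC`; returns the results table."""
    return CellDMC(**kwargs).fit(betas, composition, phenotype, sheet=sheet).results_


def classify_dmct(
    fits_by_group: Mapping[str, pd.DataFrame], q_threshold: float = 0.05
) -> dict:
    """Per-cell-type hit sets with direction and cross-group sharing counts."""
    per_group: dict[str, dict[str, dict[str, set]]] = {}
    cell_types: set[str] = set()
    for group, res in fits_by_group.items():
        cell_types |= set(res["cell_type"].unique())
        per_group[group] = {}
        for ct in res["cell_type"].unique():
            sub = res[(res["cell_type"] == ct) & (res["q"] < q_threshold)]
            per_group[group][ct] = {
                "hits": set(sub["probe_id"]),
                "hyper": set(sub.loc[sub["direction"] == "hyper", "probe_id"]),
                "hypo": set(sub.loc[sub["direction"] == "hypo", "probe_id"]),
            }
    sharing = {}
    for ct in cell_types:
        sets = [per_group[g][ct]["hits"] for g in per_group if ct in per_group[g]]
        sharing[ct] = {
            "n_groups": len(sets),
            "intersection_all": set.intersection(*sets) if sets else set(),
            "union": set().union(*sets) if sets else set(),
        }
    return {"per_group": per_group, "sharing": sharing}
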