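"""Methylation dysregulation index (MDI) and its accompanying statistics.

MDI summarizes epigenome-wide alteration of a sample relative to non-tumor
tissue: the mean absolute deviation of the sample's beta values from the
per-probe median of the non-tumor samples. It is computed overall and per
genomic context, and compared across tumor types/grades with rank-based
tests (Kruskal-Wallis, Wilcoxon rank-sum, Spearman), distribution shifts
with the two-sample Kolmogorov-Smirnov test, outliers with a single-pass
two-sided Grubbs test, and context/tumor-type associations with OLS.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from ._utils import check_beta_matrix

logger = logging.getLogger(__name__)


def reference_medians(betas: pd.DataFrame, nontumor_ids: Sequence[str]) -> pd.Series:
    """Per-probe median over non-tumor samples, ignoring missing values.

    Probes with no non-tumor observation are dropped (and logged).
    """
    nontumor_ids = list(nontumor_ids)
    if not nontumor_ids:
        raise ValidationError("nontumor_ids is empty")
    missing = set(nontumor_ids) - set(betas.columns)
    if missing:
        raise ValidationError(f"non-tumor samples absent from matrix: {sorted(missing)}")
    check_beta_matrix(betas)
    ref = betas[nontumor_ids].median(axis=1, skipna=True)
    dropped = ref.index[ref.isna()]
    if len(dropped):
        logger.warning("reference_medians: dropping %d probes with no non-tumor data", len(dropped))
    return ref.dropna()


def compute_mdi(
    betas: pd.DataFrame,
    reference: pd.Series,
    probe_subset: Sequence[str] | None = None,
    assay: str = "5hmC",
    context: str = "all",
    aggregation: str = "mean",
) -> pd.DataFrame:
    """One MDI record per sample: aggregated |beta - reference| over probes.

    ``aggregation`` is "mean" (default) or "median"; missing betas are
    excluded pairwise and the per-sample probe count used is recorded.
    """
    if probe_subset is not None:
        probes = reference.index.intersection(pd.Index(probe_subset))
    else:
        probes = reference.index.intersection(betas.index)
    if len(probes) == 0:
        raise ValidationError("no probes with reference values in the requested subset")
    dev = (betas.loc[probes].sub(reference.loc[probes], axis=0)).abs()
    if aggregation == "mean":
        mdi = dev.mean(axis=0, skipna=True)
    elif aggregation == "median":
        mdi = dev.median(axis=0, skipna=True)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    n_used = dev.notna().sum(axis=0)
    if (n_used < 1).any():
        raise ValidationError("a sample has no non-missing probes in the subset")
    return pd.DataFrame(
        {
            "sample_id": betas.columns,
            "assay": assay,
            "context": context,
            "mdi": mdi.to_numpy(),
            "n_probes_used": n_used.to_numpy(),
        }
    )


def mdi_by_context(
    betas: pd.DataFrame,
    reference: pd.Series,
    annotation: pd.DataFrame,
    contexts: Sequence[str],
    assay: str = "5hmC",
    aggregation: str = "mean",
) -> pd.DataFrame:
    """MDI per sample per genomic context (probes carrying the context flag).

    Contexts with zero flagged probes are omitted with a warning.
    """
    missing = [c for c in contexts if c not in annotation.columns]
    if missing:
        raise ValidationError(f"contexts absent from annotation: {missing}")
    out = []
    for context in contexts:
        probes = annotation.index[annotation[context].astype(bool)]
        probes = probes.intersection(reference.index).intersection(betas.index)
        if len(probes) == 0:
            logger.warning("mdi_by_context: context %r has no usable probes; omitted", context)
            continue
        out.append(
            compute_mdi(
                betas, reference, probe_subset=probes, assay=assay,
                context=context, aggregation=aggregation,
            )
        )
    if not out:
        return pd.DataFrame(columns=["sample_id", "assay", "context", "mdi", "n_probes_used"])
    return pd.concat(out, ignore_index=True)


def distribution_shift(
    tumor_medians: np.ndarray, nontumor_medians: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p for two beta-value vectors."""
    x = np.asarray(tumor_medians, dtype=float)
    y = np.asarray(nontumor_medians, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("distribution_shift: empty input vector")
    for v in (x, y):
        if (v < 0).any() or (v > 1).any():
            raise ValidationError("distribution_shift: values outside [0, 1]")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def rank_tests(mdi: pd.DataFrame, grouping: pd.Series) -> dict:
    """Kruskal-Wallis across groups plus Wilcoxon rank-sum for all pairs.

    ``mdi`` is a record table from :func:`compute_mdi`; ``grouping`` maps
    sample_id to a group label. A fully tied input (identical values in all
    groups) is flagged and reported with p = 1.
    """
    values = mdi.set_index("sample_id")["mdi"]
    groups = grouping.loc[values.index]
    by_group = [values[groups == g].to_numpy() for g in groups.unique()]
    if len(by_group) < 2:
        raise ValidationError("rank_tests: need at least 2 groups")
    out: dict = {}
    if np.ptp(np.concatenate(by_group)) == 0:
        out["kruskal"] = {"statistic": 0.0, "p": 1.0, "degenerate": True}
    else:
        kw = stats.kruskal(*by_group)
        out["kruskal"] = {"statistic": float(kw.statistic), "p": float(kw.pvalue),
                          "degenerate": False}
    pairs = {}
    labels = list(groups.unique())
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = values[groups == a], values[groups == b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                pairs[f"{a}_vs_{b}"] = {"statistic": 0.0, "p": 1.0, "degenerate": True}
            else:
                w = stats.ranksums(xa, xb)
                pairs[f"{a}_vs_{b}"] = {
                    "statistic": float(w.statistic), "p": float(w.pvalue), "degenerate": False
                }
    out["wilcoxon_pairs"] = pairs
    return out


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and p for two paired numeric vectors (>= 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman_correlation: need >= 3 paired values")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def grubbs_outlier(values: np.ndarray, alpha: float = 0.05) -> dict:
    """Two-sided single-outlier Grubbs test.

    G = max |x - mean| / sd, compared against the t-based critical value
    G_crit = ((n-1)/sqrt(n)) sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}. Zero-variance input returns a no-outlier
    decision with G = 0.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("grubbs_outlier: need >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return {"index": None, "G": 0.0, "critical": np.inf, "outlier": False}
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    crit = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return {"index": idx, "G": g, "critical": crit, "outlier": g > crit}


def context_model(
    mdi: pd.DataFrame,
    tumor_type: pd.Series,
    reference_context: str | None = None,
) -> pd.DataFrame:
    """OLS of MDI on context indicators adjusted for tumor type.

    Returns per-context coefficient, SE and p relative to the reference
    context (default: first context alphabetically). Raises on
    rank-deficient designs, naming the aliased columns.
    """
    import statsmodels.api as sm

    df = mdi.copy()
    df["tumor_type"] = tumor_type.loc[df["sample_id"]].to_numpy()
    contexts = sorted(df["context"].unique())
    if len(contexts) < 2:
        raise ValidationError("context_model: need >= 2 contexts")
    ref = reference_context or contexts[0]
    if ref not in contexts:
        raise ValidationError(f"reference context {ref!r} not present")

    ctx_dummies = pd.get_dummies(df["context"], prefix="context", dtype=float)
    ctx_dummies = ctx_dummies.drop(columns=f"context_{ref}")
    type_dummies = pd.get_dummies(df["tumor_type"], prefix="type", drop_first=True, dtype=float)
    design = pd.concat(
        [pd.Series(1.0, index=df.index, name="intercept"), ctx_dummies, type_dummies], axis=1
    )
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify aliased columns by QR pivoting on the gram matrix
        _, r = np.linalg.qr(design.to_numpy())
        aliased = [design.columns[j] for j in range(design.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValidationError(f"context_model: rank-deficient design, aliased columns {aliased}")
    fit = sm.OLS(df["mdi"].to_numpy(), design.to_numpy()).fit()
    rows = []
    for j, name in enumerate(design.columns):
        if not name.startswith("context_"):
            continue
        rows.append(
            {
                "context": name.removeprefix("context_"),
                "reference": ref,
                "coefficient": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "p": float(fit.pvalues[j]),
            }
        )
    return pd.DataFrame(rows)
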