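"""Genomic-context enrichment with probe-type-stratified Mantel-Haenszel tests.

Infinium Type I and Type II probe chemistries differ in their context
distribution and dynamic range, so enrichment of a hit set in a genomic
context is tested with the Mantel-Haenszel common odds ratio over the two
design-type strata:

    OR_MH = sum_s (a_s d_s / n_s) / sum_s (b_s c_s / n_s)

with a 95% CI from the Robins-Breslow-Greenland variance of log OR_MH and a
p-value from the MH chi-square statistic (no continuity correction by
default). Also provides the Spearman trend of context proportions across the
stepwise model series and exact Venn-partition cardinalities for hit-set
sharing.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError


def build_stratified_tables(
    hits: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    context: str,
    strata_column: str = "design_type",
) -> dict[str, tuple[int, int, int, int]]:
    """Cross-tabulate hit x context per design-type stratum.

    Returns {stratum: (a, b, c, d)} with a = hit & context,
    b = hit & not-context, c = non-hit & context, d = non-hit & not-context.
    """
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    uni = annotation.loc[annotation.index.intersection(pd.Index(sorted(universe)))]
    if len(uni) != len(universe):
        raise ValidationError("universe probes missing from annotation")
    if context not in annotation.columns:
        raise ValidationError(f"context {context!r} absent from annotation")
    is_hit = uni.index.isin(list(hits))
    in_ctx = uni[context].astype(bool).to_numpy()
    tables = {}
    for stratum in sorted(uni[strata_column].unique()):
        s = (uni[strata_column] == stratum).to_numpy()
        a = int((s & is_hit & in_ctx).sum())
        b = int((s & is_hit & ~in_ctx).sum())
        c = int((s & ~is_hit & in_ctx).sum())
        d = int((s & ~is_hit & ~in_ctx).sum())
        tables[stratum] = (a, b, c, d)
    return tables


def mantel_haenszel(
    tables: Mapping[str, tuple[int, int, int, int]],
    continuity_correction: bool = False,
) -> dict:
    """Common odds ratio, RBG 95% CI and MH chi-square p over strata.

    Empty strata (n_s = 0) are skipped; a zero denominator reports an
    infinite OR with a one-sided CI.
    """
    used = {s: t for s, t in tables.items() if sum(t) > 0}
    if not used:
        raise ValidationError("mantel_haenszel: all strata empty")

    num = den = 0.0
    # RBG variance components
    p_sum = q_sum = ps_qr = 0.0
    a_sum = e_sum = v_sum = 0.0
    for a, b, c, d in used.values():
        n = a + b + c + d
        r_s = a * d / n
        s_s = b * c / n
        num += r_s
        den += s_s
        p = (a + d) / n
        q = (b + c) / n
        p_sum += p * r_s
        q_sum += q * s_s
        ps_qr += p * s_s + q * r_s
        # chi-square components
        row1, col1 = a + b, a + c
        a_sum += a
        e_sum += row1 * col1 / n
        if n > 1:
            v_sum += row1 * (n - row1) * col1 * (n - col1) / (n**2 * (n - 1))

    if den == 0.0:
        or_mh = np.inf
        ci = (np.nan, np.inf)
    else:
        or_mh = num / den
        if num > 0:
            var_log = (
                p_sum / (2 * num**2) + ps_qr / (2 * num * den) + q_sum / (2 * den**2)
            )
            z = stats.norm.ppf(0.975)
            ci = (
                float(or_mh * np.exp(-z * np.sqrt(var_log))),
                float(or_mh * np.exp(z * np.sqrt(var_log))),
            )
        else:
            ci = (0.0, np.nan)

    if v_sum > 0:
        diff = abs(a_sum - e_sum)
        if continuity_correction:
            diff = max(diff - 0.5, 0.0)
        chi2 = diff**2 / v_sum
        p_val = float(stats.chi2.sf(chi2, 1))
    else:
        chi2, p_val = 0.0, 1.0

    return {
        "or_mh": float(or_mh),
        "ci95": ci,
        "chi2": float(chi2),
        "p": p_val,
        "n_strata_used": len(used),
    }


def enrichment_test(
    hits: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    context: str,
    direction_label: str = "all",
    continuity_correction: bool = False,
) -> dict:
    """Convenience: tabulate then test one context; carries counts provenance."""
    tables = build_stratified_tables(hits, universe, annotation, context)
    res = mantel_haenszel(tables, continuity_correction=continuity_correction)
    res.update({"context": context, "direction": direction_label, "tables": tables})
    return res


def context_trend(
    hit_sets: Mapping[int, set[str]],
    annotation: pd.DataFrame,
    context: str,
) -> dict:
    """Spearman correlation between k and the context proportion of hits_k.

    Fewer than 3 non-empty hit sets yields an undefined (flagged) result.
    """
    ks, props = [], []
    for k in sorted(hit_sets):
        hits = hit_sets[k]
        if not hits:
            continue
        sub = annotation.loc[annotation.index.intersection(pd.Index(sorted(hits)))]
        ks.append(k)
        props.append(float(sub[context].astype(bool).mean()))
    if len(ks) < 3:
        return {"context": context, "rho": np.nan, "p": np.nan, "defined": False}
    rho, p = stats.spearmanr(ks, props)
    return {
        "context": context,
        "rho": float(rho),
        "p": float(p),
        "defined": bool(np.isfinite(rho)),
        "k": ks,
        "proportions": props,
    }


def sharing_sets(named_sets: Mapping[str, set[str]]) -> dict[tuple[bool, ...], int]:
    """Exact cardinality of every region of the Venn partition.

    Keys are membership tuples aligned with sorted set names; the all-False
    region is omitted. Cardinalities sum to the union size by construction.
    """
    if len(named_sets) < 2:
        raise ValidationError("sharing_sets: need >= 2 sets")
    names = sorted(named_sets)
    union = set().union(*named_sets.values())
    out = {}
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = set(union)
        for name, member in zip(names, pattern):
            region &= named_sets[name] if member else (union - named_sets[name])
        out[pattern] = len(region)
    out["names"] = names  # type: ignore[index]
    return out
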