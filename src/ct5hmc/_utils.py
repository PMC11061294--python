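"""Small shared numerics: FDR adjustment, seed derivation, simplex checks."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError

SIMPLEX_TOL = 1e-6


def bh_adjust(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, NaN-safe.

    ``pi0 < 1`` rescales the adjusted values (Storey-style q-values with a
    fixed null proportion estimate).
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() > 0:
        q[ok] = multipletests(p[ok], method="fdr_bh")[1] * pi0
    return np.clip(q, 0.0, 1.0)


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Fixed-lambda Storey estimate of the null proportion pi0."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return 1.0
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def check_beta_matrix(mat: pd.DataFrame, name: str = "betas") -> pd.DataFrame:
    """Validate a probes x samples matrix of fractional values in [0, 1]."""
    values = mat.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValidationError(f"{name}: values outside [0, 1]")
    return mat


def check_simplex_rows(comp: pd.DataFrame, tol: float = SIMPLEX_TOL) -> pd.DataFrame:
    """Validate that composition rows are non-negative and sum to 1."""
    values = comp.to_numpy(dtype=float)
    if (values < -tol).any():
        raise ValidationError("composition: negative fractions")
    sums = values.sum(axis=1)
    bad = np.abs(sums - 1.0) > tol
    if bad.any():
        offender = comp.index[np.argmax(bad)]
        raise ValidationError(
            f"composition: row {offender!r} sums to {sums[bad][0]:.6g}, not 1"
        )
    return comp
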