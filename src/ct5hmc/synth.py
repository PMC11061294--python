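"""Synthetic cohort generator for paired BS/oxBS methylation studies.

Emulates the statistical structure of a pediatric CNS tumor cohort profiled
with tandem bisulfite (BS) and oxidative-bisulfite (oxBS) conversion on an
EPIC-like probe set, together with matched cell-type compositions from
single-nuclei data and bulk RNA-seq counts:

* per-cell-type true 5mC/5hmC profiles with genome-wide 5hmC prevalence a
  small fraction of 5mC (~6% by default),
* Dirichlet cell-type compositions that may differ between tumor groups and
  non-tumor tissue,
* planted cell-type- or bulk-level modification effects with an auditable
  clip report (ground truth for recovery tests),
* Beta-distributed measurement noise on the bulk mixtures (BS reads m + h,
  oxBS reads m),
* negative-binomial gene counts with planted log2 fold changes,
* per-nucleus QC metrics plus HTO and genotype demultiplexing calls
  corrupted from truth at configurable rates.

Every operation is deterministic given the config seed; independent stages
draw from seeds derived per stage name so they can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ValidationError
from ._utils import check_simplex_rows, derive_seed

DEFAULT_CELL_TYPES = ("NEU", "NSC", "OPC", "RGC", "UBC", "other")
DEFAULT_GROUPS = {"NonTumor": 2, "ATC": 8, "EMB": 6, "EPN": 10, "GNN": 8}

# Qualitative placeholders: non-tumor tissue neuron-rich, tumors shifted
# toward progenitor-like cell types (NSC/OPC/RGC/UBC).
DEFAULT_CONCENTRATIONS = {
    "NonTumor": (12.0, 1.5, 1.5, 1.5, 1.5, 4.0),
    "ATC": (5.0, 4.0, 5.0, 3.0, 1.5, 4.0),
    "EMB": (2.5, 6.0, 3.0, 5.0, 4.0, 4.0),
    "EPN": (4.0, 4.0, 3.0, 6.0, 2.0, 4.0),
    "GNN": (8.0, 3.0, 3.0, 3.0, 2.0, 4.0),
}

CONTEXT_FLAGS = (
    "TSS200",
    "TSS1500",
    "gene_body",
    "first_exon",
    "UTR5",
    "UTR3",
    "exon_boundary",
    "enhancer",
    "DHS",
    "TFBS",
    "open_chromatin",
)

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")


@dataclass
class CohortConfig:
    """Study-level knobs of the synthetic cohort.

    Defaults mirror the emulated study: five cell types of interest plus a
    remainder, four tumor groups vs non-tumor tissue at the cohort's sample
    sizes, and genome-wide 5hmC at 6% of 5mC.
    """

    n_probes: int = 10_000
    n_genes: int = 1_000
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    groups: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    nontumor_group: str = "NonTumor"
    dirichlet_concentrations: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CONCENTRATIONS.items()}
    )
    hmc_to_mc_ratio: float = 0.06
    measurement_precision: float = 200.0
    nb_dispersion: float = 0.1
    context_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "TSS200": 0.08,
            "TSS1500": 0.10,
            "gene_body": 0.35,
            "first_exon": 0.05,
            "UTR5": 0.08,
            "UTR3": 0.05,
            "exon_boundary": 0.05,
            "enhancer": 0.12,
            "DHS": 0.25,
            "TFBS": 0.20,
            "open_chromatin": 0.15,
        }
    )
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be positive")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        for g, n in self.groups.items():
            if n <= 0:
                raise ConfigurationError(f"groups[{g!r}]: sample count must be positive")
        for g in self.groups:
            conc = self.dirichlet_concentrations.get(g)
            if conc is None:
                raise ConfigurationError(f"dirichlet_concentrations missing group {g!r}")
            if len(conc) != len(self.cell_types):
                raise ConfigurationError(
                    f"dirichlet_concentrations[{g!r}]: length must match cell_types"
                )
            if any(a <= 0 for a in conc):
                raise ConfigurationError(f"dirichlet_concentrations[{g!r}]: must be positive")
        if not (0.0 < self.hmc_to_mc_ratio <= 1.0):
            raise ConfigurationError("hmc_to_mc_ratio must be in (0, 1]")
        if self.measurement_precision <= 0:
            raise ConfigurationError("measurement_precision must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        for k, p in self.context_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"context_probs[{k!r}] must be in [0, 1]")
        return self

    def probe_ids(self) -> pd.Index:
        width = len(str(self.n_probes))
        return pd.Index([f"cg{i:0{max(width, 6)}d}" for i in range(self.n_probes)], name="probe_id")

    def gene_ids(self) -> pd.Index:
        return pd.Index([f"G{i:05d}" for i in range(self.n_genes)], name="gene_id")


def _rng(config: CohortConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(config.seed, stage))


def simulate_reference_profiles(config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Per-cell-type true 5mC and 5hmC levels (probes x cell types).

    5mC is bimodal (mostly unmethylated or mostly methylated CpGs) with
    correlated cell-type variation around a shared per-probe base level.
    5hmC is drawn proportional to 5mC with exponential probe-to-probe
    variation so that genome-wide mean(h)/mean(m) tracks
    ``hmc_to_mc_ratio``; entries are clipped to keep m + h <= 1.
    """
    config.validate()
    rng = _rng(config, "reference_profiles")
    probes = config.probe_ids()
    k = len(config.cell_types)

    high = rng.random(config.n_probes) < 0.6
    base = np.where(
        high,
        rng.beta(8.0, 0.9, size=config.n_probes),
        rng.beta(0.9, 8.0, size=config.n_probes),
    )
    base = np.clip(base, 1e-3, 1 - 1e-3)
    kappa = 50.0
    m = rng.beta(kappa * base[:, None], kappa * (1.0 - base[:, None]), size=(config.n_probes, k))

    scale = rng.exponential(1.0, size=(config.n_probes, k))
    h = np.minimum(config.hmc_to_mc_ratio * m * scale, 1.0 - m)
    # clipping at m + h <= 1 drags the realized prevalence below target at
    # heavily methylated probes; rescale-and-reclip until it converges
    for _ in range(12):
        realized = h.mean() / m.mean()
        if realized <= 0 or abs(realized / config.hmc_to_mc_ratio - 1.0) < 1e-3:
            break
        h = np.minimum(h * (config.hmc_to_mc_ratio / realized), 1.0 - m)

    m_df = pd.DataFrame(m, index=probes, columns=list(config.cell_types))
    h_df = pd.DataFrame(h, index=probes, columns=list(config.cell_types))
    return {"5mC": m_df, "5hmC": h_df}


def simulate_samples(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample sheet (group, sex, age, purity, grade) and Dirichlet compositions.

    Covariates are drawn independently of group; composition differences
    between groups are controlled entirely by the per-group Dirichlet
    concentrations (pass identical vectors for a composition-null cohort).
    """
    config.validate()
    if len(config.groups) < 2:
        raise ConfigurationError("groups: at least 2 groups required")
    rng = _rng(config, "samples")

    rows = []
    comps = []
    for group, n in config.groups.items():
        conc = np.asarray(config.dirichlet_concentrations[group], dtype=float)
        w = rng.dirichlet(conc, size=n)
        is_tumor = group != config.nontumor_group
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "age": float(np.round(rng.uniform(1.0, 18.0), 2)),
                    # drawn independently of group (clean regime): a purity
                    # confounded with the group indicator would alias the contrast
                    "purity": float(np.round(rng.beta(8.0, 2.0), 3)),
                    "grade": int(rng.integers(1, 5)) if is_tumor else 0,
                }
            )
        comps.append(w)

    sheet = pd.DataFrame(rows).set_index("sample_id")
    composition = pd.DataFrame(
        np.vstack(comps), index=sheet.index, columns=list(config.cell_types)
    )
    if len(config.cell_types) == 1:
        composition.iloc[:, 0] = 1.0
    return sheet, composition


def make_truth_table(records: Sequence[dict]) -> pd.DataFrame:
    """Assemble and validate a planted-effect truth table.

    Each record: probe_id, cell_type (granular name or ``"bulk"`` for all
    cell types), group, delta_5hmC, delta_5mC (signed fractions in [-1, 1]).
    """
    truth = pd.DataFrame(
        records, columns=["probe_id", "cell_type", "group", "delta_5hmC", "delta_5mC"]
    )
    if truth.empty:
        return truth
    for col in ("delta_5hmC", "delta_5mC"):
        if (truth[col].abs() > 1).any():
            raise ValidationError(f"truth table: {col} outside [-1, 1]")
    if truth.duplicated(["probe_id", "cell_type", "group"]).any():
        raise ValidationError("truth table: duplicate (probe, cell_type, group) entries")
    return truth


def plant_effects(
    truth: pd.DataFrame,
    profiles: dict[str, pd.DataFrame],
    groups: Sequence[str],
) -> tuple[dict[str, dict[str, pd.DataFrame]], pd.DataFrame]:
    """Apply planted deltas to reference profiles, per group.

    Returns ``{group: {"5mC": df, "5hmC": df}}`` (unaffected groups share the
    reference values) and a clip report listing every entry whose realized
    delta differs from the requested one. 5mC is shifted first and clipped to
    [0, 1]; 5hmC is then clipped to [0, 1 - m] so m + h <= 1 always holds.
    """
    m_ref, h_ref = profiles["5mC"], profiles["5hmC"]
    cell_types = list(m_ref.columns)
    out = {g: {"5mC": m_ref.copy(), "5hmC": h_ref.copy()} for g in groups}
    clip_rows = []
    if truth is None or len(truth) == 0:
        return out, pd.DataFrame(
            columns=["probe_id", "cell_type", "group", "assay", "requested", "realized"]
        )

    unknown_probes = set(truth["probe_id"]) - set(m_ref.index)
    if unknown_probes:
        raise ValidationError(f"truth table: unknown probe ids {sorted(unknown_probes)[:5]}")
    unknown_ct = set(truth["cell_type"]) - set(cell_types) - {"bulk"}
    if unknown_ct:
        raise ValidationError(f"truth table: unknown cell types {sorted(unknown_ct)}")
    unknown_groups = set(truth["group"]) - set(groups)
    if unknown_groups:
        raise ValidationError(f"truth table: unknown groups {sorted(unknown_groups)}")

    for rec in truth.itertuples(index=False):
        targets = cell_types if rec.cell_type == "bulk" else [rec.cell_type]
        for ct in targets:
            m0 = out[rec.group]["5mC"].at[rec.probe_id, ct]
            h0 = out[rec.group]["5hmC"].at[rec.probe_id, ct]
            m1 = float(np.clip(m0 + rec.delta_5mC, 0.0, 1.0))
            h1 = float(np.clip(h0 + rec.delta_5hmC, 0.0, 1.0 - m1))
            out[rec.group]["5mC"].at[rec.probe_id, ct] = m1
            out[rec.group]["5hmC"].at[rec.probe_id, ct] = h1
            for assay, requested, realized in (
                ("5mC", rec.delta_5mC, m1 - m0),
                ("5hmC", rec.delta_5hmC, h1 - h0),
            ):
                if abs(realized - requested) > 1e-12:
                    clip_rows.append(
                        {
                            "probe_id": rec.probe_id,
                            "cell_type": ct,
                            "group": rec.group,
                            "assay": assay,
                            "requested": requested,
                            "realized": realized,
                        }
                    )
    report = pd.DataFrame(
        clip_rows, columns=["probe_id", "cell_type", "group", "assay", "requested", "realized"]
    )
    return out, report


def render_measurements(
    group_profiles: dict[str, dict[str, pd.DataFrame]],
    composition: pd.DataFrame,
    sheet: pd.DataFrame,
    config: CohortConfig,
) -> dict[str, pd.DataFrame]:
    """Mix cell-type profiles into bulk samples and add array noise.

    Bulk truth per sample i: m_i = sum_k w_ik m_k, h_i = sum_k w_ik h_k using
    that sample's group profile. BS measures m + h and oxBS measures m; the
    observed betas are Beta-distributed with those means and a shared
    precision pseudo-count. Returns bs, ox, true_m, true_h (probes x samples).
    """
    config.validate()
    check_simplex_rows(composition)
    rng = _rng(config, "measurements")

    some_group = next(iter(group_profiles))
    probes = group_profiles[some_group]["5mC"].index
    cell_types = list(group_profiles[some_group]["5mC"].columns)
    if list(composition.columns) != cell_types:
        raise ValidationError("composition columns do not match profile cell types")

    n_s = len(composition)
    true_m = np.empty((len(probes), n_s))
    true_h = np.empty((len(probes), n_s))
    for j, sample in enumerate(composition.index):
        group = sheet.loc[sample, "group"]
        prof = group_profiles[group]
        w = composition.loc[sample].to_numpy()
        true_m[:, j] = prof["5mC"].to_numpy() @ w
        true_h[:, j] = prof["5hmC"].to_numpy() @ w

    prec = config.measurement_precision

    def noisy(mean: np.ndarray) -> np.ndarray:
        mu = np.clip(mean, 1e-6, 1.0 - 1e-6)
        return rng.beta(mu * prec, (1.0 - mu) * prec)

    bs = noisy(true_m + true_h)
    ox = noisy(true_m)
    cols = composition.index
    return {
        "bs": pd.DataFrame(bs, index=probes, columns=cols),
        "ox": pd.DataFrame(ox, index=probes, columns=cols),
        "true_m": pd.DataFrame(true_m, index=probes, columns=cols),
        "true_h": pd.DataFrame(true_h, index=probes, columns=cols),
    }


def simulate_counts(
    config: CohortConfig,
    sheet: pd.DataFrame,
    de_truth: pd.DataFrame | None = None,
    baseline: np.ndarray | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial gene counts (genes x samples) with planted log2FCs.

    ``de_truth`` is a genes x groups table of log2 fold changes relative to
    the baseline expression (missing genes/groups mean no change). Counts are
    NB with mean baseline * 2**log2FC * size_factor and dispersion
    ``nb_dispersion`` (variance mu + dispersion * mu**2).
    """
    config.validate()
    rng = _rng(config, "counts")
    genes = config.gene_ids()
    if baseline is None:
        baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=config.n_genes))
    baseline = np.asarray(baseline, dtype=float)
    if (baseline < 0).any():
        raise ConfigurationError("baseline: negative expression means")
    if size_factors is None:
        size_factors = pd.Series(1.0, index=sheet.index)

    lfc = np.zeros((config.n_genes, len(sheet)))
    if de_truth is not None and len(de_truth):
        for group in de_truth.columns:
            cols = (sheet["group"] == group).to_numpy()
            vals = de_truth.reindex(genes)[group].fillna(0.0).to_numpy()
            lfc[:, cols] = vals[:, None]

    mu = baseline[:, None] * (2.0**lfc) * size_factors.to_numpy()[None, :]
    disp = config.nb_dispersion
    if disp < 1e-8:
        counts = rng.poisson(mu)
    else:
        # NB as gamma-Poisson: shape r = 1/disp, p = r / (r + mu)
        r = 1.0 / disp
        counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
        counts = np.where(mu == 0, 0, counts)
    return pd.DataFrame(counts, index=genes, columns=sheet.index)


def simulate_nuclei(
    n: int,
    sample_pool: Sequence[str],
    error_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-nucleus QC metrics plus HTO and genotype calls corrupted from truth.

    ``error_rates`` keys (all default 0): hto_doublet, hto_negative,
    hto_misassign, geno_doublet, geno_unassigned, geno_misassign. Truth is
    retained in the ``true_sample`` column for scoring.
    """
    rates = {
        "hto_doublet": 0.0,
        "hto_negative": 0.0,
        "hto_misassign": 0.0,
        "geno_doublet": 0.0,
        "geno_unassigned": 0.0,
        "geno_misassign": 0.0,
    }
    rates.update(error_rates or {})
    for key, val in rates.items():
        if not (0.0 <= val <= 1.0):
            raise ConfigurationError(f"error_rates[{key!r}] must be in [0, 1]")
    if n <= 0:
        raise ConfigurationError("n must be positive")

    rng = np.random.default_rng(seed)
    samples = list(sample_pool)
    truth = rng.choice(samples, size=n)

    def corrupt(true_calls, special: list[tuple[str, float]], misassign: float):
        calls = true_calls.astype(object).copy()
        u = rng.random(n)
        edge = 0.0
        assigned = np.zeros(n, dtype=bool)
        for token, rate in special:
            pick = (~assigned) & (u < edge + rate)
            calls[pick] = token
            assigned |= pick
            edge += rate
        mis = (~assigned) & (rng.random(n) < misassign)
        for i in np.nonzero(mis)[0]:
            others = [s for s in samples if s != true_calls[i]]
            if others:
                calls[i] = rng.choice(others)
        return calls

    hto = corrupt(
        truth,
        [("Doublet", rates["hto_doublet"]), ("Negative", rates["hto_negative"])],
        rates["hto_misassign"],
    )
    geno = corrupt(
        truth,
        [("Doublet", rates["geno_doublet"]), ("Unassigned", rates["geno_unassigned"])],
        rates["geno_misassign"],
    )

    n_features = np.round(np.exp(rng.normal(np.log(4000.0), 0.5, size=n))).astype(int)
    pct_mito = np.clip(rng.beta(1.0, 30.0, size=n) * 100.0, 0.0, 100.0)
    return pd.DataFrame(
        {
            "barcode": [f"BC{i:06d}" for i in range(n)],
            "n_features": n_features,
            "pct_mito": np.round(pct_mito, 3),
            "hto_call": hto,
            "genotype_call": geno,
            "true_sample": truth,
        }
    ).set_index("barcode")


def simulate_annotation(config: CohortConfig) -> pd.DataFrame:
    """BED-like probe annotation with design type, island relation and flags.

    Contexts are independent Bernoulli flags at the configured probabilities;
    each probe maps to 0-2 gene ids drawn from the cohort's gene universe.
    """
    config.validate()
    rng = _rng(config, "annotation")
    probes = config.probe_ids()
    n = config.n_probes

    start = np.sort(rng.integers(1, 2_000_000_000, size=n))
    ann = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=n)],
            "start": start,
            "end": start + 2,
            # EPIC-like mix: ~16% Type I probes
            "design_type": np.where(rng.random(n) < 0.16, "I", "II"),
            "island_relation": rng.choice(
                ISLAND_RELATIONS, size=n, p=(0.30, 0.20, 0.10, 0.40)
            ),
        },
        index=probes,
    )
    for flag in CONTEXT_FLAGS:
        p = config.context_probs.get(flag, 0.0)
        ann[flag] = (rng.random(n) < p).astype(int)

    genes = config.gene_ids().to_numpy()
    n_mapped = rng.choice([0, 1, 2], size=n, p=(0.25, 0.60, 0.15))
    mapped = [";".join(rng.choice(genes, size=k, replace=False)) for k in n_mapped]
    ann["genes"] = mapped
    return ann


@dataclass
class Cohort:
    """Bundle of everything one synthetic cohort produces."""

    config: CohortConfig
    sheet: pd.DataFrame
    composition: pd.DataFrame
    annotation: pd.DataFrame
    reference_profiles: dict[str, pd.DataFrame]
    group_profiles: dict[str, dict[str, pd.DataFrame]]
    truth: pd.DataFrame
    clip_report: pd.DataFrame
    bs: pd.DataFrame
    ox: pd.DataFrame
    true_m: pd.DataFrame
    true_h: pd.DataFrame
    counts: pd.DataFrame
    de_truth: pd.DataFrame | None


def simulate_cohort(
    config: CohortConfig,
    truth: pd.DataFrame | None = None,
    de_truth: pd.DataFrame | None = None,
) -> Cohort:
    """Run the full generator: profiles -> samples -> effects -> measurements -> counts."""
    config.validate()
    profiles = simulate_reference_profiles(config)
    sheet, composition = simulate_samples(config)
    truth = truth if truth is not None else make_truth_table([])
    group_profiles, clip_report = plant_effects(truth, profiles, list(config.groups))
    meas = render_measurements(group_profiles, composition, sheet, config)
    counts = simulate_counts(config, sheet, de_truth=de_truth)
    annotation = simulate_annotation(config)
    return Cohort(
        config=config,
        sheet=sheet,
        composition=composition,
        annotation=annotation,
        reference_profiles=profiles,
        group_profiles=group_profiles,
        truth=truth,
        clip_report=clip_report,
        bs=meas["bs"],
        ox=meas["ox"],
        true_m=meas["true_m"],
        true_h=meas["true_h"],
        counts=counts,
        de_truth=de_truth,
    )
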