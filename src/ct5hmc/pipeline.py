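"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the analysis flow: simulate (or load) -> oxBS MLE ->
dysregulation indices -> stepwise EWAS -> cell-type interaction models ->
context enrichment -> differential expression -> integration. Every output
file is hashed into a run manifest together with the config and the derived
per-stage seeds, so identical configs reproduce identical manifests for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import celldmc, enrichment, ewas, expression, io, mdi, oxbs, synth
from ._errors import ValidationError
from ._utils import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "oxbs", "mdi", "ewas", "dmct", "enrichment", "de")
DEFAULT_CONTEXTS = ("TSS200", "TSS1500", "gene_body", "enhancer", "DHS", "open_chromatin")


@dataclass
class PipelineConfig:
    """Validated view of the YAML pipeline configuration."""

    outdir: Path
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, str] | None = None
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"q": 0.05, "p_adj": 0.05, "alpha": 0.05}
    )
    cell_type_order: tuple = ewas.DEFAULT_CELL_TYPE_ORDER
    contexts: tuple = DEFAULT_CONTEXTS
    stages: Mapping[str, bool] = field(default_factory=dict)
    nontumor_group: str = "NonTumor"
    oxbs_pseudocounts: Mapping[str, float] = field(
        default_factory=lambda: {"n_bs": 100.0, "n_ox": 100.0}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["outdir"] = Path(raw.get("outdir", "ct5hmc_run"))
        if "cell_type_order" in kwargs:
            kwargs["cell_type_order"] = tuple(kwargs["cell_type_order"])
        if "contexts" in kwargs:
            kwargs["contexts"] = tuple(kwargs["contexts"])
        return cls(**kwargs)

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    def stage_seed(self, name: str) -> int:
        return derive_seed(self.seed, f"stage:{name}")


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every problem with the config; empty list means valid."""
    failures: list[str] = []
    for key, val in config.thresholds.items():
        if not (0.0 < float(val) < 1.0):
            failures.append(f"thresholds[{key!r}] = {val}: must be in (0, 1)")
    if config.simulate is None and config.inputs is None:
        failures.append("either 'simulate' or 'inputs' must be provided")
    if config.inputs is not None:
        for name, path in config.inputs.items():
            if not Path(path).exists():
                failures.append(f"inputs[{name!r}]: missing file {path}")
    if config.simulate is not None:
        try:
            _make_cohort_config(config).validate()
        except Exception as exc:  # report, do not raise
            failures.append(f"simulate: {exc}")
    for stage in config.stages:
        if stage not in DEFAULT_STAGES:
            failures.append(f"stages[{stage!r}]: unknown stage")
    return failures


def _make_cohort_config(config: PipelineConfig) -> synth.CohortConfig:
    params = dict(config.simulate or {})
    params.setdefault("seed", config.stage_seed("simulate"))
    return synth.CohortConfig(**params)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    failures = validate_config(config)
    if failures:
        raise ValidationError("invalid config: " + "; ".join(failures))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in DEFAULT_STAGES},
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    q_thr = float(config.thresholds.get("q", 0.05))

    def emit(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # ---- inputs -----------------------------------------------------
        if config.simulate is not None:
            cohort_cfg = _make_cohort_config(config)
            cohort = synth.simulate_cohort(cohort_cfg)
            sheet, composition, annotation = cohort.sheet, cohort.composition, cohort.annotation
            bs, ox, counts = cohort.bs, cohort.ox, cohort.counts
            if config.stage_enabled("simulate"):
                emit("bs", io.write_matrix(bs, outdir / "bs.tsv.gz"))
                emit("ox", io.write_matrix(ox, outdir / "ox.tsv.gz"))
                emit("sheet", io.write_matrix(sheet, outdir / "samples.tsv"))
                emit("composition", io.write_matrix(composition, outdir / "composition.tsv"))
                emit("annotation", io.write_annotation(annotation, outdir / "probes.bed"))
                emit("counts", io.write_matrix(counts, outdir / "counts.tsv.gz"))
                manifest["stages"]["simulate"] = "ok"
        else:
            paths = config.inputs
            bs = io.read_matrix(paths["bs"])
            ox = io.read_matrix(paths["ox"])
            sheet = io.read_matrix(paths["sheet"])
            composition = io.read_matrix(paths["composition"])
            annotation = io.read_annotation(paths["annotation"])
            counts = io.read_matrix(paths["counts"]) if "counts" in paths else None

        groups = [g for g in sheet["group"].unique() if g != config.nontumor_group]
        nontumor_ids = sheet.index[sheet["group"] == config.nontumor_group]

        # ---- oxBS MLE ---------------------------------------------------
        mc = hc = None
        if config.stage_enabled("oxbs"):
            mc, hc, boundary = oxbs.estimate_modifications(
                bs, ox, **config.oxbs_pseudocounts
            )
            emit("5mC", io.write_matrix(mc, outdir / "5mc.tsv.gz"))
            emit("5hmC", io.write_matrix(hc, outdir / "5hmc.tsv.gz"))
            manifest["stages"]["oxbs"] = "ok"

        # ---- MDI --------------------------------------------------------
        if config.stage_enabled("mdi") and mc is not None:
            records = []
            for assay, mat in (("5mC", mc), ("5hmC", hc)):
                ref = mdi.reference_medians(mat, nontumor_ids)
                records.append(mdi.compute_mdi(mat, ref, assay=assay))
                records.append(
                    mdi.mdi_by_context(mat, ref, annotation, list(config.contexts), assay=assay)
                )
            import pandas as pd

            mdi_table = pd.concat(records, ignore_index=True)
            emit("mdi", io.write_table(mdi_table, outdir / "mdi.tsv"))
            manifest["stages"]["mdi"] = "ok"

        # ---- stepwise EWAS ----------------------------------------------
        hit_sets_by_group: dict[str, set] = {}
        stepwise_hits: dict[str, dict[int, set]] = {}
        if config.stage_enabled("ewas") and hc is not None:
            for group in groups:
                series = ewas.stepwise_series(
                    hc, sheet, composition, group,
                    cell_type_order=config.cell_type_order,
                    nontumor_group=config.nontumor_group,
                    q_threshold=q_thr,
                )
                k_max = max(series)
                io.write_table(
                    series[k_max]["results"], outdir / f"ewas_5hmc_{group}_k{k_max}.tsv.gz"
                )
                emit(f"ewas_{group}", outdir / f"ewas_5hmc_{group}_k{k_max}.tsv.gz")
                hit_sets_by_group[group] = series[k_max]["hits"]
                stepwise_hits[group] = {k: series[k]["hits"] for k in series}
            counts_summary = {
                g: {k: len(h) for k, h in stepwise_hits[g].items()} for g in groups
            }
            sharing = (
                ewas.summarize_hits(hit_sets_by_group, annotation, config.contexts)
                if len(groups) >= 2
                else {}
            )
            emit(
                "ewas_summary",
                io.write_json(
                    {"stepwise_hit_counts": counts_summary, "sharing": sharing},
                    outdir / "ewas_summary.json",
                ),
            )
            manifest["stages"]["ewas"] = "ok"

        # ---- cell-type interaction models -------------------------------
        dmct_by_group: dict[str, Any] = {}
        if config.stage_enabled("dmct") and hc is not None:
            agg = celldmc.aggregate_celltypes(composition)
            for group in groups:
                keep = sheet.index[
                    (sheet["group"] == group) | (sheet["group"] == config.nontumor_group)
                ]
                phen = (sheet.loc[keep, "group"] == group).astype(float)
                res = celldmc.fit_dmct(
                    hc[keep], agg.loc[keep], phen, sheet=sheet.loc[keep]
                )
                dmct_by_group[group] = res
                io.write_table(res, outdir / f"dmct_5hmc_{group}.tsv.gz")
                emit(f"dmct_{group}", outdir / f"dmct_5hmc_{group}.tsv.gz")
            summary = celldmc.classify_dmct(dmct_by_group, q_threshold=q_thr)
            emit(
                "dmct_summary",
                io.write_json(
                    {
                        ct: {
                            "n_union": len(info["union"]),
                            "n_shared_all": len(info["intersection_all"]),
                        }
                        for ct, info in summary["sharing"].items()
                    },
                    outdir / "dmct_summary.json",
                ),
            )
            manifest["stages"]["dmct"] = "ok"

        # ---- context enrichment -----------------------------------------
        if config.stage_enabled("enrichment") and hit_sets_by_group:
            universe = set(annotation.index)
            rows = []
            for group, hits in hit_sets_by_group.items():
                if not hits:
                    continue
                for context in config.contexts:
                    res = enrichment.enrichment_test(hits, universe, annotation, context)
                    rows.append(
                        {
                            "group": group,
                            "context": context,
                            "or_mh": res["or_mh"],
                            "ci_low": res["ci95"][0],
                            "ci_high": res["ci95"][1],
                            "p": res["p"],
                        }
                    )
            import pandas as pd

            emit(
                "enrichment",
                io.write_table(pd.DataFrame(rows), outdir / "enrichment.tsv"),
            )
            manifest["stages"]["enrichment"] = "ok"

        # ---- differential expression ------------------------------------
        if config.stage_enabled("de") and counts is not None:
            for group in groups:
                res = expression.fit_nb_de(
                    counts, sheet, group, composition=composition,
                    cell_types=tuple(config.cell_type_order),
                    nontumor_group=config.nontumor_group,
                )
                io.write_table(res, outdir / f"de_{group}.tsv.gz")
                emit(f"de_{group}", outdir / f"de_{group}.tsv.gz")
            manifest["stages"]["de"] = "ok"

    except Exception as exc:
        manifest["failed_stage"] = {
            "error": f"{type(exc).__name__}: {exc}",
            "completed": list(manifest["stages"]),
        }
        io.write_json(manifest, outdir / "manifest.json")
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
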