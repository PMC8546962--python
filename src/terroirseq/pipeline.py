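"""End-to-end orchestration with a reproducibility manifest.

A run either simulates a synthetic study from a scenario config or loads
user-supplied count tables, then executes the requested stages in
dependency order (filter -> transform/diversity -> community tests /
mantel / concordance / signatures).  Every artifact is written under the
output directory and listed in ``manifest.json`` with its SHA-256 hash,
alongside all seeds and thresholds.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .compositional import (
    aitchison_distance,
    alpha_diversity,
    clr_transform,
    core_microbiome,
)
from .concordance import concordance_table, detection_overlap
from .datamodel import (
    CountTable,
    SampleMetadata,
    ValidationError,
    align_samples,
    filter_organelle_asvs,
)
from .permstats import (
    anosim,
    fdr_adjust,
    haversine_matrix,
    mantel,
    permanova,
    scale_center,
)
from .signatures import (
    amplicon_features,
    consensus_signature,
    fermentation_labels,
    summarize_timeseries,
)
from .synth import ScenarioConfig, generate_study

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "filter",
    "diversity",
    "community-tests",
    "mantel",
    "concordance",
    "signatures",
)


@dataclass
class RunConfig:
    outdir: str
    scenario: dict | None = None
    inputs: dict | None = None  # paths: bacterial, fungal, transcripts{tp: path}, metadata
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    prevalence: float = 0.90
    abundance: float = 0.01
    fdr_threshold: float = 0.1
    vita_p: float = 0.05
    n_permutations: int = 999
    signature_target: str = "site"
    signature_scheme: str = "split70"
    signature_seeds: int = 20
    signature_trees: int = 200
    concordance_species: str = "Hanseniaspora uvarum"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = tio.read_yaml(path)
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        if self.scenario is None and self.inputs is None:
            raise ValidationError("config needs either a scenario or input paths")
        if self.inputs is not None:
            needed = {"fungal", "metadata"}
            if "signatures" in self.stages or "concordance" in self.stages:
                needed |= {"transcripts"}
            missing = needed - set(self.inputs)
            if missing:
                raise ValidationError(
                    f"stages {self.stages} need input path(s): {sorted(missing)}"
                )
            for key, value in self.inputs.items():
                paths = value.values() if isinstance(value, dict) else [value]
                for p in paths:
                    if not Path(p).exists():
                        raise ValidationError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("terroirseq")
    root.addHandler(handler)
    manifest: dict = {
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
        "thresholds": {
            "prevalence": cfg.prevalence,
            "abundance": cfg.abundance,
            "fdr": cfg.fdr_threshold,
            "vita_p": cfg.vita_p,
        },
        "stages": {},
        "artifacts": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["artifacts"].append({"path": name, "sha256": _sha256(path)})

    try:
        # ---- acquire data ------------------------------------------------
        if cfg.scenario is not None:
            scenario = ScenarioConfig.from_dict({**cfg.scenario, "seed": cfg.seed})
            study = generate_study(scenario)
            bacterial, fungal = study.bacterial_counts, study.fungal_counts
            transcripts, meta = study.transcript_counts, study.metadata
            for p in study.write(outdir / "synthetic"):
                manifest["artifacts"].append(
                    {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                )
        else:
            bacterial = (
                tio.read_count_table(cfg.inputs["bacterial"], "16S")
                if "bacterial" in cfg.inputs
                else None
            )
            fungal = tio.read_count_table(cfg.inputs["fungal"], "ITS")
            transcripts = {
                float(tp): tio.read_count_table(path, "mRNA")
                for tp, path in cfg.inputs.get("transcripts", {}).items()
            }
            meta = tio.read_metadata(cfg.inputs["metadata"])
        if ("signatures" in cfg.stages or "concordance" in cfg.stages) and not transcripts:
            raise ValidationError(
                "signatures/concordance stages requested but no transcript tables"
            )

        # ---- stages ------------------------------------------------------
        if "filter" in cfg.stages and bacterial is not None:
            bacterial, removed = filter_organelle_asvs(bacterial)
            manifest["stages"]["filter"] = {"removed_organelle_asvs": len(removed)}
            emit("bacterial_filtered.tsv", lambda p: tio.write_count_table(bacterial, p))

        dna_mask = meta.frame["timepoint_hours"].isna()
        dna_meta = SampleMetadata(meta.frame[dna_mask].copy()) if dna_mask.any() else meta

        if "diversity" in cfg.stages:
            out = {}
            for name, table in (("bacterial", bacterial), ("fungal", fungal)):
                if table is None:
                    continue
                core = core_microbiome(table, cfg.prevalence, cfg.abundance)
                out[name] = {
                    "core_microbiome": core,
                    "shannon_mean": float(alpha_diversity(table, "shannon").mean()),
                    "chao1_mean": float(alpha_diversity(table, "chao1").mean()),
                }
            manifest["stages"]["diversity"] = {
                k: {"core_size": len(v["core_microbiome"])} for k, v in out.items()
            }
            emit("diversity.json", lambda p: tio.write_json(out, p))

        if "community-tests" in cfg.stages:
            results = {}
            for name, table in (("bacterial", bacterial), ("fungal", fungal)):
                if table is None:
                    continue
                aligned, m = align_samples(table, dna_meta)
                dm = aitchison_distance(clr_transform(aligned))
                for factor in ("site", "region", "vintage"):
                    groups = m.labels(factor)
                    if groups.nunique() < 2 or groups.value_counts().min() < 2:
                        continue
                    for test, fn in (("anosim", anosim), ("permanova", permanova)):
                        res = fn(dm, groups, n_perm=cfg.n_permutations, seed=cfg.seed)
                        results[f"{name}.{factor}.{test}"] = res.to_dict()
            manifest["stages"]["community-tests"] = {"n_tests": len(results)}
            emit("community_tests.json", lambda p: tio.write_json(results, p))

        if "mantel" in cfg.stages:
            sites = dna_meta.frame.groupby("site").first()
            geo = haversine_matrix(
                sites[["latitude_deg", "longitude_deg"]], ids=list(sites.index)
            )
            results, raw_p = {}, []
            env_cols = [
                c
                for c in ("precipitation_mm", "gdd", "pH", "titratable_acidity", "malic_acid")
                if c in sites.columns
            ]
            from .compositional import euclidean_distance

            for col in env_cols:
                scaled = scale_center(sites[[col]])
                if scaled.shape[1] == 0:
                    continue
                dm = euclidean_distance(scaled, metric_name=col)
                res = mantel(geo, dm, n_perm=cfg.n_permutations, seed=cfg.seed)
                results[f"geo~{col}"] = res.to_dict()
                raw_p.append(res.p_value)
            if raw_p:
                adjusted = fdr_adjust(raw_p)
                for key, adj in zip(list(results), adjusted):
                    results[key]["p_adjusted"] = float(adj)
                    results[key]["significant"] = bool(adj < cfg.fdr_threshold)
            manifest["stages"]["mantel"] = {"n_tests": len(results)}
            emit("mantel.json", lambda p: tio.write_json(results, p))

        if "concordance" in cfg.stages:
            res = concordance_table(fungal, transcripts, meta, cfg.concordance_species)
            any_tp = next(iter(transcripts.values()))
            overlap = detection_overlap(fungal, any_tp)
            payload = {
                "regressions": [vars(r) for r in res],
                "detection_overlap": overlap,
            }
            manifest["stages"]["concordance"] = {
                "n_timepoints": len(res),
                "n_shared_species": overlap["n_shared"],
            }
            emit("concordance.json", lambda p: tio.write_json(payload, p))

        if "signatures" in cfg.stages:
            features = summarize_timeseries(transcripts, meta)
            labels = fermentation_labels(features, meta, cfg.signature_target)
            labels.name = cfg.signature_target
            sig, models = consensus_signature(
                features,
                labels,
                scheme=cfg.signature_scheme,
                n_seeds=cfg.signature_seeds,
                base_seed=cfg.seed,
                n_trees=cfg.signature_trees,
            )
            metrics = {
                "mean_accuracy": float(np.mean([m.accuracy for m in models])),
                "mean_kappa": float(np.mean([m.kappa for m in models])),
                "n_models": len(models),
                "signature_sizes": {c: len(sig.genes(c)) for c in sig.signatures},
            }
            manifest["stages"]["signatures"] = metrics
            emit("signature_models.json", lambda p: tio.write_json(metrics, p))
            emit(
                "signatures.tsv",
                lambda p: sig.to_frame().to_csv(p, sep="\t", index=False),
            )
    except Exception as exc:
        manifest["stages"]["failed"] = str(exc)
        manifest["status"] = "failed"
        tio.write_json(manifest, outdir / "manifest.json")
        root.removeHandler(handler)
        raise
    manifest["status"] = "ok"
    tio.write_json(manifest, outdir / "manifest.json")
    manifest["artifacts"].append({"path": "manifest.json"})
    root.removeHandler(handler)
    handler.close()
    return manifest
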