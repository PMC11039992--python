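"""End-to-end orchestration: validate a run config, execute the stages in
dependency order, and write a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as msio
from .binding import fit_one_site
from .coevolution import evaluate_recovery, rank_coevolution
from .errors import ConfigError
from .splicing import classify_events, enrichment_test, filter_significant_events
from .splicing.events import EVENT_TYPES
from .synthetic_data import (
    BindingConfig,
    LossModel,
    SignificanceModel,
    SyntheticEventConfig,
    simulate_as_events,
    simulate_emsa,
    simulate_gene_loss,
    simulate_gene_models,
    simulate_tree,
)

__all__ = ["RunConfig", "RunManifest", "run_workflow"]

ARTIFACT_VERSION = "0.1.0"

# Recognized config keys, per section.  Unknown keys are rejected.
_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "log_level", "stages", "profiles", "events", "emsa"},
    "profiles": {"n_species", "n_background", "loss_rate", "module_size", "rho",
                 "query", "top_k"},
    "events": {"n_genes", "frac_u12_genes", "n_events", "aa_enrichment_fold",
               "event_type_weights", "pr_min", "dpsi_min", "event_type"},
    "emsa": {"kd_true", "bmax_true", "noise_sd", "n_replicates", "concentrations"},
}
_STOCHASTIC_STAGES = {"profiles", "events", "emsa"}
_DEFAULT_STAGES = ("profiles", "events", "emsa")


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int | None
    out_dir: Path
    stages: tuple[str, ...]
    profiles: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    emsa: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict, out_dir: str | Path | None = None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _SCHEMA[""]
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section in ("profiles", "events", "emsa"):
            sub = raw.get(section, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            bad = set(sub) - _SCHEMA[section]
            if bad:
                raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
        stages = tuple(raw.get("stages", _DEFAULT_STAGES))
        for stage in stages:
            if stage not in _DEFAULT_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        seed = raw.get("seed")
        if seed is None and set(stages) & _STOCHASTIC_STAGES:
            raise ConfigError("seed is required for stochastic stages")
        if seed is not None and not isinstance(seed, int):
            raise ConfigError("seed must be an integer")
        out = Path(out_dir if out_dir is not None else raw.get("out_dir", "."))
        return cls(
            seed=seed,
            out_dir=out,
            stages=stages,
            profiles=dict(raw.get("profiles", {})),
            events=dict(raw.get("events", {})),
            emsa=dict(raw.get("emsa", {})),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {}, out_dir=out_dir)

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "profiles": self.profiles,
            "events": self.events,
            "emsa": self.emsa,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """What a run produced: outputs, checksums, runtimes."""

    artifact_version: str
    config_hash: str
    stages: dict = field(default_factory=dict)

    def write(self, path) -> None:
        # Atomic: write to a temp file then rename.
        payload = {
            "artifact_version": self.artifact_version,
            "config_hash": self.config_hash,
            "stages": self.stages,
        }
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_record(outputs: list[Path], t0: float) -> dict:
    return {
        "outputs": {p.name: _sha256(p) for p in outputs},
        "runtime_s": round(time.monotonic() - t0, 4),
        "status": "complete",
    }


def run_workflow(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write ``manifest.json``.

    Identical config + seed produce byte-identical primary outputs.  A
    stage failure leaves earlier stages' records in the manifest with the
    failing stage marked, then re-raises.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(artifact_version=ARTIFACT_VERSION, config_hash=config.config_hash())

    try:
        if "profiles" in config.stages:
            t0 = time.monotonic()
            p = config.profiles
            tree = simulate_tree(int(p.get("n_species", 60)), seed=config.seed)
            module_size = int(p.get("module_size", 8))
            model = LossModel(
                lam=float(p.get("loss_rate", 1.0)),
                module_members=tuple(f"mod{i + 1:03d}" for i in range(module_size)),
                rho=float(p.get("rho", 0.8)),
            )
            matrix = simulate_gene_loss(
                tree, int(p.get("n_background", 500)), model, seed=config.seed
            )
            tree_path = out / "species_tree.nwk"
            msio.write_newick(tree, tree_path)
            matrix_path = out / "presence_absence.tsv"
            matrix.to_tsv(matrix_path)

            query = str(p.get("query", model.module_members[0]))
            ranking = rank_coevolution(query, matrix)
            ranking_path = out / "coevolution_ranking.tsv"
            ranking.to_frame().to_csv(ranking_path, sep="\t", index=False)
            reference = [m for m in model.module_members if m != query]
            report = evaluate_recovery(ranking, reference, k=int(p.get("top_k", 20)))
            report_path = out / "recovery_report.json"
            report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
            manifest.stages["profiles"] = _stage_record(
                [tree_path, matrix_path, ranking_path, report_path], t0
            )

        if "events" in config.stages:
            t0 = time.monotonic()
            e = config.events
            n_genes = int(e.get("n_genes", 400))
            frac = float(e.get("frac_u12_genes", 0.25))
            genes, u12 = simulate_gene_models(n_genes, frac, seed=config.seed)
            cfg = SyntheticEventConfig(
                n_genes=n_genes,
                frac_u12_genes=frac,
                n_events=int(e.get("n_events", 2000)),
                aa_enrichment_fold=float(e.get("aa_enrichment_fold", 3.0)),
                significance=SignificanceModel(),
                seed=config.seed,
            )
            events = simulate_as_events(cfg, u12, genes)
            genes_path = out / "gene_models.bed12"
            msio.write_bed12(genes.values(), genes_path)
            u12_path = out / "u12_introns.bed"
            msio.write_bed6(u12, u12_path)
            events_path = out / "as_events.tsv"
            msio.write_events_tsv(events, events_path)

            kept = filter_significant_events(
                events, float(e.get("pr_min", 0.9)), float(e.get("dpsi_min", 0.05))
            )
            classified, skipped = classify_events(kept, u12, genes)
            classified_path = out / "classified_events.tsv"
            msio.write_events_tsv(
                [ev for ev, _ in classified], classified_path,
                extra={"event_class": [cls.value for _, cls in classified]},
            )
            enrichment = {
                etype: enrichment_test(classified, etype).to_dict()
                for etype in EVENT_TYPES
            }
            enrichment["n_skipped"] = len(skipped)
            enrich_path = out / "enrichment.json"
            enrich_path.write_text(json.dumps(enrichment, indent=2, sort_keys=True) + "\n")
            manifest.stages["events"] = _stage_record(
                [genes_path, u12_path, events_path, classified_path, enrich_path], t0
            )

        if "emsa" in config.stages:
            t0 = time.monotonic()
            b = config.emsa
            cfg = BindingConfig(
                kd_true=float(b.get("kd_true", 2.0)),
                bmax_true=float(b.get("bmax_true", 1.0)),
                noise_sd=float(b.get("noise_sd", 0.02)),
                n_replicates=int(b.get("n_replicates", 3)),
                seed=config.seed,
            )
            data = simulate_emsa(cfg)
            data_path = out / "binding_data.tsv"
            msio.write_binding_tsv(data, data_path)
            estimate = fit_one_site(data)
            fit_path = out / "kd_estimate.json"
            fit_path.write_text(json.dumps(estimate.to_dict(), indent=2, sort_keys=True) + "\n")
            manifest.stages["emsa"] = _stage_record([data_path, fit_path], t0)
    except Exception:
        manifest.stages["_failed"] = {"status": "failed"}
        manifest.write(out / "manifest.json")
        raise

    manifest.write(out / "manifest.json")
    return manifest
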