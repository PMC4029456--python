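"""End-to-end orchestration from one configuration object.

``run_pipeline`` composes the stages — load or simulate the inputs,
sample negatives, extract features for each requested feature set,
cross-validate each requested classifier, and optionally run the
importance procedure — and writes feature tables plus a machine- and
human-readable report.  One global seed is fanned out to the stages
through a seed sequence so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import CVSpec, cross_validate
from .features import TrapParams, build_feature_matrix
from .importance import ImportanceSpec, repeated_importance
from .io import (
    Genome,
    GenomicRegion,
    LabeledFeatureMatrix,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_jaspar_pfm,
    write_feature_table,
)
from .model import ModelSpec
from .sampling import SamplerSpec, fit_length_distribution, sample_negatives
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "assemble_training_set"]

log = logging.getLogger("enhancerclass")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    genome_path: str | None = None
    positives_path: str | None = None
    track_paths: tuple[str, ...] = ()
    pfm_path: str | None = None
    feature_sets: tuple[str, ...] = ("EPI", "MOT", "ALL")
    model_kinds: tuple[str, ...] = ("rf", "svm", "bde")
    cv_k: int = 10
    run_importance: bool = False
    importance_repetitions: int = 30
    window_width: int = 50
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        real = self.genome_path is not None and self.positives_path is not None
        if self.synthetic is None and not real:
            raise ValueError("config needs either synthetic settings or input paths")


def assemble_training_set(
    dataset: SyntheticDataset, seed: int
) -> list[GenomicRegion]:
    """Positives plus an equal number of length-matched sampled negatives."""
    mean, sd = fit_length_distribution(dataset.positives)
    spec = SamplerSpec(
        n=len(dataset.positives),
        length_mean=mean,
        length_sd=sd,
        exclusions={
            "positives": dataset.positives,
            **({"repeats": dataset.repeat_tracts} if dataset.repeat_tracts else {}),
        },
    )
    rng = np.random.default_rng(seed)
    negatives = sample_negatives(dataset.genome.sizes(), spec, rng, genome=dataset.genome)
    return list(dataset.positives) + negatives


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analysis; returns (and optionally writes) the report."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_of = {
        "simulate": int(seeds[0].generate_state(1)[0] % 2**31),
        "negatives": int(seeds[1].generate_state(1)[0] % 2**31),
        "cv": int(seeds[2].generate_state(1)[0] % 2**31),
        "importance": int(seeds[3].generate_state(1)[0] % 2**31),
    }

    @_stage("inputs")
    def load_inputs():
        if config.synthetic is not None:
            cfg = dataclasses.replace(config.synthetic, seed=seed_of["simulate"])
            return generate_dataset(cfg), None
        genome = read_fasta(config.genome_path)
        positives = read_bed(config.positives_path, label="positive")
        if not positives:
            raise ValueError("empty positive set")
        tracks = [read_bedgraph(p, config.window_width) for p in config.track_paths]
        pwms = read_jaspar_pfm(config.pfm_path) if config.pfm_path else []
        return None, (genome, positives, tracks, pwms)

    dataset, real = load_inputs()

    @_stage("sampler")
    def get_regions():
        if dataset is not None:
            return (
                dataset.genome,
                assemble_training_set(dataset, seed_of["negatives"]),
                dataset.tracks,
                dataset.pwms,
            )
        genome, positives, tracks, pwms = real
        mean, sd = fit_length_distribution(positives)
        spec = SamplerSpec(
            n=len(positives), length_mean=mean, length_sd=sd,
            exclusions={"positives": positives},
        )
        rng = np.random.default_rng(seed_of["negatives"])
        negatives = sample_negatives(genome.sizes(), spec, rng, genome=genome)
        return genome, list(positives) + negatives, tracks, pwms

    genome, regions, tracks, pwms = get_regions()

    @_stage("features")
    def extract() -> dict[str, LabeledFeatureMatrix]:
        base = build_feature_matrix(
            genome, tracks, pwms, regions, feature_set="ALL", params=TrapParams()
        )
        return {fs: base.select(fs) for fs in config.feature_sets}

    matrices = extract()

    @_stage("crossval")
    def evaluate() -> dict:
        grid = {}
        for fs, data in matrices.items():
            for kind in config.model_kinds:
                spec = ModelSpec(kind=kind, seed=seed_of["cv"])
                res = cross_validate(spec, data, CVSpec(k=config.cv_k, seed=seed_of["cv"]))
                grid[f"{fs}/{kind}"] = {
                    "auc_mean": res.auc_mean,
                    "auc_sd": res.auc_sd,
                    "error_mean": res.error_mean,
                    "error_sd": res.error_sd,
                    "k": config.cv_k,
                }
                log.info("crossval %s", res.summary())
        return grid

    grid = evaluate()

    report: dict = {
        "cv_grid": grid,
        "n_regions": len(regions),
        "feature_sets": {fs: m.feature_names for fs, m in matrices.items()},
        "manifest": {
            "version": __version__,
            "global_seed": config.seed,
            "stage_seeds": seed_of,
            "config": _config_json(config),
        },
    }

    if config.run_importance:

        @_stage("importance")
        def importance() -> dict:
            data = matrices.get("ALL") or next(iter(matrices.values()))
            rep = repeated_importance(
                data,
                ImportanceSpec(
                    n_repetitions=config.importance_repetitions,
                    seed=seed_of["importance"],
                ),
            )
            return {
                "feature_z": rep.feature_z,
                "decisions": rep.decisions,
                "expected_false_discoveries": rep.expected_false_discoveries,
            }

        report["importance"] = importance()

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fs, m in matrices.items():
            write_feature_table(m, outdir / f"features_{fs}.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "report.txt").write_text(_render_report(report))
    return report


def _config_json(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # output location is not part of the experiment
    return d


def _render_report(report: dict) -> str:
    lines = ["Cross-validated classification (AUC, mean over folds)", "-" * 56]
    kinds = sorted({key.split("/")[1] for key in report["cv_grid"]})
    sets_ = sorted({key.split("/")[0] for key in report["cv_grid"]})
    header = f"{'dataset':<10}" + "".join(f"{k:>10}" for k in kinds)
    lines.append(header)
    for fs in sets_:
        row = f"{fs:<10}"
        for kind in kinds:
            cell = report["cv_grid"].get(f"{fs}/{kind}")
            row += f"{cell['auc_mean']:>10.3f}" if cell else f"{'-':>10}"
        lines.append(row)
    if "importance" in report:
        lines.append("")
        lines.append(
            "expected false discoveries: "
            f"{report['importance']['expected_false_discoveries']:.3f}"
        )
    return "\n".join(lines) + "\n"
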