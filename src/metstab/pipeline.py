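"""Full-pipeline orchestration: ANOVA → AMMI/ASV → GGE views → GSI → LER.

One :class:`PipelineConfig` drives the whole analysis for every trait in a
trial CSV and writes a bundle of CSVs plus a plain-text summary.  Outputs
are deterministic: the same config and input produce byte-identical files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .ammi import ammi_decompose, asv
from .anova import combined_anova
from .gge import gge_views
from .ler import ler_from_trial, read_companion_csv
from .stability import gsi
from .core import TrialTable, cell_means, read_trial_csv, write_table_csv

log = logging.getLogger("metstab")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, serialisable to flat YAML."""

    input: str
    traits: list[str]
    out_dir: str
    schema: dict = field(default_factory=dict)
    svp: str = "symmetric"
    k: int | str = "max"
    impute: bool = False
    seed: int = 0
    companion: str | None = None
    sole_system: str = "sole"
    maize_only_ler: bool = True

    def validate(self) -> None:
        if not self.traits:
            raise ValueError("traits must be non-empty")
        if not Path(self.input).exists():
            raise FileNotFoundError(f"input file not found: {self.input}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage(name: str):
    """Log a stage and convert its failures into PipelineError."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis for every configured trait; return written paths.

    Per trait the bundle contains anova, ammi_scores, asv, gge_scores,
    gge_env_metrics, gge_genotype_metrics, gge_sectors, gsi and (when the
    trial has more than one cropping system) ler CSVs, plus summary.txt
    with the top-5 genotypes by mean rank, ASV rank and GSI rank.  The
    resolved config is written next to the outputs for provenance.  On any
    stage failure partial outputs are removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        with _stage("read"):
            table: TrialTable = read_trial_csv(config.input, schema=config.schema or None)
            for t in config.traits:
                if t not in table.traits:
                    raise KeyError(f"trait {t!r} not present in {config.input}")
            log.info("read %d plots, %d genotypes, %d environments",
                     len(table), table.n_genotypes, table.n_environments)

        companion = None
        if config.companion:
            with _stage("companion"):
                companion = read_companion_csv(config.companion)

        summary_lines: list[str] = []
        for trait in config.traits:
            with _stage(f"anova[{trait}]"):
                an = combined_anova(table, trait)
                path = out_dir / f"anova_{trait}.csv"
                write_table_csv(an.to_frame(), path)
                written[f"anova_{trait}"] = path

            with _stage(f"means[{trait}]"):
                means = cell_means(table, trait, impute_missing=config.impute)

            with _stage(f"ammi[{trait}]"):
                dec = ammi_decompose(means, k=config.k)
                path = out_dir / f"ammi_scores_{trait}.csv"
                write_table_csv(dec.scores_frame(), path)
                written[f"ammi_scores_{trait}"] = path
                asv_table = asv(dec)
                path = out_dir / f"asv_{trait}.csv"
                write_table_csv(asv_table.table.reset_index(), path)
                written[f"asv_{trait}"] = path

            with _stage(f"gge[{trait}]"):
                views = gge_views(means, svp=config.svp)
                for name, df in (
                    ("gge_scores", views.decomposition.scores_frame()),
                    ("gge_env_metrics", views.env_metrics.reset_index()),
                    ("gge_genotype_metrics", views.genotype_metrics.reset_index()),
                    ("gge_sectors", views.sectors),
                ):
                    path = out_dir / f"{name}_{trait}.csv"
                    write_table_csv(df, path)
                    written[f"{name}_{trait}"] = path

            with _stage(f"gsi[{trait}]"):
                gsi_table = gsi(means.genotype_means(), asv_table)
                path = out_dir / f"gsi_{trait}.csv"
                write_table_csv(gsi_table.reset_index(), path)
                written[f"gsi_{trait}"] = path

            if len(table.systems) > 1 and config.sole_system in table.systems:
                with _stage(f"ler[{trait}]"):
                    ler_table = ler_from_trial(
                        table,
                        trait,
                        sole_system=config.sole_system,
                        companion=companion,
                        maize_only=config.maize_only_ler and companion is None,
                    )
                    path = out_dir / f"ler_{trait}.csv"
                    write_table_csv(ler_table, path)
                    written[f"ler_{trait}"] = path

            def _top5(col, ascending=True):
                return ", ".join(
                    gsi_table.sort_values([col, "GSI"], ascending=ascending)
                    .head(5).index.tolist()
                )

            summary_lines += [
                f"[{trait}] top-5 by mean rank (rX): {_top5('rX')}",
                f"[{trait}] top-5 by stability rank (rASV): {_top5('rASV')}",
                f"[{trait}] top-5 by GSI rank (rGSI): {_top5('rGSI')}",
            ]

        with _stage("summary"):
            path = out_dir / "summary.txt"
            path.write_text("\n".join(summary_lines) + "\n")
            written["summary"] = path
            cfg_path = out_dir / "resolved_config.yml"
            config.to_yaml(cfg_path)
            written["config"] = cfg_path
    except PipelineError:
        # do not leave a half-written bundle behind
        for p in written.values():
            p.unlink(missing_ok=True)
        raise

    return written
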