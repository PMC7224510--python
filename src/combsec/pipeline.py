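"""End-to-end single-plate analysis: QC, normalization, combination analysis,
resampling validation, and artifact writing.

The stage order is fixed: quality control -> per-plate normalization (Q1/Q2/
Q3 ratios) -> GHSA scoring + two-level clustering -> leave-one-out
validation.  Every output is reproducible from (input plate, config, seed);
the run manifest records the package version, a config hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._plots import centroid_plot, ghsa_boxplot, partition_histogram, ratio_heatmap
from .clustering import annotate_with_need, canonical_partition
from .combination_design import exhaustive_panel, subset_search
from .errors import CombSecError, StageError
from .plate_io import (
    TISSUE_D,
    TISSUE_H,
    PlateTable,
    TreatmentCode,
    read_plate_csv,
    stimulation_label,
    summarize_layout,
    write_results,
)
from .quality_control import QCConfig, apply_qc, collapse_replicates
from .ratios import modulation_capacity, restoration_matrix, therapeutic_need
from .validation import (
    dominant_centroids,
    partition_frequencies,
    run_validation,
    summarize_ghsa,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run, loadable from a TOML file."""

    qc: QCConfig = field(default_factory=QCConfig)
    detection_filter: bool = True
    outlier_filter: bool = True
    n_v: int = 1000
    k1: int = 2
    k2: int = 2
    n_init: int = 50
    seed: int = 0
    subset_search: bool = False
    exhaustive_resampling: bool = False

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        qc = QCConfig(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    plate: PlateTable | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis on one plate; returns the artifact bundle.

    When ``outdir`` is given, tabular results, figures and a manifest are
    written there; on a stage failure the partial outputs are retained next
    to a ``FAILED`` marker naming the stage.
    """
    config = config or PipelineConfig()
    artifacts: dict[str, object] = {}
    try:
        with _stage("plate_io"):
            if not isinstance(plate, PlateTable):
                plate = read_plate_csv(plate)
            artifacts["layout"] = summarize_layout(plate)

        with _stage("quality_control"):
            qc_plate, report = apply_qc(
                plate,
                config.qc,
                detection=config.detection_filter,
                outliers=config.outlier_filter,
            )
            artifacts["qc_report"] = report.as_frame()
            collapsed = collapse_replicates(qc_plate)

        panel = exhaustive_panel(qc_plate.n_drugs)
        stimulations = sorted({s.stimulation for s in collapsed.profiles})
        to = TreatmentCode.untreated()

        for stim in stimulations:
            tag = stimulation_label(stim)
            with _stage(f"ratios[{tag}]"):
                need = therapeutic_need(collapsed, stim)
                artifacts[f"q1_{tag}"] = pd.DataFrame(
                    [need.values], index=["To"], columns=list(collapsed.proteins)
                ).rename_axis("treatment").reset_index()
                q2 = pd.DataFrame(
                    {
                        t.label: modulation_capacity(collapsed, t, stim).values
                        for t in panel
                    }
                ).T.set_axis(list(collapsed.proteins), axis=1)
                artifacts[f"q2_{tag}"] = q2.rename_axis("treatment").reset_index()
                q3 = restoration_matrix(collapsed, stim, panel)
                artifacts[f"q3_{tag}"] = q3.rename_axis("treatment").reset_index()
                artifacts[f"q3_heatmap_{tag}"] = ratio_heatmap(
                    q3, f"Restoration capacity (Q3), {tag}"
                )

            with _stage(f"validation[{tag}]"):
                runs = run_validation(
                    qc_plate,
                    stimulation=stim,
                    n_v=config.n_v,
                    seed=config.seed,
                    k1=config.k1,
                    k2=config.k2,
                    n_init=config.n_init,
                    exhaustive=config.exhaustive_resampling,
                    panel=panel,
                )
                summaries = summarize_ghsa(runs)
                artifacts[f"validation_ghsa_{tag}"] = pd.DataFrame(
                    [
                        {
                            "combination": s.combination.label,
                            "min": s.five_numbers[0],
                            "p25": s.five_numbers[1],
                            "p50": s.five_numbers[2],
                            "p75": s.five_numbers[3],
                            "max": s.five_numbers[4],
                        }
                        for s in summaries
                    ]
                )
                artifacts[f"ghsa_boxplot_{tag}"] = ghsa_boxplot(
                    summaries, f"GHSA sampling distributions, {tag}"
                )
                freq = partition_frequencies(runs)
                artifacts[f"validation_partitions_{tag}"] = freq
                artifacts[f"partition_histogram_{tag}"] = partition_histogram(
                    freq, f"Level-1 partition frequencies, {tag}"
                )

            with _stage(f"clustering[{tag}]"):
                tree = dominant_centroids(qc_plate, runs, stim, panel)
                rows = []
                for i, c in enumerate(
                    sorted(tree.clusters, key=lambda c: c.members), start=1
                ):
                    for t in c.members:
                        l2 = ""
                        if c.subclusters is not None:
                            for j, s in enumerate(
                                sorted(c.subclusters, key=lambda s: s.members), start=1
                            ):
                                if t in s.members:
                                    l2 = f"{i}.{j}"
                        rows.append(
                            {"treatment": t, "level1_id": i, "level2_id": l2}
                        )
                artifacts[f"clusters_{tag}"] = pd.DataFrame(rows)
                artifacts[f"centroids_{tag}"] = centroid_plot(
                    tree, need.values, f"Dominant-partition centroids, {tag}"
                )
                if config.subset_search:
                    srows = []
                    for i, c in enumerate(
                        sorted(tree.clusters, key=lambda c: c.members), start=1
                    ):
                        minimal = subset_search(
                            [TreatmentCode.parse(t) for t in c.members]
                        )
                        srows.append(
                            {
                                "level1_id": i,
                                "minimal_treatments": ",".join(
                                    t.label for t in minimal
                                ),
                            }
                        )
                    artifacts[f"subset_search_{tag}"] = pd.DataFrame(srows)

        ghsa_full = []
        with _stage("ghsa"):
            from .ghsa import ghsa_panel

            for stim in stimulations:
                for res in ghsa_panel(collapsed, stim, panel):
                    ghsa_full.append(
                        {
                            "stimulation": stimulation_label(stim),
                            "combination": res.combination.label,
                            "E_combination": res.effect_combination,
                            "min_subtreatment_E": res.min_subtreatment_effect,
                            "argmin": res.argmin_subtreatment.label,
                            "I_GHSA": res.index_value,
                        }
                    )
            artifacts["ghsa"] = pd.DataFrame(ghsa_full)

    except StageError as exc:
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text(f"{exc.stage}: {exc}\n")
            write_results(out, artifacts, _metadata(config, failed=exc.stage))
        raise

    if outdir is not None:
        manifest = write_results(Path(outdir), artifacts, _metadata(config))
        artifacts["manifest"] = manifest
    return artifacts


def _metadata(config: PipelineConfig, failed: str | None = None) -> dict:
    meta = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
    }
    if failed:
        meta["failed_stage"] = failed
    return meta
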