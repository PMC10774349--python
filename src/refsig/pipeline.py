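"""End-to-end orchestration: discovery phase then validation phase.

The discovery phase selects a signature by recursive ensemble feature
selection and scores it with the five held-out classifiers. For each
validation cohort the signature is transferred by exact subsequence
matching, the reduced (aggregated) table is scored with the same five
classifiers, and differential-abundance summaries are written. Every
artifact is listed in a manifest with its SHA-256 hash and the resolved
configuration, so any number in any emitted table can be regenerated from
the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import (
    AsvTable,
    SignatureRecord,
    SignatureTable,
    read_asv_table,
    write_signature_table,
)
from .diff_abundance import differential_abundance, export_heatmap
from .matching import match_signature
from .refs import RefsResult, run_refs
from .validation import ValidationReport, crossval_auc

logger = logging.getLogger(__name__)

__all__ = ["CohortPaths", "PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class CohortPaths:
    name: str
    counts: str
    fasta: str
    labels: str
    transpose: bool = False
    delimiter: str | None = None


@dataclass
class PipelineConfig:
    discovery: CohortPaths
    validation_cohorts: list[CohortPaths] = field(default_factory=list)
    out_dir: str = "refsig_out"
    seed: int = 0
    n_runs: int = 30
    n_folds: int = 10
    n_jobs: int = 1
    fold_safe_scaling: bool = False
    rc_match: bool = False
    heatmaps: bool = True


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            digest.update(block)
    return digest.hexdigest()


def _write_json(obj, path: Path, seed: int | None = None) -> None:
    if seed is not None and "seed" not in obj:
        obj = {"seed": seed, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _validation_report_dict(report: ValidationReport) -> dict:
    return {
        "per_classifier": {
            r.display_name: {
                "mean_auc": r.mean_auc,
                "sd": r.sd,
                "fold_aucs": r.fold_aucs,
            }
            for r in report.per_classifier.values()
        },
        "average_auc": report.ensemble_mean,
        "best_classifier": report.best_classifier.display_name,
        "n_folds": report.n_folds,
        "feature_ids": report.feature_ids,
    }


def _refs_result_dict(result: RefsResult) -> dict:
    return {
        "best_run": result.best_run,
        "best_cycle": result.best_cycle,
        "run_seeds": result.run_seeds,
        "selected_asv_ids": result.selected_asv_ids,
        "importance_rank": result.importance_rank,
        "best_cycle_score": result.best_record.mean_score,
        "best_cycle_auc": result.best_record.mean_auc,
    }


def _signature_from_selection(
    result: RefsResult, discovery: AsvTable, directions: dict[str, str]
) -> SignatureTable:
    records = []
    for rank, asv_id in enumerate(result.selected_asv_ids, start=1):
        records.append(
            SignatureRecord(
                index=rank,
                taxonomy={r: None for r in ("domain", "phylum", "class", "order", "family", "genus", "species")},
                direction=directions.get(asv_id, "ASD increased"),
                presence={},
                sequence=discovery.sequences[asv_id],
            )
        )
    return SignatureTable(records=records)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return the manifest (also written to disk).

    Stages: ``select`` (REFS on the discovery cohort), ``validate``
    (held-out five-classifier AUC on the discovery cohort), then per
    validation cohort ``match``, ``validate`` on the reduced table, and
    ``report`` (differential abundance + heat-map). Any stage failure
    aborts with the stage name; artifacts written so far are renamed with
    a ``.partial`` suffix.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    t0 = time.time()

    def emit(path: Path) -> Path:
        artifacts.append(path)
        return path

    def fail(stage: str, err: BaseException):
        for path in artifacts:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineError(stage, err) from err

    # ---- discovery phase -------------------------------------------------
    try:
        discovery = read_asv_table(
            cfg.discovery.counts,
            cfg.discovery.fasta,
            cfg.discovery.labels,
            transpose=cfg.discovery.transpose,
            delimiter=cfg.discovery.delimiter,
        )
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail("load", err)

    logger.info("select: %d samples x %d ASVs, %d runs", discovery.n_samples,
                discovery.n_asvs, cfg.n_runs)
    try:
        result = run_refs(
            discovery,
            n_runs=cfg.n_runs,
            n_folds=cfg.n_folds,
            seed=cfg.seed,
            n_jobs=cfg.n_jobs,
            fold_safe_scaling=cfg.fold_safe_scaling,
        )
        _write_json(_refs_result_dict(result), emit(out / "refs_result.json"), seed=cfg.seed)
        pd.DataFrame(
            result.score_curve(),
            columns=["run", "cycle", "n_features", "mean_score", "sd"],
        ).to_csv(emit(out / "cycle_scores.tsv"), sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        fail("select", err)

    try:
        summary = differential_abundance(discovery, result.selected_asv_ids)
        directions = {f.asv_id: f.direction for f in summary.features.values()}
        signature = _signature_from_selection(result, discovery, directions)
        signature_path = emit(out / "signature.tsv")
        write_signature_table(signature, signature_path)
        emit(out / "signature.fasta").write_text(
            "".join(
                f">{a}\n{discovery.sequences[a]}\n" for a in result.selected_asv_ids
            )
        )

        disc_report = crossval_auc(
            discovery,
            result.selected_asv_ids,
            n_folds=cfg.n_folds,
            seed=cfg.seed,
            fold_safe_scaling=cfg.fold_safe_scaling,
        )
        _write_json(_validation_report_dict(disc_report), emit(out / "discovery_validation.json"), seed=cfg.seed)
        pd.DataFrame(disc_report.as_rows()).to_csv(
            emit(out / "discovery_auc_table.tsv"), sep="\t", index=False
        )
        export_heatmap(
            summary,
            emit(out / "discovery_abundance.tsv"),
            emit(out / "discovery_heatmap.png") if cfg.heatmaps else None,
        )
        summary.as_frame().to_csv(
            emit(out / "discovery_directions.tsv"), sep="\t", index=False
        )
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        fail("validate", err)

    cohort_summaries = {}
    # ---- validation phase ------------------------------------------------
    for cohort in cfg.validation_cohorts:
        prefix = out / f"cohort_{cohort.name}"
        try:
            if not signature_path.exists():
                raise FileNotFoundError(f"signature table missing: {signature_path}")
            vtable = read_asv_table(
                cohort.counts,
                cohort.fasta,
                cohort.labels,
                transpose=cohort.transpose,
                delimiter=cohort.delimiter,
            )
            signature_seqs = {
                a: discovery.sequences[a] for a in result.selected_asv_ids
            }
            match = match_signature(signature_seqs, vtable, rc=cfg.rc_match)
            _write_json(
                {
                    "n_matched": match.n_matched,
                    "matches": match.matches,
                    "presence": match.presence(),
                    "shared_containments": match.shared_containments,
                },
                emit(Path(f"{prefix}_match.json")),
                seed=cfg.seed,
            )
            pd.DataFrame(
                sorted(match.presence().items()), columns=["asv_id", "present"]
            ).to_csv(emit(Path(f"{prefix}_presence.tsv")), sep="\t", index=False)
        except Exception as err:  # noqa: BLE001
            fail("match", err)

        try:
            if match.reduced_table is None:
                raise ValueError(
                    f"no signature ASV matched in cohort {cohort.name!r}"
                )
            match.reduced_table.counts_frame().to_csv(
                emit(Path(f"{prefix}_reduced_counts.tsv")),
                sep="\t",
                index_label="sample_id",
            )
            vreport = crossval_auc(
                match.reduced_table,
                match.reduced_table.asv_ids,
                n_folds=cfg.n_folds,
                seed=cfg.seed,
                fold_safe_scaling=cfg.fold_safe_scaling,
            )
            _write_json(
                _validation_report_dict(vreport),
                emit(Path(f"{prefix}_validation.json")),
                seed=cfg.seed,
            )
            pd.DataFrame(vreport.as_rows()).to_csv(
                emit(Path(f"{prefix}_auc_table.tsv")), sep="\t", index=False
            )
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            fail("validate", err)

        try:
            vsummary = differential_abundance(
                match.reduced_table, match.reduced_table.asv_ids
            )
            export_heatmap(
                vsummary,
                emit(Path(f"{prefix}_abundance.tsv")),
                emit(Path(f"{prefix}_heatmap.png")) if cfg.heatmaps else None,
            )
            vsummary.as_frame().to_csv(
                emit(Path(f"{prefix}_directions.tsv")), sep="\t", index=False
            )
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001
            fail("report", err)

        cohort_summaries[cohort.name] = {
            "n_matched": match.n_matched,
            "average_auc": vreport.ensemble_mean,
        }

    manifest = {
        "refsig_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "selected_n_features": len(result.selected_asv_ids),
        "discovery_average_auc": disc_report.ensemble_mean,
        "validation_cohorts": cohort_summaries,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()
        },
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
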