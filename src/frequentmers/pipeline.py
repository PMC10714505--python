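"""End-to-end pipeline: extract -> fold -> derive -> features -> classify.

One JSON-serialisable RunConfig drives every stage.  Each stage writes
its outputs under ``<out_dir>/<stage>/`` together with a ``.done.json``
marker stamped with the config hash, so an interrupted run resumes at
the first stage whose marker is missing or whose hash no longer
matches (stale outputs from a different config are never mixed in).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import classify as cls
from . import core
from .io_manifest import (
    SampleManifest,
    load_manifest,
    read_kmerset,
    read_sample,
    write_kmerset,
)
from .kmer import KmerCodec, extract_kmerset

log = logging.getLogger("frequentmers")


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    k: int = 16
    min_count: int = 2
    r: int = 15
    n_folds: int = 10
    model: str = "logistic"          # logistic | boosted | both
    seed: int = 0
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("logistic", "boosted", "both"):
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.k < 1 or self.min_count < 1 or self.r < 1 or self.n_folds < 2:
            raise ValueError("invalid RunConfig parameter")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / ".done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, cfg_hash: str, **info) -> None:
    (stage_dir / ".done.json").write_text(
        json.dumps({"config_hash": cfg_hash, **info}, indent=1)
    )


def _stage_extract(config: RunConfig, manifests: list[SampleManifest], stage: Path) -> None:
    codec = KmerCodec(config.k)
    sidecar = {}
    for m in manifests:
        sr = read_sample(m)
        kset = extract_kmerset(
            sr, codec, min_count=config.min_count, canonical=config.canonical
        )
        write_kmerset(kset, stage / f"{m.sample_id}.kset")
        n_windows = sum(max(len(r) - config.k + 1, 0) for r in sr.reads)
        sidecar[m.sample_id] = {
            "n_reads": len(sr.reads),
            "n_windows": n_windows,
            "n_kmers": len(kset),
        }
        log.info("extract %s: %d reads, %d retained k-mers", m.sample_id,
                 len(sr.reads), len(kset))
    (stage / "counts.json").write_text(json.dumps(sidecar, indent=1))


def _load_ksets(stage: Path, sample_ids: list[str]):
    return {sid: read_kmerset(stage / f"{sid}.kset") for sid in sample_ids}


def run_pipeline(config: RunConfig) -> Path:
    """Execute (or resume) every stage; returns the run directory whose
    ``summary.json`` holds the per-fold and pooled classification
    metrics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config.json").write_text(
        json.dumps({**asdict(config), "config_hash": cfg_hash}, indent=1)
    )
    manifests = load_manifest(config.manifest)
    ids = [m.sample_id for m in manifests]

    extract_dir = out / "extract"
    extract_dir.mkdir(exist_ok=True)
    if _stage_done(extract_dir, cfg_hash):
        log.info("extract: up to date, skipping")
    else:
        _stage_extract(config, manifests, extract_dir)
        _mark_done(extract_dir, cfg_hash, n_samples=len(manifests))

    folds_dir = out / "folds"
    folds_dir.mkdir(exist_ok=True)
    if _stage_done(folds_dir, cfg_hash):
        assignment = json.loads((folds_dir / "folds.json").read_text())
        folds = cls.FoldAssignment(config.n_folds, config.seed, assignment)
    else:
        folds = cls.make_folds(manifests, config.n_folds, config.seed)
        (folds_dir / "folds.json").write_text(json.dumps(folds.assignment, indent=1))
        _mark_done(folds_dir, cfg_hash)

    derive_dir = out / "derive"
    derive_dir.mkdir(exist_ok=True)
    ksets = _load_ksets(extract_dir, ids)
    catalogs: dict[int, core.FrequentmerCatalog] = {}
    if _stage_done(derive_dir, cfg_hash):
        from .kmer import KmerSet

        for f in range(config.n_folds):
            c = read_kmerset(derive_dir / f"fold{f}.control.kset")
            p = read_kmerset(derive_dir / f"fold{f}.patient.kset")
            catalogs[f] = core.FrequentmerCatalog(f, config.r, config.k, c.kmers, p.kmers)
        log.info("derive: up to date, skipping")
    else:
        from .kmer import KmerSet

        for f in range(config.n_folds):
            train = [ksets[s] for s in folds.train_ids(f)]
            index = core.build_index(train, manifests, fold_id=f)
            cat = core.derive_frequentmers(index, config.r)
            catalogs[f] = cat
            write_kmerset(
                KmerSet(f"fold{f}.control", config.k, cat.control_fms),
                derive_dir / f"fold{f}.control.kset",
            )
            write_kmerset(
                KmerSet(f"fold{f}.patient", config.k, cat.patient_fms),
                derive_dir / f"fold{f}.patient.kset",
            )
            log.info("derive fold %d: %d control + %d patient frequentmers",
                     f, len(cat.control_fms), len(cat.patient_fms))
        _mark_done(derive_dir, cfg_hash)

    classify_dir = out / "classify"
    classify_dir.mkdir(exist_ok=True)
    if not _stage_done(classify_dir, cfg_hash):
        model_kinds = ["logistic", "boosted"] if config.model == "both" else [config.model]
        summary: dict = {"config_hash": cfg_hash, "models": {}}
        for kind in model_kinds:
            results = []
            fold_rows = []
            for f in range(config.n_folds):
                cat = catalogs[f]
                train_fm = cls.build_features(cat, ksets, manifests, folds.train_ids(f))
                test_fm = cls.build_features(cat, ksets, manifests, folds.test_ids(f))
                if kind == "logistic":
                    res = cls.fit_logistic(train_fm, test_fm)
                else:
                    res = cls.fit_boosted(train_fm, test_fm, seed=config.seed)
                results.append(res)
                rec = core.test_recovery(
                    cat, [ksets[s] for s in folds.test_ids(f)], manifests
                )
                fold_rows.append(
                    {
                        "fold": f,
                        "n_features": cat.n_total,
                        "auc": res.auc,
                        "recovery_fraction": rec.recovery_fraction,
                    }
                )
                if res.coefficients is not None:
                    ranked = cls.coefficient_report(res, train_fm)
                    np.savetxt(
                        classify_dir / f"fold{f}.coefficients.tsv",
                        np.column_stack(
                            [ranked.kmers.astype(np.int64), ranked.coefficients]
                        ),
                        fmt=("%d", "%.8g"),
                        delimiter="\t",
                        header="kmer\tcoefficient",
                        comments="",
                    )
            rep = cls.evaluate(results)
            summary["models"][kind] = {
                "pooled_auc": rep.pooled_auc,
                "mean_auc": rep.mean_auc,
                "auc_ci95": list(rep.auc_ci95),
                "fold_aucs": rep.fold_aucs,
                "confusion_pct": rep.confusion_pct,
                "folds": fold_rows,
            }
        (classify_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        _mark_done(classify_dir, cfg_hash)
    else:
        log.info("classify: up to date, skipping")

    return out
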