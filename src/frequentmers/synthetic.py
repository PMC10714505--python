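"""Two-cohort synthetic metagenome generator with planted markers.

The simulator emulates the statistical structure the frequentmer method
relies on: both cohorts draw reads from a shared background sequence
pool (the common microbiome), while cohort-specific marker sequences
are planted into a controlled subset of one cohort's samples.  Marker
prevalence, per-base substitution error, and the number of reads drawn
per included marker are all parameters, so every downstream stage —
singleton filter, recurrency/absence rule, classifiers, traceback —
has exact ground truth.

Markers are rejection-sampled to be k-mer-disjoint from the background
and from each other, so each marker k-mer's cohort support equals the
marker's inclusion pattern (up to error).  The error model is
substitution-only; indels are out of scope.

Everything is reproducible from the spec seed, including the emitted
FASTQ bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CohortIndex, FrequentmerCatalog
from .io_manifest import Cohort, SampleManifest, SampleReads, write_manifest
from .kmer import sequence_codes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

EXPOSURE_COVARIATE = "exposure"


@dataclass
class SyntheticCohortSpec:
    """Parameters of the planted-marker simulation.

    Defaults describe a small but realistic screen: 30 samples per
    cohort, a shared 50 kb background sampled at ~4x per sample, ten
    patient markers and five control markers of 100 bp carried by half
    of their cohort, 0.5% per-base substitution error, and three reads
    per included marker so its k-mers survive the singleton filter.
    """

    n_patients: int = 30
    n_controls: int = 30
    n_background_refs: int = 5
    background_len: int = 10_000
    n_patient_markers: int = 10
    n_control_markers: int = 5
    marker_len: int = 100
    prevalence: float = 0.5
    reads_per_sample: int = 2_000
    read_len: int = 100
    error_rate: float = 0.005
    coverage_per_included_marker: int = 3
    exposure_fraction: float = 0.0
    n_exposure_markers: int = 0
    k: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "error_rate", "exposure_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.marker_len < self.k:
            raise ValueError("marker_len must be >= k")
        if self.read_len < self.marker_len:
            raise ValueError(
                "read_len must be >= marker_len so each marker read covers "
                "the full marker"
            )
        if self.coverage_per_included_marker < 1:
            raise ValueError("coverage_per_included_marker must be >= 1")


@dataclass
class GroundTruth:
    """Planted-marker truth: marker sequences with cohort/exposure
    labels, the per-sample inclusion matrix (pre-error), and each
    marker's k-mer codes."""

    markers: pd.DataFrame            # name, kind (patient/control/exposure), sequence
    inclusion: pd.DataFrame          # markers x samples, bool
    marker_kmers: dict[str, np.ndarray]
    exposure_positive: list[str]     # exposure-positive patient sample ids
    k: int

    def kmers_of_kind(self, kinds: Sequence[str]) -> np.ndarray:
        names = self.markers.loc[self.markers["kind"].isin(kinds), "name"]
        if len(names) == 0:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate([self.marker_kmers[n] for n in names]))

    def all_marker_kmers(self) -> np.ndarray:
        return self.kmers_of_kind(["patient", "control", "exposure"])

    def expected_sample_kmers(self, sample_id: str) -> np.ndarray:
        """Marker k-mers a sample carries pre-error, per the inclusion
        matrix."""
        inc = self.inclusion[sample_id]
        names = inc.index[inc]
        if len(names) == 0:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate([self.marker_kmers[n] for n in names]))


def _random_seq_arr(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _sample_markers(
    rng: np.random.Generator,
    kinds: list[str],
    spec: SyntheticCohortSpec,
    forbidden: set[int],
    max_attempts: int = 200,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Rejection-sample marker sequences whose k-mer sets are disjoint
    from ``forbidden`` (background plus previously accepted markers)."""
    rows, kmers = [], {}
    for i, kind in enumerate(kinds):
        name = f"{kind}_marker_{i:03d}"
        for attempt in range(max_attempts):
            arr = _random_seq_arr(rng, spec.marker_len)
            codes = np.unique(sequence_codes(_arr_to_str(arr), spec.k))
            if len(codes) == spec.marker_len - spec.k + 1 and not any(
                int(c) in forbidden for c in codes
            ):
                break
        else:
            raise RuntimeError(
                f"could not sample a k-mer-disjoint marker after {max_attempts} "
                "attempts; use a longer background or fewer/shorter markers"
            )
        forbidden.update(int(c) for c in codes)
        rows.append({"name": name, "kind": kind, "sequence": _arr_to_str(arr)})
        kmers[name] = codes
    return pd.DataFrame(rows, columns=["name", "kind", "sequence"]), kmers


def _apply_errors(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """I.i.d. substitution errors: each base flips to one of the other
    three with probability ``rate``."""
    if rate <= 0:
        return arr
    hit = rng.random(arr.shape) < rate
    n = int(hit.sum())
    if n == 0:
        return arr
    out = arr.copy()
    # offset 1..3 in base space guarantees a *different* base
    base_idx = np.searchsorted(_BASES, out[hit])
    out[hit] = _BASES[(base_idx + rng.integers(1, 4, size=n)) % 4]
    return out


def generate_samples(
    spec: SyntheticCohortSpec,
    inclusion_override: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[SampleManifest], list[SampleReads], GroundTruth]:
    """Generate both cohorts in memory.

    ``inclusion_override`` maps a marker name to the exact list of
    sample ids that carry it, bypassing the Bernoulli(prevalence) draw
    for that marker so tests can force exact recurrency counts.

    Returned manifests carry empty read_path lists; use
    :func:`generate` to also write FASTQ files and a loadable manifest.
    """
    rng = np.random.default_rng(spec.seed)
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    controls = [f"C{i:03d}" for i in range(spec.n_controls)]
    samples = patients + controls

    refs = [_random_seq_arr(rng, spec.background_len) for _ in range(spec.n_background_refs)]
    forbidden: set[int] = set()
    for ref in refs:
        forbidden.update(int(c) for c in sequence_codes(_arr_to_str(ref), spec.k))
        # refs are sampled circularly below; the wrap-around junction
        # k-mers belong to the background universe too
        junction = np.concatenate([ref[-(spec.k - 1):], ref[: spec.k - 1]])
        forbidden.update(int(c) for c in sequence_codes(_arr_to_str(junction), spec.k))

    kinds = (
        ["patient"] * spec.n_patient_markers
        + ["control"] * spec.n_control_markers
        + ["exposure"] * spec.n_exposure_markers
    )
    markers, marker_kmers = _sample_markers(rng, kinds, spec, forbidden)

    n_pos = int(round(spec.exposure_fraction * spec.n_patients))
    exposure_positive = sorted(
        np.array(patients)[rng.permutation(spec.n_patients)[:n_pos]].tolist()
    )

    eligible = {
        "patient": set(patients),
        "control": set(controls),
        "exposure": set(exposure_positive),
    }
    inclusion = pd.DataFrame(
        False, index=list(markers["name"]), columns=samples, dtype=bool
    )
    override = dict(inclusion_override or {})
    for name, kind in zip(markers["name"], markers["kind"]):
        if name in override:
            for sid in override[name]:
                inclusion.loc[name, sid] = True
            continue
        for sid in samples:
            if sid in eligible[kind] and rng.random() < spec.prevalence:
                inclusion.loc[name, sid] = True
    unknown = set(override) - set(markers["name"])
    if unknown:
        raise KeyError(f"inclusion_override names unknown markers: {sorted(unknown)}")

    marker_arr = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for name, seq in zip(markers["name"], markers["sequence"])
    }

    manifests, all_reads = [], []
    for sid in samples:
        cohort = Cohort.patient if sid.startswith("P") else Cohort.control
        n_bg = spec.reads_per_sample
        ref_idx = rng.integers(0, spec.n_background_refs, size=n_bg)
        # background refs are circular (bacterial chromosomes): wrap-around
        # sampling gives uniform per-position coverage with no edge dropout
        starts = rng.integers(0, spec.background_len, size=n_bg)
        read_arrays = []
        for ri, s in zip(ref_idx, starts):
            end = s + spec.read_len
            if end <= spec.background_len:
                read_arrays.append(refs[ri][s:end])
            else:
                read_arrays.append(
                    np.concatenate([refs[ri][s:], refs[ri][: end - spec.background_len]])
                )
        for name in inclusion.index[inclusion[sid]]:
            for _ in range(spec.coverage_per_included_marker):
                read_arrays.append(marker_arr[name])
        lengths = [len(a) for a in read_arrays]
        flat = _apply_errors(rng, np.concatenate(read_arrays), spec.error_rate)
        reads, offset = [], 0
        for ln in lengths:
            reads.append(flat[offset : offset + ln].tobytes().decode("ascii"))
            offset += ln
        exposures = {}
        if cohort == Cohort.patient and spec.exposure_fraction > 0:
            exposures[EXPOSURE_COVARIATE] = sid in exposure_positive
        manifests.append(SampleManifest(sid, [], cohort, exposures))
        all_reads.append(SampleReads(sid, reads))

    truth = GroundTruth(markers, inclusion, marker_kmers, exposure_positive, spec.k)
    return manifests, all_reads, truth


def generate(
    spec: SyntheticCohortSpec,
    out_dir: str | Path,
    inclusion_override: Mapping[str, Sequence[str]] | None = None,
    gzip_fastq: bool = True,
) -> tuple[list[SampleManifest], GroundTruth]:
    """Generate both cohorts and write FASTQ files, a manifest CSV
    (``manifest.csv``) and a truth JSON to ``out_dir``."""
    import gzip as _gzip
    import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests, all_reads, truth = generate_samples(spec, inclusion_override)
    for m, sr in zip(manifests, all_reads):
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        path = out_dir / f"{m.sample_id}{suffix}"
        if gzip_fastq:
            # fixed mtime so reruns are byte-identical
            opener = lambda p: _io.TextIOWrapper(
                _gzip.GzipFile(p, mode="wb", mtime=0)
            )
        else:
            opener = lambda p: open(p, "w")
        with opener(path) as fh:
            for i, read in enumerate(sr.reads):
                fh.write(f"@{m.sample_id}.{i}\n{read}\n+\n{'I' * len(read)}\n")
        m.read_paths = [path.resolve()]
    write_manifest(manifests, out_dir / "manifest.csv", relative_to=out_dir)
    truth_payload = {
        "markers": truth.markers.to_dict(orient="records"),
        "inclusion": {
            name: truth.inclusion.columns[truth.inclusion.loc[name]].tolist()
            for name in truth.inclusion.index
        },
        "exposure_positive": truth.exposure_positive,
        "k": truth.k,
        "spec": asdict(spec),
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    return manifests, truth


@dataclass
class RecoveryScore:
    recall_patient: float       # recovered / marker k-mers meeting the rule, patient side
    recall_control: float
    precision_patient: float    # marker-derived fraction of the patient catalog
    precision_control: float
    n_eligible_patient: int
    n_eligible_control: int


def score_recovery(
    catalog: FrequentmerCatalog, truth: GroundTruth, index: CohortIndex
) -> RecoveryScore:
    """Precision/recall of planted-marker k-mer recovery.

    Recall denominators are the marker k-mers that actually meet the
    (>= r own-cohort samples, 0 other-cohort samples) condition in the
    post-error index; precision is the marker-derived fraction of each
    catalog side.
    """
    r = catalog.r

    def _eligible(kinds, own_counts, other_counts):
        marker_k = truth.kmers_of_kind(kinds)
        if len(marker_k) == 0 or len(index.kmers) == 0:
            return np.empty(0, dtype=np.uint64)
        pos = np.searchsorted(index.kmers, marker_k)
        pos = np.clip(pos, 0, len(index.kmers) - 1)
        in_index = index.kmers[pos] == marker_k
        ok = np.zeros(len(marker_k), dtype=bool)
        ok[in_index] = (own_counts[pos[in_index]] >= r) & (other_counts[pos[in_index]] == 0)
        return marker_k[ok]

    elig_p = _eligible(["patient", "exposure"], index.n_patient, index.n_control)
    elig_c = _eligible(["control"], index.n_control, index.n_patient)

    def _recall(eligible, fms):
        if len(eligible) == 0:
            return float("nan")
        return float(np.isin(eligible, fms).mean())

    all_marker = truth.all_marker_kmers()

    def _precision(fms):
        if len(fms) == 0:
            return float("nan")
        return float(np.isin(fms, all_marker).mean())

    return RecoveryScore(
        recall_patient=_recall(elig_p, catalog.patient_fms),
        recall_control=_recall(elig_c, catalog.control_fms),
        precision_patient=_precision(catalog.patient_fms),
        precision_control=_precision(catalog.control_fms),
        n_eligible_patient=len(elig_p),
        n_eligible_control=len(elig_c),
    )
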