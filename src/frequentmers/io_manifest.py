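"""Sample manifests, read loading, and the ``.kset`` on-disk format.

The manifest is a CSV/TSV table with header columns ``sample_id``,
``cohort`` and ``read_paths`` (semicolon-separated file list); any
further column is treated as a binary exposure covariate (1/0,
true/false, or NA for unknown).

Reads may be FASTA or FASTQ, plain or gzip-compressed, with the format
auto-detected per file.  All runs of a sample are concatenated into one
single-end read list; base qualities are discarded — the downstream
method is presence/absence and its only error control is the
within-sample singleton filter.

``.kset`` files store one sample's retained k-mer set as a small header
followed by the sorted codes at a fixed width of ceil(2k/8) bytes each,
little-endian.  Sorted fixed-width storage lets the cohort index be
built by a streaming multiway merge without decoding.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .kmer import KmerSet

_KSET_MAGIC = b"FQMK"
_KSET_VERSION = 1

_VALID = set("ACGTN")
_NORM = str.maketrans(
    {chr(c): "N" for c in range(128) if chr(c).upper() not in "ACGTN"}
)


class Cohort(str, Enum):
    patient = "patient"
    control = "control"


@dataclass
class SampleManifest:
    sample_id: str
    read_paths: list[Path]
    cohort: Cohort
    exposures: dict[str, bool] = field(default_factory=dict)


@dataclass
class SampleReads:
    sample_id: str
    reads: list[str]

    def __len__(self) -> int:
        return len(self.reads)


_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}
_NA = {"", "na", "nan", "none", "unknown", "?"}

_RESERVED_COLS = {"sample_id", "cohort", "read_paths"}


def _parse_exposure(value) -> bool | None:
    s = str(value).strip().lower()
    if s in _NA:
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse exposure value {value!r} as boolean/NA")


def load_manifest(path: str | Path) -> list[SampleManifest]:
    """Parse a manifest table into one SampleManifest per row.

    Hard errors: duplicate sample ids, unknown cohort values, and read
    paths that do not exist at load time.  Relative read paths resolve
    against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = _RESERVED_COLS - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in manifest: {dups}")
    exposure_cols = [c for c in df.columns if c not in _RESERVED_COLS]
    out: list[SampleManifest] = []
    for _, row in df.iterrows():
        raw_cohort = row["cohort"].strip().lower()
        try:
            cohort = Cohort(raw_cohort)
        except ValueError:
            raise ValueError(
                f"unknown cohort {row['cohort']!r} for sample {row['sample_id']!r}"
                f" (expected 'patient' or 'control')"
            ) from None
        paths = []
        for token in str(row["read_paths"]).split(";"):
            token = token.strip()
            if not token:
                continue
            p = Path(token)
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise FileNotFoundError(
                    f"read file {p} for sample {row['sample_id']!r} does not exist"
                )
            paths.append(p)
        if not paths:
            raise ValueError(f"sample {row['sample_id']!r} lists no read paths")
        exposures: dict[str, bool] = {}
        for col in exposure_cols:
            val = _parse_exposure(row[col])
            if val is not None:
                exposures[col] = val
        out.append(SampleManifest(row["sample_id"], paths, cohort, exposures))
    return out


def write_manifest(
    manifests: Sequence[SampleManifest],
    path: str | Path,
    relative_to: Path | None = None,
) -> None:
    """Inverse of load_manifest (exposure unknowns written as NA).

    With ``relative_to``, read paths are written relative to that
    directory (load_manifest resolves relative paths against the
    manifest's own directory, so pass the manifest's parent to get a
    relocatable manifest)."""
    cols = sorted({name for m in manifests for name in m.exposures})
    rows = []
    for m in manifests:
        paths = [
            str(Path(p).resolve().relative_to(relative_to.resolve()))
            if relative_to is not None
            else str(p)
            for p in m.read_paths
        ]
        row = {
            "sample_id": m.sample_id,
            "cohort": m.cohort.value,
            "read_paths": ";".join(paths),
        }
        for c in cols:
            v = m.exposures.get(c)
            row[c] = "NA" if v is None else int(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _open_maybe_gzip(path: Path) -> io.TextIOWrapper:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))  # type: ignore[arg-type]
    return io.TextIOWrapper(fh)


def _normalize(seq: str) -> str:
    return seq.upper().translate(_NORM)


def _iter_reads_one_file(path: Path) -> Iterator[str]:
    with _open_maybe_gzip(path) as probe:
        first = probe.read(1)
    with _open_maybe_gzip(path) as handle:
        if first == ">":
            for idx, (title, seq) in enumerate(SimpleFastaParser(handle)):
                if not seq:
                    raise ValueError(
                        f"{path}: FASTA record {idx} ({title.split()[0] if title else '?'})"
                        " has an empty sequence"
                    )
                yield _normalize(seq)
        elif first == "@":
            try:
                for idx, (_title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                    if len(seq) != len(qual):
                        raise ValueError(
                            f"{path}: FASTQ record {idx} sequence/quality length mismatch"
                        )
                    yield _normalize(seq)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ ({exc})") from None
        elif first == "":
            return
        else:
            raise ValueError(f"{path}: unrecognised format (starts with {first!r})")


def read_sample(manifest: SampleManifest) -> SampleReads:
    """Load and merge all runs of a sample, single-end, normalized to ACGTN."""
    reads: list[str] = []
    for p in manifest.read_paths:
        reads.extend(_iter_reads_one_file(p))
    return SampleReads(manifest.sample_id, reads)


# --------------------------------------------------------------------------
# .kset binary format


def kset_record_width(k: int) -> int:
    return (2 * k + 7) // 8


def write_kmerset(kset: KmerSet, path: str | Path) -> None:
    """Serialize a sorted KmerSet.

    Layout: magic, version, k (u16), record width (u8), count (u64),
    sample_id (u16 length + utf-8), then ``count`` fixed-width
    little-endian codes in ascending order.
    """
    kmers = np.asarray(kset.kmers, dtype=np.uint64)
    if len(kmers) > 1 and not np.all(kmers[1:] > kmers[:-1]):
        raise ValueError("KmerSet must be strictly ascending before writing")
    width = kset_record_width(kset.k)
    sid = kset.sample_id.encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_KSET_MAGIC)
        fh.write(struct.pack("<BHBQ", _KSET_VERSION, kset.k, width, len(kmers)))
        fh.write(struct.pack("<H", len(sid)))
        fh.write(sid)
        # little-endian u64 view truncated to `width` bytes per record
        raw = kmers.astype("<u8").tobytes()
        payload = b"".join(raw[i * 8 : i * 8 + width] for i in range(len(kmers)))
        fh.write(payload)


def read_kset_header(fh) -> tuple[int, int, int, str]:
    magic = fh.read(4)
    if magic != _KSET_MAGIC:
        raise ValueError("not a .kset file (bad magic)")
    version, k, width, count = struct.unpack("<BHBQ", fh.read(12))
    if version != _KSET_VERSION:
        raise ValueError(f"unsupported .kset version {version}")
    (sid_len,) = struct.unpack("<H", fh.read(2))
    sample_id = fh.read(sid_len).decode("utf-8")
    return k, width, count, sample_id


def read_kmerset(path: str | Path) -> KmerSet:
    with open(path, "rb") as fh:
        k, width, count, sample_id = read_kset_header(fh)
        payload = fh.read()
    if len(payload) != count * width:
        raise ValueError(
            f"{path}: payload holds {len(payload)} bytes, header promises"
            f" {count} records of {width} bytes"
        )
    if count == 0:
        return KmerSet(sample_id, k)
    buf = np.frombuffer(payload, dtype=np.uint8).reshape(count, width)
    full = np.zeros((count, 8), dtype=np.uint8)
    full[:, :width] = buf
    kmers = full.view("<u8").ravel().astype(np.uint64)
    return KmerSet(sample_id, k, kmers)


def iter_kset_codes(path: str | Path, chunk: int = 65536) -> Iterator[np.ndarray]:
    """Stream the sorted codes of a .kset file in bounded-size chunks."""
    with open(path, "rb") as fh:
        k, width, count, _sid = read_kset_header(fh)
        remaining = count
        while remaining > 0:
            n = min(chunk, remaining)
            raw = fh.read(n * width)
            if len(raw) != n * width:
                raise ValueError(f"{path}: truncated payload")
            buf = np.frombuffer(raw, dtype=np.uint8).reshape(n, width)
            full = np.zeros((n, 8), dtype=np.uint8)
            full[:, :width] = buf
            yield full.view("<u8").ravel().astype(np.uint64)
            remaining -= n
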