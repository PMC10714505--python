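"""Cohort recurrency index and frequentmer derivation.

A *frequentmer of recurrency r* is a k-mer present in at least ``r``
distinct samples of one cohort of a training split and absent from
every sample of the other cohort.  Recurrency counts distinct samples,
never read-level occurrences: each sample contributes its retained
k-mer set (presence only) to the index.

Two index backends share one contract: an in-memory build over KmerSet
objects, and a streaming multiway merge over sorted ``.kset`` files
whose memory footprint is bounded by the number of open streams rather
than the k-mer universe.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_manifest import Cohort, SampleManifest, iter_kset_codes, read_kset_header
from .kmer import KmerSet


@dataclass
class CohortIndex:
    """Per-cohort sample-recurrency counts for every k-mer seen in a
    training split.  ``kmers`` is sorted ascending; the two count arrays
    are parallel to it."""

    k: int
    fold_id: int
    kmers: np.ndarray
    n_control: np.ndarray
    n_patient: np.ndarray
    m_controls: int = 0  # control samples indexed
    l_patients: int = 0  # patient samples indexed

    def __len__(self) -> int:
        return len(self.kmers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kmer": self.kmers, "n_control": self.n_control, "n_patient": self.n_patient}
        )


@dataclass
class FrequentmerCatalog:
    """Disjoint control/patient frequentmer sets at one recurrency
    threshold, tied to the fold whose training split produced them."""

    fold_id: int
    r: int
    k: int
    control_fms: np.ndarray
    patient_fms: np.ndarray

    @property
    def n_total(self) -> int:
        return len(self.control_fms) + len(self.patient_fms)

    def feature_order(self) -> np.ndarray:
        """Canonical feature column order: control block then patient
        block, each ascending."""
        return np.concatenate(
            [np.sort(self.control_fms), np.sort(self.patient_fms)]
        ).astype(np.uint64)


def _cohort_of(manifests: Iterable[SampleManifest]) -> dict[str, Cohort]:
    return {m.sample_id: m.cohort for m in manifests}


def build_index(
    ksets: Sequence[KmerSet],
    manifests: Sequence[SampleManifest],
    fold_id: int = 0,
) -> CohortIndex:
    """In-memory index build: count, per k-mer, the number of distinct
    training samples of each cohort whose retained set contains it."""
    cohort_of = _cohort_of(manifests)
    ks = {s.k for s in ksets}
    if len(ks) > 1:
        raise ValueError(f"mixed k among KmerSets: {sorted(ks)}")
    k = ks.pop() if ks else 0
    chunks, is_patient = [], []
    m = l = 0
    for s in ksets:
        if s.sample_id not in cohort_of:
            raise KeyError(f"sample {s.sample_id!r} not present in manifest")
        pat = cohort_of[s.sample_id] == Cohort.patient
        l += pat
        m += not pat
        chunks.append(s.kmers)
        is_patient.append(np.full(len(s.kmers), pat, dtype=bool))
    if not chunks or sum(map(len, chunks)) == 0:
        return CohortIndex(
            k, fold_id, np.empty(0, np.uint64), np.empty(0, np.int64),
            np.empty(0, np.int64), m, l,
        )
    codes = np.concatenate(chunks)
    pat_mask = np.concatenate(is_patient)
    uniq, inv = np.unique(codes, return_inverse=True)
    n_patient = np.bincount(inv, weights=pat_mask, minlength=len(uniq)).astype(np.int64)
    n_control = np.bincount(inv, minlength=len(uniq)).astype(np.int64) - n_patient
    return CohortIndex(k, fold_id, uniq, n_control, n_patient, m, l)


def build_index_streaming(
    kset_paths: Sequence[str | Path],
    manifests: Sequence[SampleManifest],
    fold_id: int = 0,
    chunk: int = 65536,
) -> CohortIndex:
    """Streaming index build over sorted ``.kset`` files.

    Performs a heap-based multiway merge of per-file chunk streams;
    memory is bounded by ``chunk`` times the number of files.  Output is
    identical to :func:`build_index` on the same data.
    """
    cohort_of = _cohort_of(manifests)
    headers = []
    for p in kset_paths:
        with open(p, "rb") as fh:
            k, _w, _c, sid = read_kset_header(fh)
        if sid not in cohort_of:
            raise KeyError(f"sample {sid!r} (from {p}) not present in manifest")
        headers.append((k, sid))
    ks = {h[0] for h in headers}
    if len(ks) > 1:
        raise ValueError(f"mixed k among .kset files: {sorted(ks)}")
    k = ks.pop() if ks else 0
    m = sum(cohort_of[sid] == Cohort.control for _, sid in headers)
    l = len(headers) - m

    def stream(path, is_pat):
        for arr in iter_kset_codes(path, chunk=chunk):
            for code in arr.tolist():
                yield code, is_pat

    streams = [
        stream(p, cohort_of[sid] == Cohort.patient)
        for p, (_k, sid) in zip(kset_paths, headers)
    ]
    out_k, out_c, out_p = [], [], []
    cur = None
    cc = cp = 0
    for code, is_pat in heapq.merge(*streams):
        if code != cur:
            if cur is not None:
                out_k.append(cur)
                out_c.append(cc)
                out_p.append(cp)
            cur, cc, cp = code, 0, 0
        if is_pat:
            cp += 1
        else:
            cc += 1
    if cur is not None:
        out_k.append(cur)
        out_c.append(cc)
        out_p.append(cp)
    return CohortIndex(
        k, fold_id,
        np.asarray(out_k, dtype=np.uint64),
        np.asarray(out_c, dtype=np.int64),
        np.asarray(out_p, dtype=np.int64),
        m, l,
    )


def derive_frequentmers(index: CohortIndex, r: int) -> FrequentmerCatalog:
    """Apply the recurrency/absence rule to an index.

    control frequentmers: present in >= r control samples, 0 patients;
    patient frequentmers: present in >= r patient samples, 0 controls.
    """
    if r < 1:
        raise ValueError("recurrency threshold r must be >= 1")
    if r <= 1:
        warnings.warn(
            "r <= 1 degenerates to mere group-absence; every group-exclusive "
            "k-mer qualifies",
            stacklevel=2,
        )
    control = index.kmers[(index.n_control >= r) & (index.n_patient == 0)]
    patient = index.kmers[(index.n_patient >= r) & (index.n_control == 0)]
    return FrequentmerCatalog(index.fold_id, r, index.k, control, patient)


def recurrency_sweep(index: CohortIndex, r_values: Sequence[int]) -> pd.DataFrame:
    """Catalog sizes and the patient share of frequentmers across a grid
    of recurrency thresholds.

    ``patient_ratio`` is n_patient_fms / (n_patient_fms + n_control_fms),
    NaN when no frequentmers exist at that threshold.
    """
    if len(r_values) == 0:
        raise ValueError("r_values must be non-empty")
    rows = []
    for r in r_values:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cat = derive_frequentmers(index, r)
        total = cat.n_total
        rows.append(
            {
                "r": r,
                "n_control_fms": len(cat.control_fms),
                "n_patient_fms": len(cat.patient_fms),
                "patient_ratio": (len(cat.patient_fms) / total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """How well a fold's training-derived catalog is re-observed in the
    held-out test samples."""

    fold_id: int
    r: int
    recovery_fraction: float          # catalog fms seen in >= 1 test sample
    recovery_fraction_control: float  # restricted to control fms (NaN if none)
    recovery_fraction_patient: float
    per_sample: pd.DataFrame          # sample_id, cohort, n_control_fms, n_patient_fms
    votes: pd.DataFrame               # kmer, side, n_control_samples, n_patient_samples, vote
    mannwhitney_u: float              # patient-fm counts, patient vs control test samples
    mannwhitney_p: float
    control_fm_enrichment: float      # mean control-fm hits in control / in patient samples
    patient_fm_enrichment: float

    n_recovered: int = 0
    n_catalog: int = 0


def _membership_counts(fms: np.ndarray, ksets: Sequence[KmerSet]) -> np.ndarray:
    """(n_samples, n_fms) boolean presence matrix via sorted search."""
    out = np.zeros((len(ksets), len(fms)), dtype=bool)
    for i, s in enumerate(ksets):
        if len(s.kmers) and len(fms):
            idx = np.searchsorted(s.kmers, fms)
            idx = np.clip(idx, 0, len(s.kmers) - 1)
            out[i] = s.kmers[idx] == fms
    return out


def test_recovery(
    catalog: FrequentmerCatalog,
    test_ksets: Sequence[KmerSet],
    manifests: Sequence[SampleManifest],
) -> RecoveryReport:
    """Evaluate a catalog on held-out test samples.

    Reports the fraction of catalog frequentmers recovered in >= 1 test
    sample, per-sample detection counts by frequentmer side, a
    majority-vote cohort assignment per recovered frequentmer (ties are
    unassigned), and a Mann-Whitney U comparing per-sample patient-
    frequentmer counts between the two test cohorts.
    """
    if len(test_ksets) == 0:
        raise ValueError("empty test set")
    cohort_of = _cohort_of(manifests)
    cohorts = [cohort_of[s.sample_id] for s in test_ksets]
    is_pat = np.array([c == Cohort.patient for c in cohorts])

    ctrl = np.sort(catalog.control_fms).astype(np.uint64)
    pat = np.sort(catalog.patient_fms).astype(np.uint64)
    pres_c = _membership_counts(ctrl, test_ksets)  # samples x control fms
    pres_p = _membership_counts(pat, test_ksets)

    per_sample = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in test_ksets],
            "cohort": [c.value for c in cohorts],
            "n_control_fms": pres_c.sum(axis=1),
            "n_patient_fms": pres_p.sum(axis=1),
        }
    )

    def _vote_frame(fms, pres, side):
        n_in_pat = pres[is_pat].sum(axis=0)
        n_in_ctrl = pres[~is_pat].sum(axis=0)
        recovered = (n_in_pat + n_in_ctrl) > 0
        vote = np.where(
            n_in_ctrl > n_in_pat, "control", np.where(n_in_pat > n_in_ctrl, "patient", "unassigned")
        )
        return pd.DataFrame(
            {
                "kmer": fms,
                "side": side,
                "n_control_samples": n_in_ctrl,
                "n_patient_samples": n_in_pat,
                "recovered": recovered,
                "vote": np.where(recovered, vote, "unrecovered"),
            }
        )

    votes = pd.concat(
        [_vote_frame(ctrl, pres_c, "control"), _vote_frame(pat, pres_p, "patient")],
        ignore_index=True,
    )
    n_catalog = catalog.n_total
    n_recovered = int(votes["recovered"].sum())

    def _frac(side):
        sub = votes[votes["side"] == side]
        return float(sub["recovered"].mean()) if len(sub) else float("nan")

    pat_counts_in_pat = per_sample.loc[is_pat, "n_patient_fms"].to_numpy(float)
    pat_counts_in_ctrl = per_sample.loc[~is_pat, "n_patient_fms"].to_numpy(float)
    if len(pat_counts_in_pat) and len(pat_counts_in_ctrl):
        try:
            u, p = stats.mannwhitneyu(pat_counts_in_pat, pat_counts_in_ctrl)
        except ValueError:  # all-identical values
            u, p = float("nan"), 1.0
    else:
        u, p = float("nan"), float("nan")

    def _enrich(pres, in_group):
        """mean per-sample hit count in own-cohort test samples over the
        mean in the opposite cohort (Fig-2e-style fold enrichment)."""
        own = pres[in_group].sum(axis=1).mean() if in_group.any() else np.nan
        other = pres[~in_group].sum(axis=1).mean() if (~in_group).any() else np.nan
        if not np.isfinite(own) or not np.isfinite(other):
            return float("nan")
        if other == 0:
            # perfectly exclusive detection: unbounded enrichment
            return float("inf") if own > 0 else float("nan")
        return float(own / other)

    return RecoveryReport(
        fold_id=catalog.fold_id,
        r=catalog.r,
        recovery_fraction=(n_recovered / n_catalog) if n_catalog else float("nan"),
        recovery_fraction_control=_frac("control"),
        recovery_fraction_patient=_frac("patient"),
        per_sample=per_sample,
        votes=votes,
        mannwhitney_u=float(u),
        mannwhitney_p=float(p),
        control_fm_enrichment=_enrich(pres_c, ~is_pat),
        patient_fm_enrichment=_enrich(pres_p, is_pat),
        n_recovered=n_recovered,
        n_catalog=n_catalog,
    )
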