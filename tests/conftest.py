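import numpy as np
import pytest

from frequentmers import (
    Cohort,
    KmerCodec,
    KmerSet,
    SampleManifest,
    build_index,
)


def make_manifest(sample_id, cohort, exposures=None):
    return SampleManifest(sample_id, [], Cohort(cohort), exposures or {})


def kset_from_strings(sample_id, k, seqs):
    """KmerSet straight from explicit k-mer strings (no filtering)."""
    codec = KmerCodec(k)
    codes = np.sort(np.array([codec.encode(s) for s in seqs], dtype=np.uint64))
    return KmerSet(sample_id, k, np.unique(codes))


@pytest.fixture
def toy_cohort():
    """Five samples, k=3: H1..H3 controls, P1..P2 patients."""
    manifests = [
        make_manifest("H1", "control"),
        make_manifest("H2", "control"),
        make_manifest("H3", "control"),
        make_manifest("P1", "patient"),
        make_manifest("P2", "patient"),
    ]
    ksets = [
        kset_from_strings("H1", 3, ["AAA", "CCC"]),
        kset_from_strings("H2", 3, ["AAA", "GGG"]),
        kset_from_strings("H3", 3, ["CCC", "TTT"]),
        kset_from_strings("P1", 3, ["AAA", "TTT"]),
        kset_from_strings("P2", 3, ["GGG", "CCA"]),
    ]
    return manifests, ksets


@pytest.fixture
def toy_index(toy_cohort):
    manifests, ksets = toy_cohort
    return build_index(ksets, manifests, fold_id=0)


def naive_frequentmers(ksets, manifests, r):
    """Brute-force derivation: per-k-mer membership scans over samples.

    Independent of the indexed implementation — plain python sets only.
    """
    cohort_of = {m.sample_id: m.cohort for m in manifests}
    sets = {s.sample_id: set(int(c) for c in s.kmers) for s in ksets}
    universe = set().union(*sets.values()) if sets else set()
    control, patient = [], []
    for code in universe:
        n_c = sum(
            1 for sid, ks in sets.items()
            if cohort_of[sid] == Cohort.control and code in ks
        )
        n_p = sum(
            1 for sid, ks in sets.items()
            if cohort_of[sid] == Cohort.patient and code in ks
        )
        if n_c >= r and n_p == 0:
            control.append(code)
        if n_p >= r and n_c == 0:
            patient.append(code)
    return set(control), set(patient)


def random_cohort(rng, k, max_samples=12, max_kmers=200):
    """Random small cohort for oracle-equivalence checks."""
    n_c = int(rng.integers(1, max_samples // 2 + 1))
    n_p = int(rng.integers(1, max_samples // 2 + 1))
    universe = int(min(4**k, 4 * max_kmers))
    manifests, ksets = [], []
    for i in range(n_c):
        manifests.append(make_manifest(f"H{i}", "control"))
        n = int(rng.integers(0, max_kmers + 1))
        codes = np.unique(rng.integers(0, universe, size=n).astype(np.uint64))
        ksets.append(KmerSet(f"H{i}", k, codes))
    for i in range(n_p):
        manifests.append(make_manifest(f"P{i}", "patient"))
        n = int(rng.integers(0, max_kmers + 1))
        codes = np.unique(rng.integers(0, universe, size=n).astype(np.uint64))
        ksets.append(KmerSet(f"P{i}", k, codes))
    return manifests, ksets
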