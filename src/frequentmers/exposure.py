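"""Exposure-restricted frequentmers and Jaccard profile comparisons.

Within the patient cohort, a binary covariate (e.g. viral infection
status or high alcohol intake) splits samples into exposure-positive
and exposure-negative subgroups.  A subset-specific frequentmer must be
a patient frequentmer (absent from every control) that is additionally
present in at least ``r`` exposure-positive patients and absent from
every exposure-negative patient.

Profile similarity between subgroups is quantified with the Jaccard
index over per-sample frequentmer sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_manifest import Cohort, SampleManifest
from .kmer import KmerSet


@dataclass
class ExposureReport:
    covariate: str
    r: int
    subset_specific_fms: np.ndarray   # sorted codes
    per_fm_prevalence: np.ndarray     # fraction of exposure-positive samples with each fm
    n_positive: int
    n_negative: int

    def prevalence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kmer": self.subset_specific_fms, "prevalence": self.per_fm_prevalence}
        )

    def prevalence_histogram(self, n_bins: int = 10) -> pd.DataFrame:
        """Counts of frequentmers per percentage-of-positive-samples bin."""
        edges = np.linspace(0, 1, n_bins + 1)
        counts, _ = np.histogram(self.per_fm_prevalence, bins=edges)
        return pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "n_fms": counts}
        )


def subset_specific_frequentmers(
    ksets: list[KmerSet],
    manifests: list[SampleManifest],
    covariate: str,
    r: int,
) -> ExposureReport:
    """Frequentmers confined to the exposure-positive patient subgroup.

    Requires presence in >= r exposure-positive patients and absence
    from all exposure-negative patients and all controls.  Patients with
    unknown exposure status are excluded with a warning rather than
    treated as negative.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    info = {m.sample_id: m for m in manifests}
    if not any(covariate in m.exposures for m in manifests):
        raise KeyError(f"covariate {covariate!r} absent from manifest")
    pos, neg, ctrl = [], [], []
    n_unknown = 0
    for s in ksets:
        m = info[s.sample_id]
        if m.cohort == Cohort.control:
            ctrl.append(s)
        elif covariate not in m.exposures:
            n_unknown += 1
        elif m.exposures[covariate]:
            pos.append(s)
        else:
            neg.append(s)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} patient sample(s) with unknown {covariate!r} status "
            "excluded from the subgroup analysis",
            stacklevel=2,
        )
    if not pos:
        raise ValueError(f"no exposure-positive patient samples for {covariate!r}")

    def _union_counts(group):
        if not group or all(len(s.kmers) == 0 for s in group):
            return np.empty(0, np.uint64), np.empty(0, np.int64)
        codes = np.concatenate([s.kmers for s in group])
        uniq, counts = np.unique(codes, return_counts=True)
        return uniq, counts

    pos_k, pos_n = _union_counts(pos)
    neg_k, _ = _union_counts(neg)
    ctrl_k, _ = _union_counts(ctrl)
    excluded = np.union1d(neg_k, ctrl_k)
    keep = (pos_n >= r) & ~np.isin(pos_k, excluded)
    fms = pos_k[keep]
    prevalence = pos_n[keep] / len(pos)
    return ExposureReport(covariate, r, fms, prevalence, len(pos), len(neg))


@dataclass
class ComparisonReport:
    within_group: np.ndarray   # Jaccard over same-group pairs (both groups pooled)
    cross_group: np.ndarray    # Jaccard over pairs straddling the groups
    within_a: np.ndarray
    within_b: np.ndarray
    t_statistic: float
    p_value: float
    paired: bool
    empty_pair_count: int      # pairs where both sets were empty (J=0 by convention)


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty, by convention."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard_profile_comparison(
    sample_fm_sets: list,
    group_mask: list[bool] | np.ndarray,
    paired: bool = False,
    pairs: list[tuple[int, int]] | None = None,
) -> ComparisonReport:
    """Compare frequentmer-profile similarity within and across two
    sample subgroups.

    Computes the Jaccard index for every within-group and every
    cross-group sample pair, then a two-sample Welch t-test between the
    pooled within-group and the cross-group distributions.  The opt-in
    paired mode requires an explicit list of (within_index, cross_index)
    positions into the two distributions and runs a paired t-test on
    those matched values.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if len(group_mask) != len(sample_fm_sets):
        raise ValueError("group_mask length must match sample count")
    idx_a = np.flatnonzero(group_mask)
    idx_b = np.flatnonzero(~group_mask)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    sets = [set(np.asarray(s, dtype=np.uint64).tolist()) if not isinstance(s, set) else s
            for s in sample_fm_sets]
    empty_pairs = 0

    def _pairs(indices):
        nonlocal empty_pairs
        vals = []
        for i, j in itertools.combinations(indices, 2):
            if not sets[i] and not sets[j]:
                empty_pairs += 1
            vals.append(jaccard(sets[i], sets[j]))
        return np.asarray(vals)

    within_a = _pairs(idx_a)
    within_b = _pairs(idx_b)
    within = np.concatenate([within_a, within_b])
    cross_vals = []
    for i in idx_a:
        for j in idx_b:
            if not sets[i] and not sets[j]:
                empty_pairs += 1
            cross_vals.append(jaccard(sets[i], sets[j]))
    cross = np.asarray(cross_vals)

    if paired:
        if pairs is None:
            raise ValueError("paired mode requires an explicit pairs list")
        w = np.array([within[i] for i, _ in pairs])
        c = np.array([cross[j] for _, j in pairs])
        t, p = stats.ttest_rel(w, c)
    else:
        t, p = stats.ttest_ind(within, cross, equal_var=False)
    return ComparisonReport(
        within_group=within,
        cross_group=cross,
        within_a=within_a,
        within_b=within_b,
        t_statistic=float(t),
        p_value=float(p),
        paired=paired,
        empty_pair_count=empty_pairs,
    )
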