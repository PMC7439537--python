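"""Compositional statistics: CLR, Aitchison distances, diversity, PERMANOVA,
and the nonparametric test battery with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from microguild.data_model import AbundanceTable, MetadataTable

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_DEPTH = 16_000


class ClrMatrix:
    """Samples x OTUs matrix of centered log-ratio values (rows sum to zero)."""

    def __init__(self, sample_ids: list[str], otu_ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sample_ids), len(otu_ids)):
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("CLR matrix contains non-finite values")
        if np.any(np.abs(values.sum(axis=1)) > 1e-8):
            raise ValueError("CLR rows must sum to zero")
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)
        self.values = values

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError("distance matrix must be square over ids")
        if np.any(np.isnan(values)):
            raise ValueError("distance matrix contains NaN")
        if np.any(np.abs(values - values.T) > 1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(values < -1e-12):
            raise ValueError("distances must be non-negative")
        self.ids = list(ids)
        self.values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, two-sided p, optional BH q, direction."""

    name: str
    statistic: float
    p: float
    q: float | None = None
    direction: int = 0
    n: int = 0

    def with_q(self, q: float) -> "TestResult":
        return TestResult(self.name, self.statistic, self.p, q, self.direction, self.n)


def clr_transform(
    table: AbundanceTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    depth: int = DEFAULT_DEPTH,
) -> ClrMatrix:
    """Centered log-ratio transform of an abundance table.

    For counts the pseudocount is added to every count. For relative
    abundances the pseudocount is interpreted as a count-equivalent at the
    stated sequencing ``depth`` (i.e. ``pseudocount / depth`` is added).
    Row ``i``, OTU ``j`` maps to ``ln((x_ij + d) / g_i)`` with ``g_i`` the
    geometric mean of the adjusted row, so every row sums to zero.
    """
    if table.mode == "counts":
        adjusted = table.values + pseudocount
    else:
        adjusted = table.values + pseudocount / float(depth)
    if np.any(adjusted <= 0):
        raise ValueError("adjusted abundances must be strictly positive")
    logs = np.log(adjusted)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(table.sample_ids, table.otu_ids, clr)


def aitchison_distance_matrix(clr: ClrMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between CLR rows (Aitchison distance)."""
    if len(clr.sample_ids) < 2:
        raise ValueError("need at least two samples")
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(clr.sample_ids, squareform(pdist(clr.values, "euclidean")))


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Shannon index (nats) and OTU richness per sample.

    Works on counts or relative abundances; proportions are computed
    internally and zero components are skipped in the entropy sum.
    """
    rows = []
    for i, sid in enumerate(table.sample_ids):
        vec = table.values[i]
        total = vec.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} is empty")
        p = vec[vec > 0] / total
        rows.append(
            {
                "sample_id": sid,
                "shannon": float(-(p * np.log(p)).sum()),
                "richness": int((vec > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def beta_dispersion_summaries(
    d: DistanceMatrix, meta: MetadataTable, baseline: str = "BL"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-subject and intra-subject dissimilarity summaries.

    Inter: all unordered sample pairs within the same arm and timepoint.
    Intra: for each subject, distance from its baseline sample to each later
    timepoint. Subjects without a baseline sample are excluded with a warning.
    """
    for sid in d.ids:
        if sid not in meta:
            raise ValueError(f"metadata missing sample {sid!r}")
    inter_rows = []
    recs = [meta[s] for s in d.ids]
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in recs:
        groups.setdefault((rec.arm, rec.timepoint), []).append(rec.sample_id)
    for (arm, tp), samples in sorted(groups.items()):
        if len(samples) < 2:
            warnings.warn(
                f"arm {arm!r} timepoint {tp!r} has fewer than two samples; "
                "no inter-subject pairs",
                stacklevel=2,
            )
            continue
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                inter_rows.append(
                    {
                        "arm": arm,
                        "timepoint": tp,
                        "sample_a": samples[i],
                        "sample_b": samples[j],
                        "distance": d[samples[i], samples[j]],
                    }
                )
    intra_rows = []
    by_subject: dict[str, dict[str, str]] = {}
    for rec in recs:
        by_subject.setdefault(rec.subject_id, {})[rec.timepoint] = rec.sample_id
    for subject, tps in sorted(by_subject.items()):
        if baseline not in tps:
            warnings.warn(
                f"subject {subject!r} lacks baseline sample; excluded from "
                "intra-subject shifts",
                stacklevel=2,
            )
            continue
        for tp, sid in sorted(tps.items()):
            if tp == baseline:
                continue
            intra_rows.append(
                {
                    "subject_id": subject,
                    "arm": meta[sid].arm,
                    "timepoint": tp,
                    "distance": d[tps[baseline], sid],
                }
            )
    return pd.DataFrame(inter_rows), pd.DataFrame(intra_rows)


def _group_indicators(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    indicators = np.zeros((len(uniq), len(labels)), dtype=float)
    indicators[inv, np.arange(len(labels))] = 1.0
    return indicators, np.array([int(s) for s in indicators.sum(axis=1)])


def _ss_within(d2: np.ndarray, indicators: np.ndarray, sizes: np.ndarray) -> float:
    # sum_{i<j in g} d2_ij = z^T D2 z / 2 for indicator z of group g
    ssw = 0.0
    for z, n_g in zip(indicators, sizes):
        ssw += float(z @ d2 @ z) / (2.0 * n_g)
    return ssw


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "sampled",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = [SS_between/(g-1)] / [SS_within/(N-g)], with
    SS_total = (1/N) * sum_{i<j} d_ij^2 and
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2.
    With ``method="sampled"`` the p value is
    ``(1 + #{permuted F >= observed F}) / (n_perm + 1)`` under free random
    permutation of the labels; ``method="exact"`` enumerates every label
    permutation (n <= 8 only) and p is the exact fraction with F >= observed
    (the identity permutation counts, so p >= 1/n!).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != len(d.ids):
        raise ValueError("labels must align with distance matrix ids")
    indicators, sizes = _group_indicators(labels)
    g = len(sizes)
    if g < 2:
        raise ValueError("need at least two groups")
    if sizes.max() < 2:
        raise ValueError("at least one group must have two or more members")
    d2 = d.values**2
    if not np.any(d2 > 0):
        raise ValueError("degenerate matrix: all distances are zero")
    ss_total = float(d2[np.triu_indices(n, k=1)].sum()) / n
    ss_within = _ss_within(d2, indicators, sizes)
    ss_between = ss_total - ss_within

    def f_from_ssw(ssw):
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / (g - 1)) / (ssw / (n - g))

    f_obs = f_from_ssw(ss_within)
    if method == "exact":
        import itertools
        import math

        if n > 8:
            raise ValueError("exact enumeration supported only for n <= 8")
        perm_cols = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        total = math.factorial(n)
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        perm_cols = np.empty((n_perm, n), dtype=np.intp)
        for p in range(n_perm):
            perm_cols[p] = rng.permutation(n)
        total = None
    else:
        raise ValueError(f"unknown method {method!r}")
    ssw_perm = np.zeros(perm_cols.shape[0])
    for z, n_g in zip(indicators, sizes):
        zp = z[perm_cols]  # (n_perm, n)
        ssw_perm += np.einsum("pi,ij,pj->p", zp, d2, zp) / (2.0 * n_g)
    f_perm = f_from_ssw(ssw_perm)
    exceed = int(np.count_nonzero(f_perm >= f_obs - 1e-12))
    if method == "exact":
        p_value = exceed / total  # identity permutation is in the enumeration
        reported_n_perm = total
    else:
        p_value = (1 + exceed) / (n_perm + 1)
        reported_n_perm = n_perm
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p=float(p_value),
        n_perm=reported_n_perm,
        group_sizes=tuple(int(s) for s in np.sort(sizes)[::-1]),
    )


def paired_rank_test(x_before, x_after, name: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are discarded. If every difference is zero the test is
    vacuous and ``p = 1`` is returned with a warning.
    """
    x_before = np.asarray(x_before, dtype=float)
    x_after = np.asarray(x_after, dtype=float)
    if x_before.shape != x_after.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = x_after - x_before
    nonzero = diffs[diffs != 0]
    direction = int(np.sign(np.median(diffs))) if diffs.size else 0
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(name, 0.0, 1.0, direction=0, n=len(diffs))
    stat, p = sps.wilcoxon(x_after, x_before, alternative="two-sided")
    return TestResult(name, float(stat), float(p), direction=direction, n=len(diffs))


def unpaired_rank_test(x_a, x_b, name: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test between two independent groups."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = sps.mannwhitneyu(x_a, x_b, alternative="two-sided")
    direction = int(np.sign(np.median(x_a) - np.median(x_b)))
    return TestResult(name, float(stat), float(min(p, 1.0)), direction=direction,
                      n=x_a.size + x_b.size)


def friedman_dunn(matrix, column_names: list[str] | None = None):
    """Friedman omnibus test plus Dunn-corrected pairwise comparisons.

    ``matrix`` is subjects x k >= 3 repeated measures (complete cases).
    Pairwise z = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(6n)); two-sided normal p,
    Bonferroni-multiplied by the number of pairs and capped at one.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if k < 3:
        raise ValueError("need k >= 3 repeated measures; use paired_rank_test for k = 2")
    if np.any(np.isnan(matrix)):
        raise ValueError("complete cases only: matrix contains NaN")
    if column_names is None:
        column_names = [f"t{j}" for j in range(k)]
    ranks = sps.rankdata(matrix, axis=1)
    mean_ranks = ranks.mean(axis=0)
    if np.allclose(matrix, matrix[:, [0]]):
        omnibus = TestResult("friedman", 0.0, 1.0, n=n)
    else:
        stat, p = sps.friedmanchisquare(*(matrix[:, j] for j in range(k)))
        omnibus = TestResult("friedman", float(stat), float(p), n=n)
    n_pairs = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            pairwise.append(
                TestResult(
                    f"{column_names[i]} vs {column_names[j]}",
                    float(z),
                    float(min(1.0, p_raw * n_pairs)),
                    direction=int(np.sign(z)),
                    n=n,
                )
            )
    return omnibus, pairwise


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values.

    q_(i) = min over j >= i of (m * p_(j) / j), mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def attach_bh_q(results: list[TestResult]) -> list[TestResult]:
    """Attach BH q values computed over a family of test results."""
    if not results:
        return []
    q = bh_fdr([r.p for r in results])
    return [r.with_q(float(qi)) for r, qi in zip(results, q)]
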