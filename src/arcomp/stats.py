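"""Group-level statistics: cluster permutation contrasts, Tucker
congruence replicability, and resting-period temporal stability.

The spatial contrast between two alpha components is tested with a
one-sided paired cluster-based permutation test on the source grid:
per-source paired t statistics, a cluster-forming threshold at a
percentile of the t distribution, spatially connected suprathreshold
clusters scored by their summed t values, and a max-cluster-statistic
permutation null obtained by sign-flipping the paired differences
within subjects.

Replicability of loading vectors is quantified by the Tucker congruence
coefficient (TCC); for non-negative loadings it lies in [0, 1], with
> 0.85 conventionally read as highly similar and > 0.95 as nearly
identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .headmodel import SourceGrid
from .parafac import ParafacResults

__all__ = [
    "tucker_congruence",
    "match_components",
    "find_clusters",
    "cluster_permutation_test",
    "ClusterTestResult",
    "rec_period_stability",
    "repeated_measures_anova",
    "replicability_report",
]

TCC_HIGHLY_SIMILAR = 0.85
TCC_NEARLY_IDENTICAL = 0.95


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker congruence coefficient sum(x*y) / sqrt(sum(x^2) sum(y^2)).

    Scale-invariant cosine similarity of loading vectors; in [0, 1] for
    non-negative inputs. Raises on zero vectors, for which the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("Tucker congruence is undefined for a zero vector")
    return float(x @ y / (nx * ny))


def match_components(
    reference: np.ndarray,
    estimated: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy TCC matching of estimated loading columns to reference columns.

    Both arguments are (dim, n_components) matrices. Returns
    (permutation, congruences): ``estimated[:, permutation[j]]`` is the
    match for ``reference[:, j]``. Greedy on the highest remaining
    congruence, which resolves the permutation indeterminacy of PARAFAC.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimated, dtype=float)
    n_ref, n_est = ref.shape[1], est.shape[1]
    if n_est < n_ref:
        raise ValueError("fewer estimated components than reference components")
    tcc = np.zeros((n_ref, n_est))
    for i in range(n_ref):
        for j in range(n_est):
            if np.linalg.norm(est[:, j]) == 0:
                tcc[i, j] = -np.inf
            else:
                tcc[i, j] = tucker_congruence(ref[:, i], est[:, j])
    perm = np.full(n_ref, -1, dtype=int)
    cong = np.zeros(n_ref)
    work = tcc.copy()
    for _ in range(n_ref):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        cong[i] = tcc[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return perm, cong


def find_clusters(
    values: np.ndarray,
    threshold: float,
    neighbor_lists: list[np.ndarray],
) -> list[np.ndarray]:
    """Connected components of {i : values[i] > threshold} under adjacency.

    Breadth-first search over the suprathreshold subgraph; returns each
    cluster as a sorted index array, ordered by decreasing summed value.
    """
    supra = np.nonzero(values > threshold)[0]
    if supra.size == 0:
        return []
    in_supra = np.zeros(len(values), dtype=bool)
    in_supra[supra] = True
    seen = np.zeros(len(values), dtype=bool)
    clusters: list[np.ndarray] = []
    for start in supra:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        members = []
        while stack:
            i = stack.pop()
            members.append(i)
            for j in neighbor_lists[i]:
                if in_supra[j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        clusters.append(np.asarray(sorted(members), dtype=int))
    clusters.sort(key=lambda c: -float(values[c].sum()))
    return clusters


@dataclass
class ClusterTestResult:
    """Outcome of a one-sided paired cluster permutation test."""

    contrast: str
    t_map: np.ndarray
    clusters: list[np.ndarray]
    cluster_stats: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    cluster_forming_threshold: float
    seed: int | None

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < 0.05

    def summary(self) -> str:
        lines = [
            f"Cluster permutation test: {self.contrast}",
            f"  threshold t > {self.cluster_forming_threshold:.3f}, "
            f"{self.n_permutations} permutations",
        ]
        if not self.clusters:
            lines.append("  no suprathreshold clusters")
        for i, (c, s, p) in enumerate(zip(self.clusters, self.cluster_stats, self.p_values)):
            lines.append(f"  cluster {i + 1}: {len(c)} sources, sum t = {s:.2f}, p = {p:.4f}")
        return "\n".join(lines)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Per-column one-sample t statistic of subject x source differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def cluster_permutation_test(
    loadA: np.ndarray,
    loadB: np.ndarray,
    grid: SourceGrid | list[np.ndarray],
    n_perm: int = 5000,
    pct: float = 99.0,
    seed: int | None = None,
    plus_one: bool = False,
) -> list[ClusterTestResult]:
    """Both one-sided contrasts (A > B and B > A) of per-subject loadings.

    ``loadA``/``loadB`` are (subjects x sources) matrices of
    max-normalized spatial loadings. The cluster-forming threshold is
    the ``pct`` percentile of the t distribution with n-1 degrees of
    freedom; the null distribution is the maximum cluster statistic
    over random within-subject sign flips of the paired differences.
    P-values use the strict count (null > observed) / n_perm, clipped
    below at 1/n_perm; ``plus_one`` switches to the
    (count + 1)/(n_perm + 1) convention.
    """
    loadA = np.asarray(loadA, dtype=float)
    loadB = np.asarray(loadB, dtype=float)
    if loadA.shape != loadB.shape:
        raise ValueError("loading matrices must have the same shape")
    n_subj, n_src = loadA.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    neighbor_lists = grid.neighbor_lists() if isinstance(grid, SourceGrid) else grid
    if len(neighbor_lists) != n_src:
        raise ValueError("adjacency size does not match the number of sources")

    threshold = float(sps.t.ppf(pct / 100.0, df=n_subj - 1))
    diffs = loadA - loadB
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))

    # sign flips leave per-source sums of squares unchanged, so the
    # permuted t maps only need flipped sums
    sumsq = np.sum(diffs**2, axis=0)

    def _null_max_stats(d: np.ndarray) -> np.ndarray:
        sums = flips @ d
        mean = sums / n_subj
        var = (sumsq - n_subj * mean**2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = mean / np.sqrt(var / n_subj)
        t_null = np.where(var <= 0, 0.0, t_null)
        out = np.zeros(n_perm)
        for p in range(n_perm):
            row = t_null[p]
            cl = find_clusters(row, threshold, neighbor_lists)
            if cl:
                out[p] = float(row[cl[0]].sum())
        return out

    results = []
    for contrast, d in (("A>B", diffs), ("B>A", -diffs)):
        t_map = _paired_t(d)
        clusters = find_clusters(t_map, threshold, neighbor_lists)
        stats = np.array([float(t_map[c].sum()) for c in clusters])
        null = _null_max_stats(d)
        if plus_one:
            p_vals = np.array([(np.sum(null > s) + 1.0) / (n_perm + 1.0) for s in stats])
        else:
            p_vals = np.array([np.sum(null > s) / n_perm for s in stats])
            p_vals = np.clip(p_vals, 1.0 / n_perm, 1.0)
        results.append(
            ClusterTestResult(
                contrast=contrast,
                t_map=t_map,
                clusters=clusters,
                cluster_stats=stats,
                p_values=p_vals,
                n_permutations=n_perm,
                cluster_forming_threshold=threshold,
                seed=seed,
            )
        )
    return results


def rec_period_stability(
    results: ParafacResults,
    boundaries: np.ndarray,
) -> pd.DataFrame:
    """Per-period means of max-normalized temporal loadings.

    ``boundaries`` are sample indices splitting the recording into
    resting periods; windows are assigned to periods by their centers.
    Returns a DataFrame (periods x components). Group-level testing
    across subjects is done by stacking these tables and calling
    :func:`repeated_measures_anova` per component.
    """
    centers = results.model.window_centers
    if centers is None:
        raise ValueError("model carries no window-center metadata")
    boundaries = np.asarray(boundaries, dtype=int)
    period = np.searchsorted(boundaries, centers, side="right")
    n_periods = len(boundaries) + 1
    if n_periods < 2:
        raise ValueError("need at least 2 periods")
    C = results.C
    maxes = C.max(axis=0)
    if np.any(maxes == 0):
        raise ValueError("a temporal loading column is identically zero")
    Cn = C / maxes
    rows = []
    for p in range(n_periods):
        sel = period == p
        if not np.any(sel):
            raise ValueError(f"period {p} contains no analysis windows")
        rows.append(Cn[sel].mean(axis=0))
    return pd.DataFrame(
        rows,
        index=[f"REC{p + 1}" for p in range(n_periods)],
        columns=[f"component{k + 1}" for k in range(C.shape[1])],
    )


def repeated_measures_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA by explicit sums of squares.

    ``data`` is (subjects x conditions). The F statistic is the
    between-condition mean square over the subject-by-condition
    residual mean square, with (c-1, (c-1)(n-1)) degrees of freedom.
    Returns (F, p).
    """
    data = np.asarray(data, dtype=float)
    n, c = data.shape
    if n < 2 or c < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = c * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = c - 1
    df_err = (c - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_cond, df_err))
    return float(F), p


def replicability_report(
    results_a: ParafacResults,
    results_b: ParafacResults,
    modes: tuple[str, ...] = ("frequency", "space"),
) -> pd.DataFrame:
    """Session-to-session TCC of matched components, per mode.

    Components of session B are matched to session A by frequency-mode
    congruence; each row reports the TCC and the verdicts at the 0.85
    (highly similar) and 0.95 (nearly identical) thresholds.
    """
    mode_idx = {"frequency": 0, "space": 1, "time": 2}
    perm, _ = match_components(results_a.A, results_b.A)
    rows = []
    for k in range(results_a.K)[: results_b.K]:
        for mode in modes:
            m = mode_idx[mode]
            tcc = tucker_congruence(
                results_a.factors[m][:, k], results_b.factors[m][:, perm[k]]
            )
            rows.append(
                {
                    "component": k + 1,
                    "mode": mode,
                    "tcc": tcc,
                    "highly_similar": tcc > TCC_HIGHLY_SIMILAR,
                    "nearly_identical": tcc > TCC_NEARLY_IDENTICAL,
                }
            )
    return pd.DataFrame(rows)
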