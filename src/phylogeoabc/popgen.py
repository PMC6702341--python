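"""Population-genetic statistics.

Diversity indices (h, Hd, S, pi), the neutrality statistics Tajima's D,
Fu's Fs and Ramos-Onsins & Rozas' R2, mismatch distributions, one-level
AMOVA / Phi_ST, raw and net between-group distances, the Mantel test, and
the per-locus summary-statistic vector consumed by the ABC engine.

Conventions
-----------
* Mean pairwise differences (k-bar) are computed under pairwise deletion
  of gaps and ambiguous bases.
* When an alignment is invariant (S = 0), D, Fs and R2 are reported as
  0.0 rather than undefined, matching the usual tabular reporting for
  monomorphic samples.
* Fu's Fs uses theta-hat = k-bar and the Ewens sampling formula with
  exact unsigned Stirling numbers of the first kind, evaluated in the
  log domain so samples of several hundred sequences do not overflow.
* A singleton (for R2) is an allele carried by exactly one sequence in
  the sample, folded: a column where some residue occurs once.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .seq_data import (
    UNAMBIGUOUS,
    LocusAlignment,
    PopulationMap,
    collapse_haplotypes,
    pairwise_difference_matrix,
)

__all__ = [
    "DiversitySummary",
    "NeutralityResult",
    "MismatchHistogram",
    "AmovaResult",
    "GroupDistanceSummary",
    "SummaryStatVector",
    "diversity_indices",
    "tajimas_d",
    "tajimas_d_from_counts",
    "fus_fs",
    "fus_fs_from_counts",
    "r2_statistic",
    "r2_from_counts",
    "neutrality_p_value",
    "mismatch_distribution",
    "amova_phist",
    "group_distances",
    "net_distance",
    "mantel_test",
    "summary_vector",
    "STAT_NAMES",
]

#: Canonical order of the candidate ABC summary statistics.
STAT_NAMES = ("pi", "ss", "D", "piw", "pib")


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    h: int
    S: int
    Hd: float
    Hd_sd: float
    pi: float          # per site
    pi_sd: float
    k_bar: float       # mean pairwise differences (count)


@dataclass(frozen=True)
class NeutralityResult:
    statistic: str     # "D", "Fs" or "R2"
    value: float
    p_value: float | None = None


@dataclass(frozen=True)
class MismatchHistogram:
    """Relative frequency of each pairwise-difference count."""

    frequencies: dict[int, float]

    def mean(self) -> float:
        return sum(d * f for d, f in self.frequencies.items())


@dataclass(frozen=True)
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Raw/net between-group and within-group mean pairwise differences."""

    within: dict[str, float]                    # group -> pi_X (count units)
    raw: dict[tuple[str, str], float]           # (X, Y) -> d_raw
    net: dict[tuple[str, str], float]           # (X, Y) -> d_raw - (pi_X+pi_Y)/2
    small_groups: tuple[str, ...] = ()          # groups of size < 2 (pi set to 0)


@dataclass(frozen=True)
class SummaryStatVector:
    names: tuple[str, ...]
    values: np.ndarray
    vector_spec: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# core per-alignment quantities


def segregating_sites(aln: LocusAlignment) -> int:
    """Number of columns with at least two distinct unambiguous residues."""
    mat = aln.matrix()
    ok = np.isin(mat, list(UNAMBIGUOUS))
    S = 0
    for j in range(mat.shape[1]):
        col = mat[ok[:, j], j]
        if col.size >= 2 and np.unique(col).size >= 2:
            S += 1
    return S


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    d = pairwise_difference_matrix(aln)
    n = aln.n
    iu = np.triu_indices(n, 1)
    return float(d[iu].mean())


def diversity_indices(aln: LocusAlignment) -> DiversitySummary:
    """Haplotype and nucleotide diversity with Nei's sampling variances.

    Hd = n (1 - sum p_i^2) / (n - 1); pi = k-bar / L.  The Hd variance is
    Nei (1987) eq. 8.12 and the pi variance the standard no-recombination
    sampling variance, both reported as standard deviations.
    """
    if aln.n < 2:
        raise ValueError("diversity indices need n >= 2")
    n = aln.n
    L = aln.length
    haps = collapse_haplotypes(aln)
    p = haps.frequencies()
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    hd = n * (1.0 - sp2) / (n - 1)
    vh = 2.0 / (n * (n - 1)) * (
        2.0 * (n - 2) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    k_bar = mean_pairwise_differences(aln)
    pi = k_bar / L
    vpi = (n + 1) / (3.0 * (n - 1)) * pi / L + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return DiversitySummary(
        n=n,
        h=haps.h,
        S=segregating_sites(aln),
        Hd=hd,
        Hd_sd=math.sqrt(max(vh, 0.0)),
        pi=pi,
        pi_sd=math.sqrt(max(vpi, 0.0)),
        k_bar=k_bar,
    )


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, variance coefficients e1, e2) bundled as needed by D."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d_from_counts(n: int, S: int, k_bar: float) -> float:
    """Tajima's D from sample size, segregating sites and k-bar."""
    if S == 0:
        return 0.0  # monomorphic convention, any n
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        # at n = 3 the variance coefficients vanish identically, and so
        # does the numerator (every biallelic site contributes exactly
        # S/a1 to k-bar): D is 0 by construction
        return 0.0
    return (k_bar - S / a1) / math.sqrt(var)


def tajimas_d(aln: LocusAlignment) -> NeutralityResult:
    S = segregating_sites(aln)
    k = mean_pairwise_differences(aln) if S else 0.0
    return NeutralityResult("D", tajimas_d_from_counts(aln.n, S, k))


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n, from the exact integer recurrence.

    |s(n+1, k)| = |s(n, k-1)| + n |s(n, k)|; computed in exact integer
    arithmetic and converted to logs once, so n of several hundred is
    safe.
    """
    row = [1]  # n = 0
    for m in range(n):
        nxt = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            if v:
                nxt[k + 1] += v
                nxt[k] += m * v
        row = nxt
    return tuple(math.log(v) if v else -math.inf for v in row)


def _ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k) for k = 0..n under the Ewens sampling formula."""
    ls = np.asarray(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_denom = sum(math.log(theta + i) for i in range(n))
    with np.errstate(divide="ignore"):
        return ls + k * math.log(theta) - log_denom


def fus_fs_from_counts(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, observed haplotype count and theta-hat.

    S' = Pr(K >= k_obs) under the Ewens sampling formula with
    theta-hat = k-bar; Fs = ln(S' / (1 - S')).  Both tails are summed in
    the log domain so the logit stays accurate when S' is near 0 or 1.
    """
    if n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    if theta <= 0.0:
        return 0.0  # monomorphic convention
    if k_obs < 1 or k_obs > n:
        raise ValueError("haplotype count outside [1, n]")
    if k_obs == 1:
        raise ValueError(
            "S' = 1 with nonzero diversity: Fs is numerically degenerate"
        )
    lp = _ewens_log_pmf(n, theta)
    log_upper = logsumexp(lp[k_obs:])
    log_lower = logsumexp(lp[1:k_obs])
    return float(log_upper - log_lower)


def fus_fs(aln: LocusAlignment) -> NeutralityResult:
    theta = mean_pairwise_differences(aln)
    k_obs = collapse_haplotypes(aln).h
    return NeutralityResult("Fs", fus_fs_from_counts(aln.n, k_obs, theta))


# ---------------------------------------------------------------------------
# R2 of Ramos-Onsins & Rozas


def _singletons_per_sequence(aln: LocusAlignment) -> np.ndarray:
    """U_i: number of singleton alleles carried by sequence i (folded)."""
    mat = aln.matrix()
    ok = np.isin(mat, list(UNAMBIGUOUS))
    n = aln.n
    U = np.zeros(n, dtype=float)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        valid = ok[:, j]
        residues, counts = np.unique(col[valid], return_counts=True)
        if residues.size < 2:
            continue
        for res, cnt in zip(residues, counts):
            if cnt == 1:
                U[valid & (col == res)] += 1
    return U


def r2_from_counts(n: int, S: int, k_bar: float, U: np.ndarray) -> float:
    if S == 0:
        return 0.0
    return float(math.sqrt(np.mean((U - k_bar / 2.0) ** 2)) / S)


def r2_statistic(aln: LocusAlignment) -> NeutralityResult:
    """R2 = sqrt(mean_i (U_i - k/2)^2) / S; low values signal expansion."""
    if aln.n < 2:
        raise ValueError("R2 needs n >= 2")
    S = segregating_sites(aln)
    if S == 0:
        return NeutralityResult("R2", 0.0)
    k = mean_pairwise_differences(aln)
    U = _singletons_per_sequence(aln)
    return NeutralityResult("R2", r2_from_counts(aln.n, S, k, U))


# ---------------------------------------------------------------------------
# significance by conditional neutral simulation


def neutrality_p_value(
    result: NeutralityResult,
    n: int,
    S: int,
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """One-sided p-value against the constant-size panmictic coalescent.

    Replicates are conditioned on the observed number of segregating
    sites (exactly S mutations dropped on each simulated genealogy).
    For all three statistics the reported tail is Pr(stat <= observed):
    population expansion drives D and Fs negative and R2 toward zero, so
    the low tail is the interesting one throughout.
    """
    from .simulate import _neutral_fixed_s_replicates

    if reps < 100:
        raise ValueError("need at least 100 replicates")
    if S == 0:
        return math.nan
    sims = _neutral_fixed_s_replicates(
        n=n, S=S, reps=reps, statistic=result.statistic, seed=seed
    )
    return float(np.mean(sims <= result.value))


# ---------------------------------------------------------------------------
# mismatch distribution


def mismatch_distribution(aln: LocusAlignment) -> MismatchHistogram:
    """Relative frequency of pairwise-difference counts over all pairs."""
    d = pairwise_difference_matrix(aln)
    iu = np.triu_indices(aln.n, 1)
    vals, counts = np.unique(d[iu], return_counts=True)
    total = counts.sum()
    return MismatchHistogram(
        {int(v): float(c) / total for v, c in zip(vals, counts)}
    )


# ---------------------------------------------------------------------------
# AMOVA / Phi_ST


def _amova_from_distances(
    d: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(sigma2_among, sigma2_within, phi_st) from a difference matrix.

    One-level molecular variance decomposition: the pairwise difference
    counts are used directly as squared Euclidean distances, the
    convention for haplotype data in distance-based AMOVA.
    """
    n = len(labels)
    groups, inverse = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inverse)
    iu = np.triu_indices(n, 1)
    ss_total = d[iu].sum() / n
    ss_within = 0.0
    for g in range(len(groups)):
        idx = np.where(inverse == g)[0]
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_a = len(groups) - 1
    df_w = n - len(groups)
    ms_within = ss_within / df_w if df_w > 0 else 0.0
    n_prime = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ss_among / df_a - ms_within) / n_prime
    sigma_w = ms_within
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else math.nan
    return sigma_a, sigma_w, phi


def amova_phist(
    alns: dict[str, LocusAlignment] | LocusAlignment,
    popmap: PopulationMap,
    permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, AmovaResult] | AmovaResult:
    """One-level AMOVA per locus; Phi_ST = sigma_a^2 / (sigma_a^2 + sigma_w^2).

    The permutation p-value shuffles individuals among groups and counts
    the fraction of permuted Phi_ST at least as large as the observed
    one (with the +1 small-sample correction).
    """
    if isinstance(alns, LocusAlignment):
        return _amova_single(alns, popmap, permutations, seed)
    return {
        name: _amova_single(a, popmap, permutations, seed)
        for name, a in alns.items()
    }


def _amova_single(aln, popmap, permutations, seed) -> AmovaResult:
    popmap.check_covers(aln)
    labels = np.array([popmap.group_of(s) for s in aln.sample_ids])
    if np.unique(labels).size < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    d = pairwise_difference_matrix(aln)
    if not d.any():
        import warnings

        warnings.warn("all sequences identical; Phi_ST undefined")
        return AmovaResult(0.0, 0.0, math.nan, math.nan, math.nan, None)
    sa, sw, phi = _amova_from_distances(d, labels)
    total = sa + sw
    p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(labels)
            _, _, phi_p = _amova_from_distances(d, perm)
            if not math.isnan(phi_p) and phi_p >= phi:
                hits += 1
        p = (hits + 1) / (permutations + 1)
    return AmovaResult(
        sigma_among=sa,
        sigma_within=sw,
        pct_among=100.0 * sa / total,
        pct_within=100.0 * sw / total,
        phi_st=phi,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# between-group distances (raw and net)


def group_distances(
    aln: LocusAlignment, popmap: PopulationMap
) -> GroupDistanceSummary:
    """Within-group pi, raw between-group and net between-group distances.

    d_net(X, Y) = d_raw(X, Y) - (pi_X + pi_Y) / 2, the usual correction
    of between-group divergence for within-group polymorphism.  Groups
    of size < 2 get pi = 0 and are flagged.
    """
    popmap.check_covers(aln)
    labels = np.array([popmap.group_of(s) for s in aln.sample_ids])
    groups = sorted(np.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    d = pairwise_difference_matrix(aln)
    idx = {g: np.where(labels == g)[0] for g in groups}
    within: dict[str, float] = {}
    small: list[str] = []
    for g in groups:
        i = idx[g]
        if i.size < 2:
            within[g] = 0.0
            small.append(g)
        else:
            sub = d[np.ix_(i, i)]
            within[g] = float(sub[np.triu_indices(i.size, 1)].mean())
    raw: dict[tuple[str, str], float] = {}
    net: dict[tuple[str, str], float] = {}
    for gx, gy in itertools.combinations(groups, 2):
        block = d[np.ix_(idx[gx], idx[gy])]
        raw[(gx, gy)] = float(block.mean())
        net[(gx, gy)] = net_distance(raw[(gx, gy)], within[gx], within[gy])
    return GroupDistanceSummary(within, raw, net, tuple(small))


def bonferroni_correct(p_values) -> np.ndarray:
    """Bonferroni adjustment across a family of tests (capped at 1).

    Off by default everywhere: per-population neutrality tests are
    conventionally reported with raw p-values, but the option is here
    for callers who test many groups/loci at once.
    """
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def net_distance(d_raw: float, pi_x: float, pi_y: float) -> float:
    """Net (corrected) between-group distance: d_raw - (pi_x + pi_y)/2."""
    return d_raw - (pi_x + pi_y) / 2.0


# ---------------------------------------------------------------------------
# Mantel test


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; p is the
    fraction of row/column co-permutations of m2 with r_perm >= r_obs
    (one-sided, positive association).  All n! permutations are
    enumerated when there are no more of them than ``permutations``;
    otherwise that many random permutations are sampled.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = m1.shape[0]
    if m1.shape != m2.shape or m1.shape != (n, n) or n < 3:
        raise ValueError("need two square matrices of equal dimension >= 3")
    for m in (m1, m2):
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    iu = np.triu_indices(n, 1)
    x, y = m1[iu], m2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def corr_perm(perm: np.ndarray) -> float:
        return float(np.corrcoef(x, m2[np.ix_(perm, perm)][iu])[0, 1])

    if math.factorial(n) <= permutations:
        perms = list(itertools.permutations(range(n)))
        rs = np.array([corr_perm(np.array(p)) for p in perms])
        p = float(np.mean(rs >= r_obs))
    else:
        rng = np.random.default_rng(seed)
        rs = np.array(
            [corr_perm(rng.permutation(n)) for _ in range(permutations)]
        )
        p = float(np.mean(rs >= r_obs))
    return r_obs, p


# ---------------------------------------------------------------------------
# ABC summary-statistic vector


def _locus_stats_from_alignment(
    aln: LocusAlignment, popmap: PopulationMap, groups: tuple[str, ...]
) -> dict[str, float | dict]:
    """All candidate statistics of one locus (pi-like values per site)."""
    n, L = aln.n, aln.length
    d = pairwise_difference_matrix(aln)
    labels = np.array([popmap.group_of(s) for s in aln.sample_ids])
    iu = np.triu_indices(n, 1)
    k_bar = float(d[iu].mean())
    S = segregating_sites(aln)
    out: dict[str, float | dict] = {
        "pi": k_bar / L,
        "ss": float(S),
        "D": tajimas_d_from_counts(n, S, k_bar),
    }
    idx = {g: np.where(labels == g)[0] for g in groups}
    piw = {}
    for g in groups:
        i = idx[g]
        if i.size < 2:
            piw[g] = 0.0
        else:
            sub = d[np.ix_(i, i)]
            piw[g] = float(sub[np.triu_indices(i.size, 1)].mean()) / L
    pib = {}
    for gx, gy in itertools.combinations(groups, 2):
        pib[(gx, gy)] = float(d[np.ix_(idx[gx], idx[gy])].mean()) / L
    out["piw"] = piw
    out["pib"] = pib
    return out


def locus_stats_from_counts(
    group_counts: np.ndarray, group_sizes: np.ndarray, L: int
) -> dict[str, float | dict]:
    """Candidate statistics from per-group derived-allele counts.

    ``group_counts`` is (G, S_sites): derived copies of each segregating
    site within each group.  This is the fast path for infinite-sites
    simulated loci; it agrees exactly with the alignment path (verified
    in tests) because mean pairwise differences reduce to allele-count
    algebra under two alleles per site.
    """
    group_counts = np.atleast_2d(group_counts)
    group_sizes = np.asarray(group_sizes)
    G = len(group_sizes)
    n = int(group_sizes.sum())
    d = group_counts.sum(axis=0)
    seg = (d > 0) & (d < n)
    d = d[seg]
    gc = group_counts[:, seg]
    S = int(seg.sum())
    npairs = n * (n - 1) / 2.0
    k_bar = float((d * (n - d)).sum() / npairs) if S else 0.0
    out: dict[str, float | dict] = {
        "pi": k_bar / L,
        "ss": float(S),
        "D": tajimas_d_from_counts(n, S, k_bar) if n >= 3 else 0.0,
    }
    piw = {}
    for g in range(G):
        ng = group_sizes[g]
        if ng < 2:
            piw[g] = 0.0
        else:
            dg = gc[g]
            piw[g] = float((dg * (ng - dg)).sum() / (ng * (ng - 1) / 2.0)) / L
    pib = {}
    for gx, gy in itertools.combinations(range(G), 2):
        nx, ny = group_sizes[gx], group_sizes[gy]
        dx, dy = gc[gx], gc[gy]
        pib[(gx, gy)] = float(
            (dx * (ny - dy) + dy * (nx - dx)).sum() / (nx * ny)
        ) / L
    out["piw"] = piw
    out["pib"] = pib
    return out


def _flatten_stats(
    per_locus: dict[str, dict],
    groups: tuple,
    vector_spec: tuple[str, ...],
) -> SummaryStatVector:
    """Deterministic flattening: locus-major, then stat, then group/pair."""
    names: list[str] = []
    values: list[float] = []
    pairs = list(itertools.combinations(groups, 2))
    for locus, stats in per_locus.items():
        for stat in STAT_NAMES:
            if stat not in vector_spec:
                continue
            if stat == "piw":
                for g in groups:
                    names.append(f"{locus}:piw:{g}")
                    values.append(stats["piw"][g])
            elif stat == "pib":
                for gx, gy in pairs:
                    names.append(f"{locus}:pib:{gx}-{gy}")
                    values.append(stats["pib"][(gx, gy)])
            else:
                names.append(f"{locus}:{stat}")
                values.append(stats[stat])
    return SummaryStatVector(
        tuple(names), np.asarray(values, dtype=float), tuple(vector_spec)
    )


def summary_vector(
    dataset: dict[str, LocusAlignment],
    popmap: PopulationMap,
    vector_spec: tuple[str, ...] = STAT_NAMES,
) -> SummaryStatVector:
    """Assemble the ABC summary-statistic vector of a multilocus dataset.

    ``vector_spec`` names 2-5 of {pi, ss, D, piw, pib}; piw expands to one
    value per group and pib to one per group pair; ordering is
    locus-major, then statistic (canonical order), then alphabetical
    group/pair.  Diversity-like entries are per site so loci of
    different lengths are comparable.
    """
    spec = tuple(vector_spec)
    if not spec:
        raise ValueError("empty vector spec")
    unknown = set(spec) - set(STAT_NAMES)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    groups = popmap.groups
    per_locus = {
        name: _locus_stats_from_alignment(aln, popmap, groups)
        for name, aln in dataset.items()
    }
    # alignment path keys piw/pib by group label already
    return _flatten_stats(per_locus, groups, spec)
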