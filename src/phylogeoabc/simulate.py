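"""Hudson-style structured coalescent simulation with infinite-sites
mutation.

Time is measured in units of 4 * Ne_ref * c generations for each locus,
where Ne_ref is the reference (South, ancestral-side) present size of
the draw and c the locus inheritance scale (1 nuclear, 0.25
mitochondrial).  In these units a population of relative size x
coalesces k lineages at rate k(k-1)/x, and the per-locus mutation
intensity theta = 4 * Ne_ref * c * mu * L makes the expected pairwise
diversity of a sample of two equal theta — so the mitochondrial and
nuclear scalings theta_mit = Ne mu L and theta_nuc = 4 Ne mu L fall out
of one conversion path.

Exponential growth is handled by the closed-form time rescaling of the
waiting times; joins move every lineage of the source population into
the sink.  Mutations are Poisson on total branch length and each one
opens a new 0/1 column (infinite sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import ModelSpec, ParameterDraw, PopulationSpec, DemographicEvent

__all__ = [
    "Genealogy",
    "SimulatedLocus",
    "SimulatedDataset",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
]


@dataclass
class Genealogy:
    """A binary coalescent tree over the sampled lineages.

    Nodes 0..n-1 are leaves (time 0); internal nodes follow in
    coalescence order.  ``node_population`` records where each internal
    node's merge happened.
    """

    n: int
    times: np.ndarray            # (2n-1,)
    parent: np.ndarray           # (2n-1,), root has -1
    leaf_populations: tuple[str, ...]
    node_population: tuple[str, ...]

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for node, par in enumerate(self.parent[:-1]):
            ch[par].append(node)
        return ch

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        return self.times[self.parent[:-1]] - self.times[:-1]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.times[self.root])

    def leaves_below(self, node: int, children=None) -> np.ndarray:
        if children is None:
            children = self.children()
        out: list[int] = []
        stack = [node]
        while stack:
            u = stack.pop()
            if u < self.n:
                out.append(u)
            else:
                stack.extend(children[u])
        return np.array(sorted(out), dtype=np.int64)


@dataclass
class SimulatedLocus:
    """Infinite-sites haplotypes of one simulated locus.

    Carries the (n, S) 0/1 genotype matrix and/or the per-group derived
    allele counts; the count representation is enough for every summary
    statistic and is what the reference-table pipeline stores.
    """

    name: str
    length: int
    inheritance_scale: float
    genotypes: np.ndarray | None  # (n, S) uint8, one column per mutation
    leaf_populations: tuple[str, ...]
    _counts: np.ndarray | None = None  # (G, S) derived counts per group

    @property
    def n(self) -> int:
        return len(self.leaf_populations)

    @property
    def n_sites(self) -> int:
        if self.genotypes is not None:
            return self.genotypes.shape[1]
        return self._counts.shape[1]

    def group_counts(self) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
        """(groups, per-group derived counts (G,S), group sizes)."""
        labels = np.asarray(self.leaf_populations)
        groups = tuple(sorted(set(self.leaf_populations)))
        sizes = np.array([(labels == g).sum() for g in groups])
        if self._counts is not None:
            return groups, self._counts, sizes
        counts = np.vstack(
            [self.genotypes[labels == g].sum(axis=0) for g in groups]
        )
        return groups, counts, sizes

    def to_alignment(self, rng=None, sample_prefix: str = "s"):
        """Expand to sequences on a random monomorphic background.

        Each 0/1 column becomes one alignment column at a distinct
        position: ancestral base for 0, a different base for 1.
        Statistics computed on the expansion agree with the 0/1 matrix.
        """
        from .seq_data import LocusAlignment

        if self.genotypes is None:
            raise ValueError(
                f"{self.name}: counts-only locus cannot be expanded"
            )
        if self.n_sites > self.length:
            raise ValueError(
                f"{self.name}: {self.n_sites} mutations exceed locus "
                f"length {self.length}"
            )
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        bases = np.array(list("ACGT"))
        background = rng.choice(bases, size=self.length)
        positions = rng.choice(self.length, size=self.n_sites, replace=False)
        mat = np.tile(background, (self.n, 1))
        for j, pos in enumerate(positions):
            anc = background[pos]
            derived = rng.choice([b for b in "ACGT" if b != anc])
            mat[self.genotypes[:, j] == 1, pos] = derived
        seqs = tuple(
            (f"{sample_prefix}{i:04d}", "".join(row))
            for i, row in enumerate(mat)
        )
        return LocusAlignment(self.name, seqs, self.inheritance_scale)


@dataclass
class SimulatedDataset:
    """One parameter draw plus the loci it generated."""

    model_id: int
    draw: ParameterDraw
    loci: dict[str, SimulatedLocus]

    def summary_vector(self, vector_spec=("pi", "ss", "D", "piw", "pib")):
        from .popgen import locus_stats_from_counts, _flatten_stats

        per_locus = {}
        groups_ref: tuple[str, ...] | None = None
        for name, locus in self.loci.items():
            groups, counts, sizes = locus.group_counts()
            groups_ref = groups
            stats = locus_stats_from_counts(counts, sizes, locus.length)
            # re-key piw/pib from group indices to labels
            stats["piw"] = {groups[i]: v for i, v in stats["piw"].items()}
            stats["pib"] = {
                (groups[i], groups[j]): v
                for (i, j), v in stats["pib"].items()
            }
            per_locus[name] = stats
        return _flatten_stats(per_locus, groups_ref, tuple(vector_spec))

    def to_alignments(self, seed=None):
        """Per-locus alignments plus the matching population map."""
        from .seq_data import PopulationMap

        rng = np.random.default_rng(seed)
        alignments = {}
        assignments: dict[str, tuple[str, str]] = {}
        for name, locus in self.loci.items():
            aln = locus.to_alignment(rng, sample_prefix=f"{name}_")
            alignments[name] = aln
            for sid, pop in zip(aln.sample_ids, locus.leaf_populations):
                assignments[sid] = (pop, pop)
        return alignments, PopulationMap(assignments)


# ---------------------------------------------------------------------------
# genealogy simulation


class _PopState:
    __slots__ = ("x0", "beta", "t0", "lineages", "active")

    def __init__(self, x0: float, beta: float):
        self.x0 = x0          # relative size at reference time t0
        self.beta = beta      # backward decline rate per time unit
        self.t0 = 0.0
        self.lineages: list[int] = []
        self.active = True

    def size_at(self, t: float) -> float:
        return self.x0 * math.exp(-self.beta * (t - self.t0))

    def rebase(self, t: float) -> None:
        self.x0 = self.size_at(t)
        self.t0 = t

    def waiting_time(self, t: float, E: float) -> float:
        """Solve the cumulative-hazard equation for the next coalescence."""
        k = len(self.lineages)
        rate0 = k * (k - 1) / self.size_at(t)
        if self.beta == 0.0:
            return E / rate0
        # integral of rate0 * exp(beta s) ds from 0 to w equals E
        arg = 1.0 + self.beta * E / rate0
        return math.log(arg) / self.beta


def simulate_genealogy(
    model: ModelSpec,
    draw: ParameterDraw,
    samples: dict[str, int],
    inheritance_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> Genealogy:
    """Simulate one genealogy under a demographic model.

    ``samples`` maps population name to sample size; leaves are laid out
    in alphabetical population order.  Population relative sizes are
    Ne_pop / Ne_ref with Ne_ref the draw's South present size; the time
    unit is 4 * Ne_ref * c generations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_total = sum(samples.values())
    pops_spec, events = model.concrete(draw)
    g = draw.values["gen_time"]
    ne_ref = draw.values["ne_south"]
    unit_gens = 4.0 * ne_ref * inheritance_scale

    def to_units(t_years: float) -> float:
        return t_years / (g * unit_gens)

    states: dict[str, _PopState] = {}
    for p in pops_spec:
        states[p.name] = _PopState(p.ne / ne_ref, p.alpha * unit_gens)

    leaf_pops: list[str] = []
    node = 0
    for pop in sorted(samples):
        if pop not in states:
            raise ValueError(f"no population {pop!r} in model {model.model_id}")
        k = samples[pop]
        states[pop].lineages.extend(range(node, node + k))
        leaf_pops.extend([pop] * k)
        node += k
    if n_total < 1:
        raise ValueError("need at least one sampled lineage")

    times = np.zeros(2 * n_total - 1)
    parent = np.full(2 * n_total - 1, -1, dtype=np.int64)
    node_pop: list[str] = [""] * (n_total - 1)
    next_node = n_total
    t = 0.0
    ev = [(to_units(e.time), e) for e in events]
    ev_i = 0
    remaining = n_total
    while remaining > 1:
        # candidate coalescence across populations with >= 2 lineages
        best_w = math.inf
        best_pop: _PopState | None = None
        best_name = ""
        for name, st in states.items():
            if st.active and len(st.lineages) >= 2:
                w = st.waiting_time(t, rng.exponential())
                if w < best_w:
                    best_w, best_pop, best_name = w, st, name
        t_next_event = ev[ev_i][0] if ev_i < len(ev) else math.inf
        if t + best_w >= t_next_event:
            # advance to the event and apply it
            t = t_next_event
            e = ev[ev_i][1]
            ev_i += 1
            st = states[e.pop]
            if e.kind == "join":
                states[e.sink].lineages.extend(st.lineages)
                st.lineages = []
                st.active = False
            elif e.kind == "size_change":
                st.rebase(t)
                st.x0 = e.size / ne_ref
            else:  # growth_change
                st.rebase(t)
                st.beta = e.alpha * unit_gens
            continue
        if best_pop is None:
            raise RuntimeError(
                "lineages stranded with no further events or coalescence"
            )
        t += best_w
        lin = best_pop.lineages
        k = len(lin)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        times[next_node] = t
        parent[a] = parent[b] = next_node
        node_pop[next_node - n_total] = best_name
        # O(1) removal: replace one member with the merged node, swap
        # the other with the tail
        lin[i] = next_node
        lin[j] = lin[-1]
        lin.pop()
        next_node += 1
        remaining -= 1

    return Genealogy(
        n=n_total,
        times=times,
        parent=parent,
        leaf_populations=tuple(leaf_pops),
        node_population=tuple(node_pop),
    )


# ---------------------------------------------------------------------------
# mutation dropping


def drop_mutations(
    genealogy: Genealogy,
    theta: float,
    rng: np.random.Generator | int | None = None,
    locus_name: str = "locus",
    length: int = 1000,
    inheritance_scale: float = 1.0,
    fixed_count: int | None = None,
    counts_only: bool = False,
) -> SimulatedLocus:
    """Drop infinite-sites mutations on a genealogy.

    The mutation count is Poisson(theta * total branch length) unless
    ``fixed_count`` conditions on an exact number of segregating sites;
    each mutation lands on a branch with probability proportional to its
    length and is carried by that branch's descendant leaves.

    With ``counts_only`` the genotype matrix is skipped and only
    per-group derived-allele counts are stored, computed in one
    postorder leaf-count pass — O(n + S) instead of one subtree walk
    per mutation.  The random stream is identical in both modes, so the
    same seed yields the same mutations either way.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = genealogy.n
    if n == 1:
        return SimulatedLocus(
            locus_name, length, inheritance_scale,
            np.zeros((1, 0), dtype=np.uint8), genealogy.leaf_populations,
        )
    lengths = genealogy.branch_lengths()
    total = lengths.sum()
    if fixed_count is not None:
        n_mut = int(fixed_count)
    else:
        n_mut = int(rng.poisson(theta * total))
    if n_mut and total > 0:
        branches = rng.choice(len(lengths), size=n_mut, p=lengths / total)
    else:
        branches = np.zeros(0, dtype=np.int64)
        n_mut = 0
    if counts_only:
        labels = np.asarray(genealogy.leaf_populations)
        groups = sorted(set(genealogy.leaf_populations))
        # leaves below each node, per group: children always have a
        # smaller index than their parent, so one forward pass suffices
        below = np.zeros((2 * n - 1, len(groups)), dtype=np.int64)
        for gi, g in enumerate(groups):
            below[:n, gi] = labels == g
        parent = genealogy.parent
        for node in range(2 * n - 2):
            below[parent[node]] += below[node]
        counts = below[branches].T.copy()  # (G, S)
        return SimulatedLocus(
            locus_name, length, inheritance_scale, None,
            genealogy.leaf_populations, _counts=counts,
        )
    geno = np.zeros((n, n_mut), dtype=np.uint8)
    if n_mut:
        children = genealogy.children()
        for col, br in enumerate(branches):
            leaves = genealogy.leaves_below(int(br), children)
            geno[leaves, col] = 1
    return SimulatedLocus(
        locus_name, length, inheritance_scale, geno,
        genealogy.leaf_populations,
    )


# ---------------------------------------------------------------------------
# multilocus datasets


def simulate_dataset(
    model: ModelSpec,
    draw: ParameterDraw,
    design,
    seed: int | np.random.SeedSequence | None = None,
    counts_only: bool = False,
) -> SimulatedDataset:
    """Simulate all loci of a study design under one parameter draw.

    Each locus gets an independent genealogy (own child seed) with its
    inheritance scaling and per-locus theta; the draw is shared.
    """
    loci = list(design.loci)
    if not loci:
        raise ValueError("design lists no loci")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    out: dict[str, SimulatedLocus] = {}
    for locus, child in zip(loci, ss.spawn(len(loci))):
        rng = np.random.default_rng(child)
        if f"mu_{locus.name}" not in draw.values:
            raise ValueError(
                f"draw has no mutation rate for locus {locus.name!r}"
            )
        gen = simulate_genealogy(
            model, draw, dict(locus.samples), locus.inheritance_scale, rng
        )
        theta = draw.theta(locus.name, locus.length, locus.inheritance_scale)
        out[locus.name] = drop_mutations(
            gen, theta, rng, locus.name, locus.length,
            locus.inheritance_scale, counts_only=counts_only,
        )
    return SimulatedDataset(model.model_id, draw, out)


# ---------------------------------------------------------------------------
# fixed-S neutral replicates for significance testing


def _panmictic_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Constant-size single-population coalescent (Kingman)."""
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    lineages = list(range(n))
    t = 0.0
    nxt = n
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential() / (k * (k - 1))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for idx in sorted((i, j), reverse=True):
            lineages.pop(idx)
        times[nxt] = t
        parent[a] = parent[b] = nxt
        lineages.append(nxt)
        nxt += 1
    pop = ("pop",) * n
    return Genealogy(n, times, parent, pop, ("pop",) * (n - 1))


def _neutral_fixed_s_replicates(
    n: int, S: int, reps: int, statistic: str, seed=None
) -> np.ndarray:
    """Null distribution of D, Fs or R2 conditioned on n and S."""
    from .popgen import (
        fus_fs_from_counts,
        r2_from_counts,
        tajimas_d_from_counts,
    )

    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    npairs = n * (n - 1) / 2.0
    for r in range(reps):
        gen = _panmictic_genealogy(n, rng)
        locus = drop_mutations(gen, 0.0, rng, fixed_count=S)
        geno = locus.genotypes
        d = geno.sum(axis=0)
        seg = (d > 0) & (d < n)
        dcounts = d[seg]
        k_bar = float((dcounts * (n - dcounts)).sum() / npairs)
        s_obs = int(seg.sum())
        if statistic == "D":
            out[r] = tajimas_d_from_counts(n, s_obs, k_bar)
        elif statistic == "Fs":
            if s_obs == 0:
                out[r] = 0.0
            else:
                k_hap = np.unique(geno, axis=0).shape[0]
                out[r] = (
                    0.0 if k_hap == 1
                    else fus_fs_from_counts(n, k_hap, k_bar)
                )
        elif statistic == "R2":
            U = np.zeros(n)
            for col in np.where(seg)[0]:
                c = d[col]
                if c == 1:
                    U[geno[:, col] == 1] += 1
                elif c == n - 1:
                    U[geno[:, col] == 0] += 1
            out[r] = r2_from_counts(n, s_obs, k_bar, U)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return out
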