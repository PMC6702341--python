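"""Alignment and population-map containers.

Every downstream statistic works from two primitives defined here: the
haplotype table of a locus alignment and the matrix of pairwise sequence
differences.  Gaps (``-``) and ambiguity codes are excluded pair-by-pair
(pairwise deletion) when counting differences, and a column counts as
polymorphic only if it carries two or more distinct unambiguous residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "LocusAlignment",
    "PopulationMap",
    "HaplotypeTable",
    "read_alignment",
    "write_alignment",
    "read_population_map",
    "collapse_haplotypes",
    "pairwise_difference_matrix",
]

#: Residues that take part in a pairwise comparison.  Everything else
#: (gaps, N, other IUPAC ambiguity codes) is treated as missing.
UNAMBIGUOUS = frozenset("ACGT")

#: Characters accepted on input: unambiguous bases, gap, and the IUPAC
#: ambiguity alphabet.
IUPAC_OK = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for ragged alignments, bad residues, or empty input."""


@dataclass(frozen=True)
class LocusAlignment:
    """One locus worth of aligned haplotype sequences.

    Parameters
    ----------
    locus_name:
        Label for the locus (e.g. ``"16S"``).
    sequences:
        Ordered ``(sample_id, residues)`` pairs; residues are upper-case
        strings over the IUPAC alphabet plus ``-``.
    inheritance_scale:
        Relative effective copy number of the locus: 1.0 for autosomal
        nuclear loci, 0.25 for maternally inherited mitochondrial loci.
    """

    locus_name: str
    sequences: tuple[tuple[str, str], ...]
    inheritance_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentError(f"{self.locus_name}: zero-length sequences")
        ids = [sid for sid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"{self.locus_name}: duplicate sample ids")
        if self.inheritance_scale not in (0.25, 1.0):
            raise ValueError("inheritance_scale must be 0.25 or 1.0")
        bad = {c for _, s in self.sequences for c in s} - IUPAC_OK
        if bad:
            raise AlignmentError(
                f"{self.locus_name}: non-IUPAC residues {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.sequences)

    def matrix(self) -> np.ndarray:
        """Residues as an (n, L) array of single-byte strings."""
        return np.array(
            [list(s) for _, s in self.sequences], dtype="U1"
        )

    def subset(self, sample_ids) -> "LocusAlignment":
        """Restrict to the given samples, preserving alignment order."""
        wanted = set(sample_ids)
        seqs = tuple(p for p in self.sequences if p[0] in wanted)
        return LocusAlignment(self.locus_name, seqs, self.inheritance_scale)


@dataclass(frozen=True)
class PopulationMap:
    """Sample-to-group/locality assignment with optional coordinates."""

    assignments: dict[str, tuple[str, str]]  # sample_id -> (group, locality)
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("population map is empty")

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.assignments.values()}))

    def samples_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(
            sid for sid, (g, _) in self.assignments.items() if g == group
        )

    def check_covers(self, aln: LocusAlignment) -> None:
        missing = set(aln.sample_ids) - set(self.assignments)
        if missing:
            raise ValueError(
                f"samples without population assignment: {sorted(missing)[:5]}"
            )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences of an alignment with their frequencies."""

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    membership: dict[str, int]  # sample_id -> haplotype index

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(self.counts)

    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n


def read_alignment(
    path, locus_name: str | None = None, inheritance_scale: float = 1.0
) -> LocusAlignment:
    """Read a multi-FASTA alignment into a :class:`LocusAlignment`.

    Sequences are upper-cased and validated to equal length and the IUPAC
    alphabet; record ids become sample ids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    name = locus_name if locus_name is not None else path.stem
    seqs = tuple((r.id, str(r.seq).upper()) for r in records)
    return LocusAlignment(name, seqs, inheritance_scale)


def write_alignment(aln: LocusAlignment, path) -> None:
    """Write an alignment as unwrapped FASTA (byte-stable round trip)."""
    with open(path, "w") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")


def read_population_map(path) -> PopulationMap:
    """Read a TSV ``sample_id  group  locality [lat lon]`` population map."""
    assignments: dict[str, tuple[str, str]] = {}
    coords: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "group"]:
            raise ValueError(
                "population map must start with 'sample_id<TAB>group'"
            )
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid, group = parts[0], parts[1]
            locality = parts[2] if len(parts) > 2 else group
            assignments[sid] = (group, locality)
            if len(parts) >= 5:
                coords[locality] = (float(parts[3]), float(parts[4]))
    return PopulationMap(assignments, coords)


def write_population_map(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tlocality\n")
        for sid, (group, loc) in popmap.assignments.items():
            fh.write(f"{sid}\t{group}\t{loc}\n")


def collapse_haplotypes(aln: LocusAlignment) -> HaplotypeTable:
    """Collapse an alignment to its distinct sequences.

    Identical residue strings (exact match, including gaps/ambiguities)
    share a haplotype; counts sum to the sample size.
    """
    index: dict[str, int] = {}
    counts: list[int] = []
    membership: dict[str, int] = {}
    for sid, seq in aln.sequences:
        if seq not in index:
            index[seq] = len(index)
            counts.append(0)
        counts[index[seq]] += 1
        membership[sid] = index[seq]
    haps = tuple(sorted(index, key=index.get))
    return HaplotypeTable(haps, tuple(counts), membership)


def pairwise_difference_matrix(aln: LocusAlignment) -> np.ndarray:
    """Count pairwise sequence differences under pairwise deletion.

    Entry (i, j) is the number of columns where sequences i and j both
    carry an unambiguous base (A/C/G/T) and those bases differ.  The
    matrix is symmetric with a zero diagonal.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = aln.matrix()
    ok = np.isin(mat, list(UNAMBIGUOUS))
    n = aln.n
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        counts = diff.sum(axis=1)
        out[i, i + 1 :] = counts
        out[i + 1 :, i] = counts
    return out
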