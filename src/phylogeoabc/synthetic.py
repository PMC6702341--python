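"""Study-like synthetic datasets and small worked-example fixtures.

The default study design mirrors the empirical sampling: four loci —
mitochondrial 16S (1035 bp) and ND2 (813 bp), nuclear SiaH (361 bp) and
Rhod (378 bp, both phased) — sampled from three geographic groups with
the per-locus group sizes of the source tables (16S 129/19/3,
ND2 131/35/2, SiaH 260/46/4, Rhod 292/82/4).

``make_worked_examples`` builds the four tiny western-group alignments
whose diversity and neutrality statistics are pinned down exactly by
their printed sample configurations (n, h, S, Hd); they anchor the
statistics implementations to hand-checkable values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import GROUPS, NORTH, SOUTH, WEST, ModelSpec, ParameterDraw, \
    PriorSet, build_model_catalog, draw_parameters
from .seq_data import LocusAlignment, PopulationMap, write_alignment, \
    write_population_map
from .simulate import SimulatedDataset, simulate_dataset

__all__ = [
    "LocusDesign",
    "StudyDesign",
    "default_study_design",
    "generate_study_like_dataset",
    "make_worked_examples",
]


@dataclass(frozen=True)
class LocusDesign:
    name: str
    length: int
    inheritance_scale: float
    samples: dict[str, int]  # group -> sample size

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if any(v <= 0 for v in self.samples.values()):
            raise ValueError(f"{self.name}: sample counts must be positive")


@dataclass(frozen=True)
class StudyDesign:
    loci: tuple[LocusDesign, ...]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for locus in self.loci:
            for g in locus.samples:
                if g not in seen:
                    seen.append(g)
        return tuple(sorted(seen))


def default_study_design() -> StudyDesign:
    """The empirical four-locus, three-group sampling design."""
    return StudyDesign((
        LocusDesign("16S", 1035, 0.25, {NORTH: 129, SOUTH: 19, WEST: 3}),
        LocusDesign("ND2", 813, 0.25, {NORTH: 131, SOUTH: 35, WEST: 2}),
        LocusDesign("SiaH", 361, 1.0, {NORTH: 260, SOUTH: 46, WEST: 4}),
        LocusDesign("Rhod", 378, 1.0, {NORTH: 292, SOUTH: 82, WEST: 4}),
    ))


def generate_study_like_dataset(
    model_id: int,
    truth: ParameterDraw | str = "draw",
    design: StudyDesign | None = None,
    seed: int | None = None,
    priors: PriorSet | None = None,
    out_dir=None,
) -> tuple[SimulatedDataset, ParameterDraw]:
    """Simulate one dataset of the study design under a known model.

    ``truth`` is either an explicit :class:`ParameterDraw` or "draw" to
    sample one from the priors.  With ``out_dir`` set, per-locus FASTA,
    the population map and a truth JSON (model id + parameter values)
    are written for recovery experiments.
    """
    if design is None:
        design = default_study_design()
    if priors is None:
        priors = PriorSet()
    catalog = {m.model_id: m for m in build_model_catalog()}
    if model_id not in catalog:
        raise ValueError(f"unknown model id {model_id}")
    model = catalog[model_id]
    ss = np.random.SeedSequence(seed)
    draw_ss, sim_ss, expand_ss = ss.spawn(3)
    if truth == "draw":
        truth = draw_parameters(model, priors, np.random.default_rng(draw_ss))
    elif not isinstance(truth, ParameterDraw):
        raise ValueError("truth must be a ParameterDraw or 'draw'")
    dataset = simulate_dataset(model, truth, design, sim_ss)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        alignments, popmap = dataset.to_alignments(expand_ss)
        for name, aln in alignments.items():
            write_alignment(aln, out_dir / f"{name}.fasta")
        write_population_map(popmap, out_dir / "popmap.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(
                {"model_id": model_id, "values": truth.values}, fh, indent=1
            )
    return dataset, truth


# ---------------------------------------------------------------------------
# worked examples


def _background(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, pos: int, base: str) -> str:
    if seq[pos] == base:
        base = "A" if base != "A" else "C"
    return seq[:pos] + base + seq[pos + 1:]


def make_worked_examples() -> dict[str, dict]:
    """The four western-group fixture alignments with expected values.

    (a) 16S: 3 sequences, 1035 bp, two singleton sites on different
        sequences (h=3, S=2, Hd=1);
    (b) SiaH: 4 sequences, 361 bp, one singleton site (h=2 at 3/1);
    (c) Rhod: 4 sequences, 378 bp, one site at derived count 2 (h=2 at
        2/2);
    (d) ND2: 2 identical sequences, 813 bp (monomorphic).

    Backgrounds are seeded so the FASTA bytes are stable.  Each entry
    carries the alignment plus a manifest of the statistics its
    configuration forces.
    """
    # (a) two singletons on different sequences
    bg = _background(1035, seed=1601)
    s1 = _mutate(bg, 100, "T")
    s2 = _mutate(bg, 500, "G")
    aln_16s = LocusAlignment(
        "16S", (("W1", s1), ("W2", s2), ("W3", bg)), 0.25
    )

    # (b) one singleton site
    bg = _background(361, seed=1602)
    aln_siah = LocusAlignment(
        "SiaH",
        (("W1", _mutate(bg, 50, "T")), ("W2", bg), ("W3", bg), ("W4", bg)),
        1.0,
    )

    # (c) one site, derived allele carried by two sequences
    bg = _background(378, seed=1603)
    alt = _mutate(bg, 200, "T")
    aln_rhod = LocusAlignment(
        "Rhod", (("W1", alt), ("W2", alt), ("W3", bg), ("W4", bg)), 1.0
    )

    # (d) identical pair
    bg = _background(813, seed=1604)
    aln_nd2 = LocusAlignment("ND2", (("W1", bg), ("W2", bg)), 0.25)

    return {
        "west_16S": {
            "alignment": aln_16s,
            "expected": {
                "n": 3, "h": 3, "S": 2, "Hd": 1.0, "k_bar": 4.0 / 3.0,
                "D": 0.00, "Fs": -1.22, "R2": 0.24,
                "mismatch": {1: 2.0 / 3.0, 2: 1.0 / 3.0},
            },
        },
        "west_SiaH": {
            "alignment": aln_siah,
            "expected": {
                "n": 4, "h": 2, "S": 1, "Hd": 0.5, "k_bar": 0.5,
                "D": -0.61, "Fs": 0.17, "R2": 0.43,
            },
        },
        "west_Rhod": {
            "alignment": aln_rhod,
            "expected": {
                "n": 4, "h": 2, "S": 1, "Hd": 2.0 / 3.0, "k_bar": 2.0 / 3.0,
                "D": 1.63, "Fs": 0.54, "R2": 0.33,
            },
        },
        "west_ND2": {
            "alignment": aln_nd2,
            "expected": {
                "n": 2, "h": 1, "S": 0, "Hd": 0.0, "k_bar": 0.0,
                "D": 0.00, "Fs": 0.00, "R2": 0.00,
            },
        },
    }
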