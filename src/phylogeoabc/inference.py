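"""Model/Results interface for hierarchical ABC model choice.

:class:`DemographicModelChoice` is the model object: observed data (or
their summary statistics), the six-model catalog, priors and the
sampling design.  Its :meth:`~DemographicModelChoice.fit` simulates a
reference table (or reuses one), runs the two-stage rejection
comparison, and returns a :class:`ModelChoiceResults` carrying the
posterior probabilities, the Bayes factor and validation methods
(cross-validation, goodness of fit), with a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abc as _abc
from .models import ModelSpec, PriorSet, build_model_catalog
from .popgen import STAT_NAMES, SummaryStatVector, summary_vector
from .seq_data import LocusAlignment, PopulationMap

__all__ = ["DemographicModelChoice", "ModelChoiceResults"]

#: The summary-statistic subset used for model choice by default: the
#: vector that the POD sweep selects on this design (segregating sites,
#: Tajima's D, between-group diversity).
DEFAULT_VECTOR = ("ss", "D", "pib")


class DemographicModelChoice:
    """ABC model choice for the riverine-barrier vs refugia catalog.

    Parameters
    ----------
    observed:
        Observed summary statistics (:class:`SummaryStatVector`) on the
        full stat set, or None when only simulation studies are run.
    design:
        :class:`~phylogeoabc.synthetic.StudyDesign`; defaults to the
        empirical four-locus design.
    priors:
        Shared :class:`PriorSet` or per-model mapping.
    vector_spec:
        Statistic subset used for the distances (default ss, D, pib).
    """

    def __init__(
        self,
        observed: SummaryStatVector | None = None,
        design=None,
        priors: PriorSet | dict[int, PriorSet] | None = None,
        catalog: tuple[ModelSpec, ...] | None = None,
        vector_spec: tuple[str, ...] = DEFAULT_VECTOR,
    ):
        from .synthetic import default_study_design

        self.observed = observed
        self.design = design if design is not None else default_study_design()
        self.priors = priors if priors is not None else PriorSet()
        self.catalog = catalog if catalog is not None else build_model_catalog()
        self.vector_spec = tuple(vector_spec)
        self.reference_table: _abc.ReferenceTable | None = None

    @classmethod
    def from_alignments(
        cls,
        alignments: dict[str, LocusAlignment],
        popmap: PopulationMap,
        priors=None,
        vector_spec: tuple[str, ...] = DEFAULT_VECTOR,
    ) -> "DemographicModelChoice":
        """Build the model from observed per-locus alignments.

        The simulation design (locus lengths, inheritance scales and
        per-group sample sizes) is read off the alignments and the
        population map, so simulations match the data dimensions.
        """
        from .synthetic import LocusDesign, StudyDesign

        loci = []
        for name, aln in alignments.items():
            popmap.check_covers(aln)
            counts: dict[str, int] = {}
            for sid in aln.sample_ids:
                g = popmap.group_of(sid)
                counts[g] = counts.get(g, 0) + 1
            loci.append(
                LocusDesign(name, aln.length, aln.inheritance_scale, counts)
            )
        design = StudyDesign(tuple(loci))
        observed = summary_vector(alignments, popmap, STAT_NAMES)
        return cls(observed, design, priors, vector_spec=vector_spec)

    # -- simulation ----------------------------------------------------

    def simulate_reference(
        self, n_sims: int, seed: int | None = None, vector_spec=STAT_NAMES
    ) -> _abc.ReferenceTable:
        """Build (and cache) a reference table of n_sims rows per model."""
        self.reference_table = _abc.build_reference_table(
            self.catalog, self.priors, self.design, n_sims,
            tuple(vector_spec), seed,
        )
        return self.reference_table

    def select_vector(
        self, candidates=None, pods_per_model: int = 10,
        tolerance: float = 0.01, seed: int | None = None,
    ):
        """POD sweep over candidate stat subsets on the cached table."""
        if self.reference_table is None:
            raise ValueError("simulate_reference() first")
        best, report = _abc.select_stat_vector(
            self.reference_table, candidates, pods_per_model, tolerance, seed
        )
        self.vector_spec = best
        return best, report

    def restrict_priors(self, tolerance=0.01, quantiles=(0.025, 0.975)):
        """Per-model prior restriction from the rows retained against
        the observed data (the preliminary-round narrowing step)."""
        from .models import restrict_priors

        if self.reference_table is None or self.observed is None:
            raise ValueError("needs a reference table and observed data")
        table = self.reference_table.subset_stats(self.vector_spec)
        restricted: dict[int, PriorSet] = {}
        base = self.priors
        for model in self.catalog:
            sub = table.subset_rows(table.model_ids == model.model_id)
            choice = _abc.abc_model_choice(sub, self.observed, tolerance)
            retained = sub.params.iloc[choice.retained_idx]
            pri = base[model.model_id] if isinstance(base, dict) else base
            restricted[model.model_id] = restrict_priors(
                pri, retained, quantiles, scenario=model.scenario
            )
        self.priors = restricted
        return restricted

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        n_sims: int = 5000,
        tolerance: float = 0.01,
        seed: int | None = None,
        method: str = "rejection",
        observed: SummaryStatVector | None = None,
        table: _abc.ReferenceTable | None = None,
    ) -> "ModelChoiceResults":
        """Run the hierarchical comparison against the observed data.

        Reuses ``table`` (or the cached reference table) when given;
        otherwise simulates ``n_sims`` rows per model first.
        """
        obs = observed if observed is not None else self.observed
        if obs is None:
            raise ValueError("no observed data to fit against")
        if table is None:
            table = self.reference_table
        if table is None:
            table = self.simulate_reference(n_sims, seed)
        sub = table.subset_stats(self.vector_spec)
        hier = _abc.hierarchical_comparison(sub, obs, tolerance, method, seed)
        return ModelChoiceResults(
            model=self, table=table, observed=obs, tolerance=tolerance,
            method=method, hierarchy=hier, seed=seed,
        )


@dataclass
class ModelChoiceResults:
    """Fitted hierarchical ABC comparison."""

    model: DemographicModelChoice
    table: _abc.ReferenceTable
    observed: SummaryStatVector
    tolerance: float
    method: str
    hierarchy: _abc.HierarchicalChoice
    seed: int | None = None

    @property
    def best_model(self) -> int:
        return self.hierarchy.overall

    @property
    def bayes_factor(self) -> float:
        return self.hierarchy.bayes_factor

    @property
    def posteriors(self) -> pd.DataFrame:
        """Within- and among-scenario posteriors, one row per model."""
        rows = []
        for scen, posts in sorted(self.hierarchy.within.items()):
            for mid, p in sorted(posts.items()):
                rows.append({
                    "scenario": scen,
                    "model": mid,
                    "within_scenario": p,
                    "among_scenarios": self.hierarchy.among.get(mid, np.nan),
                })
        return pd.DataFrame(rows)

    def cross_validate(
        self, pods_total: int = 100, seed: int | None = None
    ) -> pd.DataFrame:
        sub = self.table.subset_stats(self.model.vector_spec)
        return _abc.cross_validate(sub, pods_total, self.tolerance, seed)

    def goodness_of_fit(self, level: float = 95.0) -> _abc.GofReport:
        sub = self.table.subset_stats(self.model.vector_spec)
        return _abc.goodness_of_fit(
            sub, self.observed, self.tolerance,
            model_id=self.best_model, level=level,
        )

    def summary(self) -> str:
        """Two-stage posterior table with the Bayes factor."""
        h = self.hierarchy
        lines = [
            "Hierarchical ABC model choice "
            f"(tolerance {self.tolerance:g}, {self.method})",
            f"{'Scenario':>8} {'Model':>6} {'Within':>9} {'Among':>9}",
        ]
        for scen, posts in sorted(h.within.items()):
            for mid, p in sorted(posts.items()):
                among = h.among.get(mid)
                among_s = f"{among:9.4f}" if among is not None else f"{'-':>9}"
                star = "*" if mid == h.overall else " "
                lines.append(f"{scen:>8} {mid:>6} {p:9.4f} {among_s}{star}")
        bf = h.bayes_factor
        bf_s = f"{bf:.4f}" if np.isfinite(bf) else "inf"
        lines.append(
            f"Overall winner: model {h.overall} (Bayes factor {bf_s})"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ModelChoiceResults best={self.best_model} "
            f"BF={self.bayes_factor:.3g}>"
        )
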