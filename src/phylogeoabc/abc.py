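"""Rejection ABC model choice over reference tables.

The reference table couples parameter draws with summary-statistic
vectors simulated per model.  Distances are Euclidean on statistics
normalized by their pooled median absolute deviation (MAD), the common
ABC convention; the closest ``tolerance`` fraction of rows is retained
and per-model posterior probabilities are the models' shares of the
retained rows.  An optional single-hidden-layer classifier refit on the
retained rows ("neural network" adjustment) is available; plain
rejection is the default because it is exactly reproducible.

Model comparison is hierarchical: first within each scenario, then the
two scenario winners head-to-head, reported with a Bayes factor.
Validation uses pseudo-observed datasets (PODs): held-out rows of known
origin classified against the rest of the table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelSpec, PriorSet, draw_parameters
from .simulate import simulate_dataset

__all__ = [
    "ReferenceTable",
    "AbcModelChoice",
    "HierarchicalChoice",
    "GofReport",
    "build_reference_table",
    "select_stat_vector",
    "abc_model_choice",
    "hierarchical_comparison",
    "cross_validate",
    "goodness_of_fit",
]

_MIN_RETAINED = 10


@dataclass
class ReferenceTable:
    """Parameter draws and summary statistics, one row per simulation."""

    params: pd.DataFrame          # includes "model_id"
    stats: pd.DataFrame
    scenarios: dict[int, int]     # model_id -> scenario
    norm: pd.Series = field(default=None)  # per-stat MAD scale

    def __post_init__(self) -> None:
        if len(self.params) != len(self.stats):
            raise ValueError("params and stats row counts differ")
        if self.norm is None:
            self.norm = mad_scale(self.stats)

    def __len__(self) -> int:
        return len(self.stats)

    @property
    def model_ids(self) -> np.ndarray:
        return self.params["model_id"].to_numpy()

    def subset_stats(self, stat_subset: tuple[str, ...]) -> "ReferenceTable":
        """Keep only columns whose statistic kind is in ``stat_subset``.

        Column names are ``locus:stat`` or ``locus:stat:group``.
        """
        cols = [
            c for c in self.stats.columns
            if c.split(":")[1] in stat_subset
        ]
        if not cols:
            raise ValueError(f"no columns match stats {stat_subset}")
        return ReferenceTable(
            self.params, self.stats[cols], self.scenarios,
            norm=self.norm[cols],
        )

    def subset_rows(self, mask: np.ndarray) -> "ReferenceTable":
        return ReferenceTable(
            self.params[mask].reset_index(drop=True),
            self.stats[mask].reset_index(drop=True),
            self.scenarios,
            norm=self.norm,  # keep pooled normalization
        )

    def to_tsv(self, path) -> None:
        pd.concat([self.params, self.stats], axis=1).to_csv(
            path, sep="\t", index=False
        )


def mad_scale(stats: pd.DataFrame) -> pd.Series:
    """Per-statistic MAD with fallbacks (SD, then 1) for degenerate
    columns, so constant statistics do not divide by zero."""
    x = stats.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    sd = x.std(axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return pd.Series(scale, index=stats.columns)


@dataclass(frozen=True)
class AbcModelChoice:
    tolerance: float
    retained_idx: np.ndarray
    posteriors: dict[int, float]
    bayes_factors: dict[int, float]   # best vs each other model
    method: str

    @property
    def best_model(self) -> int:
        return max(self.posteriors, key=self.posteriors.get)


@dataclass(frozen=True)
class HierarchicalChoice:
    within: dict[int, dict[int, float]]   # scenario -> model -> posterior
    winners: dict[int, int]               # scenario -> winning model
    among: dict[int, float]               # winner model -> posterior
    bayes_factor: float
    overall: int


@dataclass(frozen=True)
class GofReport:
    projected: np.ndarray        # retained rows in PC space
    observed_projection: np.ndarray
    explained_variance: np.ndarray
    percentile: float            # Mahalanobis percentile of the observed
    passed: bool

    def plot(self, ax=None):
        """Scatter the retained simulations and the observed point on
        the first two principal components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            self.projected[:, 0], self.projected[:, 1],
            s=8, alpha=0.4, label="retained simulations",
        )
        ax.scatter(
            [self.observed_projection[0]], [self.observed_projection[1]],
            marker="*", s=160, color="crimson", label="observed",
        )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# reference-table construction


def build_reference_table(
    models: tuple[ModelSpec, ...],
    priors: PriorSet | dict[int, PriorSet],
    design,
    n_sims: int,
    vector_spec: tuple[str, ...] = ("pi", "ss", "D", "piw", "pib"),
    seed: int | None = None,
    max_retries: int = 3,
) -> ReferenceTable:
    """Simulate ``n_sims`` rows per model: draw, simulate, summarize.

    ``priors`` may be one shared PriorSet or a per-model mapping (as
    produced by prior restriction).  Seeding is hierarchical, so any
    (model, row) pair reproduces independently of the others.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    root = np.random.SeedSequence(seed)
    model_seeds = root.spawn(len(models))
    param_rows: list[dict] = []
    stat_rows: list[np.ndarray] = []
    stat_names: tuple[str, ...] | None = None
    for model, mseed in zip(models, model_seeds):
        pri = priors[model.model_id] if isinstance(priors, dict) else priors
        for row_ss in mseed.spawn(n_sims):
            for attempt, child in enumerate(row_ss.spawn(max_retries)):
                try:
                    rng = np.random.default_rng(child)
                    draw = draw_parameters(model, pri, rng)
                    ds = simulate_dataset(
                        model, draw, design, child, counts_only=True
                    )
                    vec = ds.summary_vector(vector_spec)
                    break
                except Exception:
                    if attempt == max_retries - 1:
                        raise
            stat_names = vec.names
            param_rows.append({"model_id": model.model_id, **draw.values})
            stat_rows.append(vec.values)
    params = pd.DataFrame(param_rows)
    stats = pd.DataFrame(np.vstack(stat_rows), columns=list(stat_names))
    scenarios = {m.model_id: m.scenario for m in models}
    return ReferenceTable(params, stats, scenarios)


# ---------------------------------------------------------------------------
# rejection machinery


def _normalized(table: ReferenceTable) -> np.ndarray:
    return table.stats.to_numpy(dtype=float) / table.norm.to_numpy()


def _observed_values(observed, table: ReferenceTable) -> np.ndarray:
    """Accept a SummaryStatVector, Series or array aligned to the table."""
    if hasattr(observed, "names"):  # SummaryStatVector
        series = pd.Series(observed.values, index=list(observed.names))
        return series[table.stats.columns].to_numpy(dtype=float)
    if isinstance(observed, pd.Series):
        return observed[table.stats.columns].to_numpy(dtype=float)
    arr = np.asarray(observed, dtype=float)
    if arr.shape != (table.stats.shape[1],):
        raise ValueError("observed vector does not match the table's stats")
    return arr


def abc_model_choice(
    table: ReferenceTable,
    observed,
    tolerance: float = 0.01,
    method: str = "rejection",
    seed: int | None = None,
) -> AbcModelChoice:
    """Rejection model choice at the given tolerance.

    Retains round(tolerance * rows) closest rows under MAD-normalized
    Euclidean distance (ties broken by strict distance order, then row
    index) and reports per-model posterior shares, optionally refit by a
    small multinomial classifier on the retained rows.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    n_rows = len(table)
    n_keep = int(round(tolerance * n_rows))
    if n_keep < _MIN_RETAINED:
        raise ValueError(
            f"tolerance {tolerance} retains {n_keep} < {_MIN_RETAINED} rows"
        )
    x = _normalized(table)
    obs = _observed_values(observed, table) / table.norm.to_numpy()
    dist = np.sqrt(((x - obs) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    retained = order[:n_keep]
    labels = table.model_ids[retained]
    model_ids = sorted(table.scenarios)
    present = [m for m in model_ids if m in set(table.model_ids)]
    if method == "rejection":
        posts = {m: float((labels == m).mean()) for m in present}
    elif method == "classifier":
        posts = _classifier_posteriors(
            x[retained], labels, obs, present, seed
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    best = max(posts, key=posts.get)
    bf = {
        m: (posts[best] / posts[m] if posts[m] > 0 else np.inf)
        for m in present
        if m != best
    }
    return AbcModelChoice(tolerance, retained, posts, bf, method)


def _classifier_posteriors(x_ret, labels, obs, present, seed):
    """Multinomial posteriors from a single-hidden-layer classifier."""
    from sklearn.neural_network import MLPClassifier

    if len(set(labels)) == 1:
        only = int(labels[0])
        return {m: (1.0 if m == only else 0.0) for m in present}
    clf = MLPClassifier(
        hidden_layer_sizes=(8,),
        activation="logistic",
        max_iter=2000,
        random_state=seed if seed is not None else 0,
    )
    clf.fit(x_ret, labels)
    proba = clf.predict_proba(obs[None, :])[0]
    posts = {m: 0.0 for m in present}
    for m, p in zip(clf.classes_, proba):
        posts[int(m)] = float(p)
    return posts


def hierarchical_comparison(
    table: ReferenceTable,
    observed,
    tolerance: float = 0.01,
    method: str = "rejection",
    seed: int | None = None,
) -> HierarchicalChoice:
    """Two-stage model choice: within scenarios, then scenario winners.

    Stage 1 runs model choice restricted to each scenario's rows; stage
    2 reruns it on the pooled rows of the two winners.  The Bayes
    factor is the stage-2 posterior ratio under equal model priors.
    """
    scenarios = sorted(set(table.scenarios.values()))
    within: dict[int, dict[int, float]] = {}
    winners: dict[int, int] = {}
    for scen in scenarios:
        members = [m for m, s in table.scenarios.items() if s == scen]
        mask = np.isin(table.model_ids, members)
        sub = table.subset_rows(mask)
        choice = abc_model_choice(sub, observed, tolerance, method, seed)
        within[scen] = choice.posteriors
        winners[scen] = choice.best_model
    finalists = sorted(winners.values())
    mask = np.isin(table.model_ids, finalists)
    final = abc_model_choice(
        table.subset_rows(mask), observed, tolerance, method, seed
    )
    among = final.posteriors
    overall = final.best_model
    other = [m for m in finalists if m != overall]
    bf = (
        among[overall] / among[other[0]] if among[other[0]] > 0 else np.inf
    ) if other else 1.0
    return HierarchicalChoice(within, winners, among, bf, overall)


# ---------------------------------------------------------------------------
# summary-vector selection with PODs


def _pod_score(
    table: ReferenceTable,
    pod_idx: np.ndarray,
    tolerance: float,
) -> float:
    """Mean over PODs of P(true model) - mean P(other models)."""
    keep = np.ones(len(table), dtype=bool)
    keep[pod_idx] = False
    rest = table.subset_rows(keep)
    scores = []
    for i in pod_idx:
        truth = int(table.model_ids[i])
        obs = table.stats.iloc[i]
        choice = abc_model_choice(rest, obs, tolerance)
        p_true = choice.posteriors.get(truth, 0.0)
        others = [p for m, p in choice.posteriors.items() if m != truth]
        scores.append(p_true - float(np.mean(others)))
    return float(np.mean(scores))


def default_candidates(stat_names=("pi", "ss", "D", "piw", "pib")):
    """All subsets of 2-5 statistics, the sweep the pipeline scores."""
    out = []
    for k in range(2, min(5, len(stat_names)) + 1):
        out.extend(itertools.combinations(stat_names, k))
    return out


def select_stat_vector(
    table: ReferenceTable,
    candidates=None,
    pods_per_model: int = 10,
    tolerance: float = 0.01,
    seed: int | None = None,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Score candidate stat subsets on held-out PODs; return the best.

    For each candidate subset, ``pods_per_model`` rows per model are
    held out and classified against the rest; the score rewards the
    posterior on the true model over the mean posterior on the others.
    """
    if pods_per_model < 1:
        raise ValueError("pods_per_model must be >= 1")
    if candidates is None:
        candidates = default_candidates()
    candidates = [tuple(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate vectors")
    known = {c.split(":")[1] for c in table.stats.columns}
    for cand in candidates:
        missing = set(cand) - known
        if missing:
            raise ValueError(f"candidate references unknown stats {missing}")
    rng = np.random.default_rng(seed)
    pod_idx = []
    ids = table.model_ids
    for m in sorted(set(ids)):
        rows = np.where(ids == m)[0]
        pod_idx.extend(rng.choice(rows, size=pods_per_model, replace=False))
    pod_idx = np.array(sorted(pod_idx))
    rows = []
    for cand in candidates:
        sub = table.subset_stats(cand)
        rows.append(
            {"vector": "+".join(cand),
             "score": _pod_score(sub, pod_idx, tolerance)}
        )
    report = pd.DataFrame(rows).sort_values(
        "score", ascending=False, ignore_index=True
    )
    best = tuple(report.loc[0, "vector"].split("+"))
    return best, report


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    table: ReferenceTable,
    pods_total: int = 100,
    tolerance: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Confusion matrix (true model rows, selected model columns).

    PODs are sampled without replacement, balanced across models; all
    POD rows are removed from the table before classification.
    """
    models = sorted(set(table.scenarios) & set(table.model_ids))
    if pods_total < len(models):
        raise ValueError("pods_total must cover every model")
    if pods_total > len(table):
        raise ValueError("pods_total exceeds the table size")
    rng = np.random.default_rng(seed)
    per = pods_total // len(models)
    extra = pods_total - per * len(models)
    ids = table.model_ids
    pod_idx: list[int] = []
    for j, m in enumerate(models):
        k = per + (1 if j < extra else 0)
        rows = np.where(ids == m)[0]
        pod_idx.extend(rng.choice(rows, size=k, replace=False))
    pod_idx = np.array(sorted(pod_idx))
    keep = np.ones(len(table), dtype=bool)
    keep[pod_idx] = False
    rest = table.subset_rows(keep)
    confusion = pd.DataFrame(0, index=models, columns=models)
    for i in pod_idx:
        truth = int(ids[i])
        choice = abc_model_choice(rest, table.stats.iloc[i], tolerance)
        confusion.loc[truth, choice.best_model] += 1
    return confusion


def scenario_confusion_rates(
    confusion: pd.DataFrame, scenarios: dict[int, int]
) -> tuple[float, float]:
    """(between-scenario, within-scenario) misclassification rates."""
    between = within = correct = 0
    for true_m in confusion.index:
        for sel_m in confusion.columns:
            cnt = int(confusion.loc[true_m, sel_m])
            if true_m == sel_m:
                correct += cnt
            elif scenarios[true_m] == scenarios[sel_m]:
                within += cnt
            else:
                between += cnt
    total = confusion.to_numpy().sum()
    return between / total, within / total


# ---------------------------------------------------------------------------
# goodness of fit


def goodness_of_fit(
    table: ReferenceTable,
    observed,
    tolerance: float = 0.01,
    model_id: int | None = None,
    level: float = 95.0,
) -> GofReport:
    """PCA envelope check of the observed statistics against retained
    simulations of one model.

    Retains the closest ``tolerance`` fraction of the (optionally
    model-restricted) rows, computes principal components of their
    statistics, projects the observed vector, and reports the
    Mahalanobis-distance percentile of the observed point within the
    retained cloud (degenerate components dropped).
    """
    if model_id is not None:
        table = table.subset_rows(table.model_ids == model_id)
    n_keep = max(int(round(tolerance * len(table))), _MIN_RETAINED)
    if len(table) < 50:
        raise ValueError("need at least 50 rows for goodness of fit")
    x = _normalized(table)
    obs = _observed_values(observed, table) / table.norm.to_numpy()
    dist = np.sqrt(((x - obs) ** 2).sum(axis=1))
    retained = np.argsort(dist, kind="stable")[:n_keep]
    if len(retained) < 50:
        retained = np.argsort(dist, kind="stable")[:50]
    xr = x[retained]
    mean = xr.mean(axis=0)
    xc = xr - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(xr.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > max(tol, 1e-12)
    if not keep.any():
        import warnings

        warnings.warn("all components degenerate; trivial fit report")
        return GofReport(
            np.zeros((len(xr), 2)), np.zeros(2), np.array([]), 0.0, True
        )
    comps = vt[keep]
    var = (s[keep] ** 2) / (len(xr) - 1)
    proj = xc @ comps.T
    obs_proj = (obs - mean) @ comps.T
    d2_ret = ((proj**2) / var).sum(axis=1)
    d2_obs = float(((obs_proj**2) / var).sum())
    percentile = 100.0 * float(np.mean(d2_ret <= d2_obs))
    if proj.shape[1] == 1:  # keep a 2-D plotting surface
        proj = np.column_stack([proj, np.zeros(len(proj))])
        obs_proj = np.append(obs_proj, 0.0)
    return GofReport(
        projected=proj,
        observed_projection=np.asarray(obs_proj),
        explained_variance=var,
        percentile=percentile,
        passed=percentile <= level,
    )
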