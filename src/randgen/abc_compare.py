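"""Random-forest ABC model comparison.

Likelihood-free comparison of the candidate generators: simulate a
reference table of summary statistics from every model under its parameter
prior, train a random-forest classifier to recognize the generating model
from the summary vector, and convert classification into posterior model
probabilities.  A separate regression forest, trained on the classifier's
out-of-bag misclassification indicator, estimates the probability that the
chosen label is wrong for a given query; running the classification
recursively — removing the winning model and re-classifying among the rest
— allocates that error mass until every model has a posterior probability.

Posteriors from several conditions multiply (and renormalize) into joint
posteriors; ratios of average posteriors over model classes give Bayesian
model-averaging Bayes factors, and matched-set ratios give feature-level
Bayes factors for the three qualitative sampler features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import samplers
from .domains import TargetDistribution
from .samplers import LOCAL_MODELS, SamplerSpec, draw_params_from_prior, generate_sequence
from .sumstats import FEATURE_NAMES, SummaryVector, summarize

__all__ = [
    "ReferenceTable",
    "PosteriorTable",
    "RecoveryReport",
    "ModelChoiceForest",
    "simulate_reference_table",
    "train_classifier",
    "posterior_for_sequence",
    "combine_posteriors",
    "class_bayes_factor",
    "feature_bayes_factor",
    "model_recovery",
    "FEATURE_SETS",
]

#: Matched model sets for feature-level Bayes factors.  Each side contains
#: only models with an identical counterpart across the divide, differing
#: in the feature of interest alone; REC and MCREC are excluded from the
#: gradient comparison because no model has recycled momentum without
#: gradient-based proposals.
FEATURE_SETS = {
    "multiple_chains": (("MC3", "MCHMC", "MCREC"), ("MH", "HMC", "REC")),
    "gradient": (("HMC", "MCHMC"), ("MH", "MC3")),
    "recycled": (("REC", "MCREC"), ("HMC", "MCHMC")),
}


@dataclass
class ReferenceTable:
    """Simulated (model, params, summary) rows used to train the forests."""

    data: pd.DataFrame
    domain: TargetDistribution
    length: int
    seed: object
    n_per_model: int

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["model"]))

    def features(self, models=None) -> tuple[np.ndarray, np.ndarray]:
        df = self.data if models is None else self.data[self.data["model"].isin(models)]
        return df[list(FEATURE_NAMES)].to_numpy(), df["model"].to_numpy()


@dataclass
class PosteriorTable:
    """Per-model posterior probabilities for one sequence."""

    probs: dict[str, float]
    elimination_order: list[str] = field(default_factory=list)
    oob_error: float | None = None

    def __post_init__(self):
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"posterior probabilities sum to {total}, not 1")

    @property
    def best(self) -> str:
        return max(self.probs, key=self.probs.get)


@dataclass
class RecoveryReport:
    """Confusion structure of a model-recovery experiment."""

    confusion: pd.DataFrame  # rows: true model (sum to 1); cols: predicted
    accuracy: dict[str, float]
    prior_error: float
    n_test: int
    table: "ReferenceTable | None" = field(default=None, repr=False)
    test_data: pd.DataFrame | None = field(default=None, repr=False)

    def class_rate(self, class_models) -> float:
        """Fraction of sequences from ``class_models`` predicted as any
        model in the class."""
        class_models = [m for m in class_models if m in self.confusion.index]
        cols = [m for m in class_models if m in self.confusion.columns]
        return float(self.confusion.loc[class_models, cols].to_numpy().sum(axis=1).mean())

    @property
    def local_class_rate(self) -> float:
        return self.class_rate(LOCAL_MODELS)


def _usable_models(models, domain: TargetDistribution) -> list[str]:
    models = list(models)
    if "schema" in models and domain.ndim == 2:
        warnings.warn("the schema model cannot sample in two-dimensional domains; "
                      "excluding it from the reference table")
        models = [m for m in models if m != "schema"]
    return models


def _simulate_rows(models, domain, n_per_model, length, rng) -> pd.DataFrame:
    rows = []
    for model in models:
        done = 0
        while done < n_per_model:
            params = draw_params_from_prior(model, domain, rng)
            seq = generate_sequence(SamplerSpec(model, params), domain, length=length, rng=rng)
            sv = summarize(seq)
            if not np.all(np.isfinite(sv.to_array())):
                continue  # too degenerate to define every statistic: resimulate
            rows.append({"model": model, **sv.to_dict()})
            done += 1
    return pd.DataFrame(rows)


def simulate_reference_table(models, domain: TargetDistribution, n_per_model: int,
                             length: int = 400, seed=None) -> ReferenceTable:
    """Simulate ``n_per_model`` summarized sequences per model, parameters
    drawn from the prior.  Rows whose summary vector is incomplete are
    resimulated, so the table is always complete."""
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    models = _usable_models(models, domain)
    rng = np.random.default_rng(seed)
    data = _simulate_rows(models, domain, n_per_model, length, rng)
    return ReferenceTable(data=data, domain=domain, length=length, seed=seed,
                          n_per_model=n_per_model)


class ModelChoiceForest:
    """Random-forest model choice with recursive posterior construction.

    ``classify`` gives hard labels (used for model recovery); ``posterior``
    runs the recursive scheme: at each step the classifier trained on the
    remaining models picks a winner, the error-regression forest estimates
    the probability ``e`` that this pick is wrong for the query, the winner
    receives a share ``1 - e`` of the remaining probability mass, and mass
    ``e`` recurses into the reduced model set (the final model takes
    whatever remains).  With two models this reduces to the published
    ABC-RF posterior (1 - e, e).
    """

    def __init__(self, table: ReferenceTable, n_trees: int = 500, seed: int = 0):
        if len(table.models) < 2:
            raise ValueError("model choice needs at least 2 models in the table")
        self.table = table
        self.n_trees = n_trees
        self.seed = seed
        self._cache: dict[frozenset, tuple] = {}
        self._full = self._fit(frozenset(table.models), fit_regressor=False)

    # ------------------------------------------------------------------
    def _fit(self, model_set: frozenset, fit_regressor: bool = True):
        key = model_set
        cached = self._cache.get(key)
        if cached is not None and (cached[1] is not None or not fit_regressor):
            return cached
        X, y = self.table.features(model_set)
        clf = RandomForestClassifier(n_estimators=self.n_trees, oob_score=True,
                                     random_state=self.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny tables: some rows never OOB
            clf.fit(X, y)
        reg = None
        if fit_regressor:
            oob = clf.oob_decision_function_
            have = ~np.isnan(oob).any(axis=1)
            pred = clf.classes_[np.argmax(oob[have], axis=1)]
            miss = (pred != y[have]).astype(float)
            reg = RandomForestRegressor(n_estimators=self.n_trees,
                                        random_state=self.seed, n_jobs=1)
            reg.fit(X[have], miss)
        self._cache[key] = (clf, reg)
        return clf, reg

    # ------------------------------------------------------------------
    @property
    def classifier(self) -> RandomForestClassifier:
        return self._full[0]

    @property
    def oob_error(self) -> float:
        """Prior error rate of the full-set classifier (out-of-bag)."""
        return float(1.0 - self.classifier.oob_score_)

    def classify(self, summaries) -> np.ndarray:
        """Hard model labels for an (n, n_features) array or SummaryVector(s)."""
        return self.classifier.predict(_as_matrix(summaries))

    def posterior(self, summary) -> PosteriorTable:
        x = _as_matrix(summary)
        if x.shape[0] != 1:
            raise ValueError("posterior() takes a single summary vector")
        remaining = set(self.table.models)
        mass = 1.0
        probs: dict[str, float] = {}
        order: list[str] = []
        while len(remaining) > 1:
            clf, reg = self._fit(frozenset(remaining))
            best = str(clf.predict(x)[0])
            e = float(np.clip(reg.predict(x)[0], 0.0, 1.0))
            probs[best] = mass * (1.0 - e)
            mass *= e
            remaining.discard(best)
            order.append(best)
        last = remaining.pop()
        probs[last] = mass
        order.append(last)
        return PosteriorTable(probs=probs, elimination_order=order,
                              oob_error=self.oob_error)


def _as_matrix(summaries) -> np.ndarray:
    if isinstance(summaries, SummaryVector):
        return summaries.to_array()[None, :]
    if isinstance(summaries, (list, tuple)) and summaries and isinstance(summaries[0], SummaryVector):
        return np.vstack([s.to_array() for s in summaries])
    x = np.asarray(summaries, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def train_classifier(table: ReferenceTable, n_trees: int = 500,
                     seed: int = 0) -> ModelChoiceForest:
    """Fit the model-choice forest on a reference table."""
    return ModelChoiceForest(table, n_trees=n_trees, seed=seed)


def posterior_for_sequence(summary, table: ReferenceTable, n_trees: int = 500,
                           seed: int = 0, forest: ModelChoiceForest | None = None) -> PosteriorTable:
    """Recursive-forest posterior over the table's models for one summary
    vector.  Pass a prefit ``forest`` to reuse cached forests across
    sequences."""
    if forest is None:
        forest = ModelChoiceForest(table, n_trees=n_trees, seed=seed)
    return forest.posterior(summary)


def combine_posteriors(tables: list[PosteriorTable]) -> PosteriorTable:
    """Joint posterior across conditions: elementwise product, renormalized."""
    if not tables:
        raise ValueError("need at least one posterior table")
    model_sets = [set(t.probs) for t in tables]
    if any(s != model_sets[0] for s in model_sets[1:]):
        raise ValueError("posterior tables cover different model sets")
    models = sorted(model_sets[0])
    prod = np.ones(len(models))
    for t in tables:
        prod *= np.array([t.probs[m] for m in models])
    total = prod.sum()
    if total == 0:
        raise ValueError("combined posterior has zero mass everywhere")
    return PosteriorTable(probs=dict(zip(models, prod / total)))


def class_bayes_factor(posterior: PosteriorTable, class_a, class_b) -> float:
    """Bayesian-model-averaging Bayes factor: ratio of the average
    posterior over class A to that over class B.  Returns ``inf`` when
    class B carries no mass."""
    a, b = set(class_a), set(class_b)
    if not a or not b or (a & b):
        raise ValueError("classes must be disjoint and non-empty")
    mean_a = np.mean([posterior.probs[m] for m in a])
    mean_b = np.mean([posterior.probs[m] for m in b])
    if mean_b == 0:
        return float("inf") if mean_a > 0 else float("nan")
    return float(mean_a / mean_b)


def feature_bayes_factor(posterior: PosteriorTable, feature: str) -> float:
    """Bayes factor for one qualitative sampler feature over matched model
    sets (see :data:`FEATURE_SETS`)."""
    try:
        with_f, without_f = FEATURE_SETS[feature]
    except KeyError:
        raise ValueError(f"unknown feature {feature!r}; known: {sorted(FEATURE_SETS)}")
    return class_bayes_factor(posterior, with_f, without_f)


def model_recovery(models, domain: TargetDistribution, n_train: int, n_test: int,
                   length: int = 400, seed=None, n_trees: int = 500) -> RecoveryReport:
    """Train on a fresh reference table and classify held-out simulations of
    known origin; report the confusion matrix and per-model accuracy."""
    models = _usable_models(models, domain)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    train_seed, test_seed, forest_seed = ss.spawn(3)
    table = simulate_reference_table(models, domain, n_train, length=length, seed=train_seed)
    forest = ModelChoiceForest(table, n_trees=n_trees,
                               seed=int(forest_seed.generate_state(1)[0] % (2**31)))
    test_rng = np.random.default_rng(test_seed)
    test = _simulate_rows(models, domain, n_test, length, test_rng)
    pred = forest.classify(test[list(FEATURE_NAMES)].to_numpy())
    conf = pd.crosstab(test["model"], pd.Series(pred, name="predicted"),
                       normalize="index")
    conf = conf.reindex(index=models, columns=models, fill_value=0.0)
    accuracy = {m: float(conf.loc[m, m]) for m in models}
    return RecoveryReport(confusion=conf, accuracy=accuracy,
                          prior_error=forest.oob_error, n_test=n_test,
                          table=table, test_data=test)
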