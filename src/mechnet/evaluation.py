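"""Classifier evaluation: ROC/AUC on labelled panels and Bayesian PPV.

The classification score for a mechanism is the mechanism-test p-value
(larger = more consistent with the mechanism), so a good classifier gives
networks truly from mechanism M systematically larger p-values under M
than networks from other mechanisms.  AUC is the probability that a random
true-M network outranks a random non-M network; a random classifier gives
AUC = 0.5, a perfect one 1.0.

Because AUC measures average accuracy, a highly accurate test can still be
wrong for most of its positive calls when the mechanism is rare:
:func:`bayes_ppv` gives the posterior probability that a positive
classification is a true positive given the test accuracy and the
mechanism's prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from . import mechanisms as mech
from .classifier import (DEFAULT_ALPHA, DirectednessMismatch, best_fit_parameter,
                         mechanism_test)
from .state_space import StackWeights, default_weights


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    label: str = ""


def roc_auc(scores: Sequence[float], labels: Sequence[bool], label: str = "") -> RocResult:
    """ROC curve and AUC for scores where larger means "more positive".

    AUC uses the rank (Mann-Whitney) formulation with tie mid-ranks, which
    equals trapezoidal integration of the tie-aware ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(~sorted_labels)[distinct]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocResult(thresholds, tpr, fpr, float(auc), label)


@dataclass
class PanelConfig:
    """Knobs of a labelled-panel evaluation run.

    Defaults are desk-scale: 30 networks per mechanism-orientation panel of
    20-node networks, grid 25 / reps 10 / null 100.  The full-scale run
    (panels of 300, grid 100 / reps 50 / null 500) uses the same code path.
    """

    n_per_panel: int = 30
    n_nodes: int = 20
    grid_size: int = 25
    reps: int = 10
    n_null: int = 100
    alpha: float = DEFAULT_ALPHA
    mechanisms: tuple = mech.MECHANISMS
    candidates: Optional[tuple] = None  # default: same as mechanisms
    orientations: tuple = (True, False)
    grown: bool = False  # build targets with the standardized growth process


def labelled_panel(config: PanelConfig, rng=None):
    """Simulate the labelled target networks of an evaluation run.

    For each mechanism-orientation combination with a valid form, sweep the
    governing parameter evenly across its range.  Returns a list of
    ``(mechanism, directed, parameter, network)`` tuples.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    panel = []
    for directed in config.orientations:
        for m in config.mechanisms:
            if m == "NM" and not directed:
                continue
            lo, hi = mech.DEFAULT_PARAMETER_RANGES[m]
            for v in np.linspace(lo, hi, config.n_per_panel):
                spec = mech.MechanismSpec(m, float(v), directed=directed)
                net = (mech.grow_network(spec, config.n_nodes, rng) if config.grown
                       else mech.simulate_mechanism(spec, config.n_nodes, rng))
                panel.append((m, directed, float(v), net))
    return panel


def panel_evaluation(config: PanelConfig = PanelConfig(),
                     weights: Optional[StackWeights] = None, rng=None,
                     progress=None) -> dict:
    """Classify a labelled simulated panel and score every candidate by ROC.

    Every target is classified against every candidate mechanism with an
    independently simulated null (fresh simulations per target).  Returns a
    dict mapping ``(candidate, directed)`` to :class:`RocResult`, where
    positives are the targets truly generated by that candidate.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if weights is None:
        weights = default_weights()
    candidates = config.candidates or config.mechanisms
    panel = labelled_panel(config, rng)
    scores = {}  # (candidate, directed) -> (p-values, labels)
    for idx, (true_mech, directed, _param, net) in enumerate(panel):
        for cand in candidates:
            if cand == "NM" and not directed:
                continue
            try:
                best = best_fit_parameter(net, cand, config.grid_size, config.reps,
                                          weights, rng)
            except DirectednessMismatch:
                continue
            p, _, _ = mechanism_test(net, cand, best, config.n_null, weights, rng)
            key = (cand, directed)
            scores.setdefault(key, ([], []))
            scores[key][0].append(p)
            scores[key][1].append(true_mech == cand)
        if progress is not None:
            progress(idx + 1, len(panel))
    results = {}
    for (cand, directed), (p_values, labels) in scores.items():
        name = f"{cand}-{'directed' if directed else 'undirected'}"
        results[(cand, directed)] = roc_auc(p_values, labels, label=name)
    return results


def bayes_ppv(accuracy: float, prevalence: float) -> float:
    """P(true | positive) by Bayes' theorem, treating the test accuracy as
    both its sensitivity and its specificity.

    With a rare mechanism even a highly accurate classifier yields mostly
    false positives: ``bayes_ppv(0.99, 0.01) == 0.5``.
    """
    if not (0.0 < accuracy <= 1.0):
        raise ValueError("accuracy must lie in (0, 1]")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    pos = accuracy * prevalence
    return pos / (pos + (1.0 - accuracy) * (1.0 - prevalence))
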