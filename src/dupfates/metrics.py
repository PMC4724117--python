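"""Pairwise divergence scores between duplicate gene copies.

Three scores, each computed per paralog pair:

* shared-annotation (Dice) similarity ``2·|A∩B| / (|A|+|B|)`` over GO term
  sets — applied to the biological-process and molecular-function domains as
  functional similarity, and to the cellular-component domain as subcellular
  colocalization;
* Pearson correlation of the two genes' expression profiles across tissues.

Pairs failing a metric's preconditions (empty annotation set, missing or
constant expression profile) are excluded from that metric with a counted
reason rather than scored zero.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Set

import numpy as np
import pandas as pd

from .model import Dataset, PairScore

#: Metric names accepted by :func:`score_all_pairs`.
METRICS = ("BP_similarity", "MF_similarity", "CC_colocalization", "expression_r")

_METRIC_DOMAIN = {"BP_similarity": "BP", "MF_similarity": "MF", "CC_colocalization": "CC"}

MIN_TISSUES = 3


def shared_annotation_similarity(terms_a: Set, terms_b: Set) -> float:
    """Dice similarity between two annotation term sets.

    Symmetric, in [0, 1]; 1 iff the sets are equal, 0 iff disjoint. Undefined
    (ValueError) when either set is empty — callers exclude such pairs.
    """
    if not terms_a or not terms_b:
        raise ValueError("similarity undefined for an empty annotation set")
    return 2.0 * len(terms_a & terms_b) / (len(terms_a) + len(terms_b))


def expression_correlation(profile_a, profile_b) -> float:
    """Pearson product-moment correlation between two tissue profiles.

    Accepts aligned array-likes, or :class:`pandas.Series` indexed by tissue
    name, in which case the profiles are aligned on their common tissues
    (at least :data:`MIN_TISSUES` required). A constant profile has zero
    variance and raises ValueError.

    Computed in centered form (mathematically identical to the raw-sums
    formula N·Σxy − Σx·Σy over the square-rooted products, but numerically
    stable).
    """
    if isinstance(profile_a, pd.Series) and isinstance(profile_b, pd.Series):
        common = profile_a.index.intersection(profile_b.index)
        if len(common) < MIN_TISSUES:
            raise ValueError(f"fewer than {MIN_TISSUES} common tissues")
        profile_a = profile_a.loc[common].to_numpy()
        profile_b = profile_b.loc[common].to_numpy()
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(a) < MIN_TISSUES:
        raise ValueError(f"fewer than {MIN_TISSUES} tissues")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt(ac @ ac) * np.sqrt(bc @ bc)
    if denom == 0.0:
        raise ValueError("constant expression profile (zero variance)")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def score_all_pairs(
    dataset: Dataset, metric: str
) -> tuple[list[PairScore], Counter]:
    """Score every pair of the dataset on one metric.

    Returns the scores plus exclusion counts keyed by reason; the counts
    reconcile with the input (len(scores) + sum(exclusions) == len(pairs)).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    scores: list[PairScore] = []
    exclusions: Counter = Counter()
    for pair in dataset.pairs:
        ga, gb = dataset.genes[pair.gene_a], dataset.genes[pair.gene_b]
        if metric == "expression_r":
            if ga.expression is None or gb.expression is None:
                exclusions["missing_expression"] += 1
                continue
            try:
                value = expression_correlation(ga.expression, gb.expression)
            except ValueError:
                exclusions["constant_profile"] += 1
                continue
            n_basis = len(ga.expression)
        else:
            domain = _METRIC_DOMAIN[metric]
            ta, tb = ga.go_terms(domain), gb.go_terms(domain)
            if not ta or not tb:
                exclusions["empty_annotation_set"] += 1
                continue
            value = shared_annotation_similarity(ta, tb)
            n_basis = len(ta) + len(tb)
        scores.append(PairScore(
            gene_a=pair.gene_a, gene_b=pair.gene_b, origin=pair.origin,
            dn=pair.dn, metric=metric, value=value, n_basis=n_basis,
        ))
    return scores, exclusions
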