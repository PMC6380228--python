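"""Edit-distance clustering of attribute names with affinity propagation.

Metadata submitters fabricate many near-identical field names (``weight
(kg)``, ``weight_kg``, ``Weight..kg``) for the same aspect of a sample.
Clustering the names by Levenshtein distance groups such typo and
decoration variants, and affinity propagation is a natural fit: it does
not need the number of clusters up front and it elects a representative
*exemplar* per cluster that can serve as the harmonized name.

Similarities are negated edit distances; the affinity-propagation
preference defaults to the median off-diagonal similarity (the algorithm's
conventional choice, producing a moderate number of clusters).  Distances
are computed on the raw, case-sensitive strings -- unit-cost edits already
group case variants -- with an opt-in casefold mode.

At full repository scale (tens of thousands of names) the similarity
matrix is dense; the edit distances themselves come from the ``edlib``
alignment library, with a plain dynamic-programming fallback for inputs
whose combined alphabet exceeds edlib's 256-symbol limit.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import edlib
import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .records_io import SampleRecord

__all__ = [
    "levenshtein",
    "similarity_matrix",
    "ClusterSet",
    "Cluster",
    "cluster_names",
    "NameUse",
    "rank_names_by_use",
]


def _levenshtein_dp(s: str, t: str) -> int:
    # classic two-row DP; only used when edlib cannot encode the alphabet
    if len(s) < len(t):
        s, t = t, s
    prev = list(range(len(t) + 1))
    for i, cs in enumerate(s, 1):
        cur = [i]
        for j, ct in enumerate(t, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cs != ct)))
        prev = cur
    return prev[-1]


def levenshtein(s: str, t: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if s == t:
        return 0
    if not s or not t:
        return len(s) or len(t)
    try:
        d = edlib.align(s, t, task="distance")["editDistance"]
    except (ValueError, MemoryError):
        return _levenshtein_dp(s, t)
    if d < 0:  # edlib reports -1 when a k-limit is hit; not expected here
        return _levenshtein_dp(s, t)
    return d


def similarity_matrix(names: Sequence[str], check_unique: bool = True) -> np.ndarray:
    """Square matrix of negated pairwise edit distances (zero diagonal)."""
    if check_unique and len(set(names)) != len(names):
        dupes = [n for n, k in Counter(names).items() if k > 1]
        raise ValueError(f"names must be unique; duplicated: {dupes[:5]!r}")
    n = len(names)
    sim = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(levenshtein(names[i], names[j]))
            sim[i, j] = sim[j, i] = -d
    return sim


@dataclass(frozen=True)
class Cluster:
    exemplar: str
    members: frozenset[str]


@dataclass
class ClusterSet:
    """A partition of a name set into exemplar-led clusters."""

    clusters: list[Cluster]
    parameters: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def exemplars(self) -> list[str]:
        return [c.exemplar for c in self.clusters]

    def cluster_of(self, name: str) -> Cluster:
        for c in self.clusters:
            if name in c.members:
                return c
        raise KeyError(name)


def cluster_names(
    names: Sequence[str],
    preference: float | None = None,
    damping: float = 0.5,
    max_iterations: int = 1000,
    convergence_iterations: int = 15,
    seed: int = 0,
    casefold: bool = False,
) -> ClusterSet:
    """Cluster attribute names around exemplars by edit-distance similarity.

    Parameters follow the affinity-propagation conventions: ``preference``
    (default: median off-diagonal similarity) controls how readily a name
    becomes an exemplar, ``damping`` in [0.5, 1) stabilizes the message
    updates, and ``seed`` fixes the tie-breaking noise so identical inputs
    give identical clusterings.  On non-convergence the names are returned
    as singleton clusters with ``converged=False`` rather than raising.
    """
    if not names:
        raise ValueError("need at least one name to cluster")
    if not 0.5 <= damping < 1.0:
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")
    names = list(names)
    params = {
        "preference": "median" if preference is None else preference,
        "damping": damping,
        "max_iterations": max_iterations,
        "convergence_iterations": convergence_iterations,
        "seed": seed,
        "casefold": casefold,
    }
    if len(names) == 1:
        return ClusterSet([Cluster(names[0], frozenset(names))], params)

    keys = [n.casefold() for n in names] if casefold else names
    sim = similarity_matrix(keys, check_unique=not casefold)
    if preference is None:
        # median of the off-diagonal similarities (the conventional default;
        # including the zero diagonal would bias toward singleton clusters)
        off_diag = sim[~np.eye(len(names), dtype=bool)]
        preference = float(np.median(off_diag))
        params["preference"] = preference
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iterations,
        convergence_iter=convergence_iterations,
        preference=preference,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        labels = ap.fit_predict(sim)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged and (len(ap.cluster_centers_indices_) == 0 or np.any(labels < 0)):
        return ClusterSet([Cluster(n, frozenset({n})) for n in names], params, converged=False)

    clusters: list[Cluster] = []
    for k, center in enumerate(ap.cluster_centers_indices_):
        members = frozenset(names[i] for i in np.flatnonzero(labels == k))
        clusters.append(Cluster(exemplar=names[center], members=members))
    return ClusterSet(clusters, params, converged=converged)


class NameUse(NamedTuple):
    name: str
    n_records: int
    n_occurrences: int


def rank_names_by_use(records: Iterable[SampleRecord]) -> list[NameUse]:
    """Frequency of use of every attribute name, most used first.

    Both the number of records containing the name and the total number of
    occurrences are reported (a record may repeat a name); ranking is by
    occurrences, ties broken lexicographically.
    """
    occurrences: Counter[str] = Counter()
    in_records: Counter[str] = Counter()
    for rec in records:
        seen: set[str] = set()
        for a in rec.attributes:
            name = a.name.strip()
            occurrences[name] += 1
            seen.add(name)
        in_records.update(seen)
    return sorted(
        (NameUse(n, in_records[n], occurrences[n]) for n in occurrences),
        key=lambda u: (-u.n_occurrences, u.name),
    )
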