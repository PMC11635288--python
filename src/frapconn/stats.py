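"""Cohort summaries: class distributions, rank-sum and t-test comparisons.

Group labels are arbitrary (treatments, mutants, or root zones; by
convention MZ = cell positions 1-10 from the quiescent center, EZ = 14-19,
DZ = >= 20).  Recovery half-times are compared pairwise with the
Mann-Whitney rank-sum test and summarized as compact letter displays;
connectivity indices across zones are compared with the two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import ConnectivityClass

__all__ = [
    "summarize_classes",
    "ranksum_compare",
    "ttest_compare",
    "assign_letters",
    "PairwiseResult",
]

CLASS_ORDER = [c.value for c in ConnectivityClass]


@dataclass
class PairwiseResult:
    """Pairwise p-values plus (for rank-sum) a compact letter display."""

    p_values: pd.DataFrame  # symmetric, diagonal = 1
    letters: dict[str, str] | None = None
    alpha: float | None = None


def summarize_classes(groups: dict[str, list]) -> pd.DataFrame:
    """Percent of items per connectivity class for each group.

    ``groups`` maps a label to a list of classes (enum members or their
    string values).  Rows are groups, columns the four classes plus ``n``;
    percentages sum to 100 per row.
    """
    rows = {}
    for label, classes in groups.items():
        if len(classes) == 0:
            raise ValueError(f"group {label!r} is empty")
        vals = [c.value if isinstance(c, ConnectivityClass) else str(c) for c in classes]
        unknown = set(vals) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes {unknown} in group {label!r}")
        n = len(vals)
        rows[label] = {cls: 100.0 * vals.count(cls) / n for cls in CLASS_ORDER}
        rows[label]["n"] = n
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[CLASS_ORDER + ["n"]]


# ---------------------------------------------------------------------------
# rank-sum (Mann-Whitney) comparisons
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 8


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(len(x), len(y)) <= _EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def ranksum_compare(groups: dict[str, list], alpha: float = 0.05) -> PairwiseResult:
    """Pairwise two-sided rank-sum tests plus a compact letter display.

    Groups whose pairwise p-value is >= alpha share at least one letter;
    significantly different groups share none.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has n < 3")
    p = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pv = _mannwhitney_p(arrays[a], arrays[b])
            p.loc[a, b] = p.loc[b, a] = pv
    letters = assign_letters(p, alpha)
    return PairwiseResult(p_values=p, letters=letters, alpha=alpha)


def assign_letters(p_values: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    Each maximal clique of the non-significance graph (edge iff p >= alpha)
    receives one letter, so two groups share a letter iff they are not
    significantly different.
    """
    import networkx as nx

    labels = list(p_values.index)
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if p_values.loc[a, b] >= alpha:
                g.add_edge(a, b)
    order = {lab: i for i, lab in enumerate(labels)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: [order[m] for m in c],
    )
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for member in clique:
            letters[member] += letter
    return letters


# ---------------------------------------------------------------------------
# t-test comparisons
# ---------------------------------------------------------------------------


def ttest_compare(groups: dict[str, list], equal_var: bool = True) -> PairwiseResult:
    """Pairwise two-sided two-sample t-tests (pooled variance by default).

    Degenerate zero-variance pairs resolve to p = 1 for equal means and
    p = 0 for different means rather than propagating NaN.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    p = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            x, y = arrays[a], arrays[b]
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                pv = 1.0 if x.mean() == y.mean() else 0.0
            else:
                pv = float(sps.ttest_ind(x, y, equal_var=equal_var).pvalue)
            p.loc[a, b] = p.loc[b, a] = pv
    return PairwiseResult(p_values=p)
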