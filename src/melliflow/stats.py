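"""Non-parametric group comparisons for landscape and richness tables.

Kruskal-Wallis H (rank formula with tie correction, chi-square
approximation), Dunn's two-by-two post-hoc z tests with Holm (default)
or Bonferroni adjustment, and a compact letter display summarising which
groups differ at the chosen alpha.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparisonResult:
    statistic: float  # Kruskal-Wallis H
    df: int
    p_value: float
    groups: list[str]
    mean_ranks: dict[str, float]
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def _bonferroni(pvals: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, pvals * len(pvals))


def compact_letter_display(
    groups: Sequence[str],
    not_different: set[frozenset[str]],
    order_key: Mapping[str, float],
) -> dict[str, str]:
    """Letters such that two groups share a letter iff a maximal clique of
    the non-significance graph contains both.

    Cliques (hence letters) are ordered by their best-ranked member so
    'a' marks the highest-valued groups.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for pair in not_different:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: (-max(order_key[m] for m in c), c),
    )
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    alphabet = itertools.chain(
        string.ascii_lowercase,
        ("".join(p) for p in itertools.product(string.ascii_lowercase, repeat=2)),
    )
    for clique, letter in zip(cliques, alphabet):
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(ls) for grp, ls in letters.items()}


def kruskal_wallis(
    samples: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
    p_adjust: str = "holm",
) -> GroupComparisonResult:
    """Kruskal-Wallis test with Dunn post-hoc comparisons.

    ``samples`` is either a mapping group-name -> values or a plain
    sequence of samples (auto-named g1, g2, ...). H uses the rank formula
    with tie correction; its p-value comes from the chi-square
    approximation with df = k - 1. Pairwise Dunn z tests are adjusted by
    Holm (default) or Bonferroni, and a compact letter display is derived
    from the adjusted p-values at ``alpha``. When every value in every
    group is identical the test is degenerate and reported as H = 0,
    p = 1 with all groups sharing one letter.
    """
    if isinstance(samples, Mapping):
        names = list(samples)
        data = [np.asarray(samples[n], dtype=float) for n in names]
    else:
        data = [np.asarray(s, dtype=float) for s in samples]
        names = [f"g{i + 1}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for n, d in zip(names, data):
        if d.size == 0:
            raise ValueError(f"group {n!r} is empty")
    if p_adjust not in ("holm", "bonferroni"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    pooled = np.concatenate(data)
    n_total = pooled.size
    k = len(data)
    ranks = sps.rankdata(pooled)
    sizes = np.array([d.size for d in data])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array(
        [ranks[bounds[i] : bounds[i + 1]].sum() for i in range(k)]
    )
    mean_ranks = rank_sums / sizes

    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n_total**3 - n_total) if n_total > 1 else 0.0

    if correction <= 0.0:  # all values identical everywhere
        h, p = 0.0, 1.0
    else:
        h_raw = 12.0 / (n_total * (n_total + 1)) * np.sum(
            rank_sums**2 / sizes
        ) - 3.0 * (n_total + 1)
        h = float(h_raw / correction)
        p = float(sps.chi2.sf(h, k - 1))

    # Dunn two-by-two z tests on the pooled mean ranks
    pairs = list(itertools.combinations(range(k), 2))
    if correction <= 0.0:
        adj = np.ones(len(pairs))
    else:
        var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
        zs = np.array(
            [
                abs(mean_ranks[i] - mean_ranks[j])
                / np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
                for i, j in pairs
            ]
        )
        praw = 2.0 * sps.norm.sf(zs)
        adj = _holm(praw) if p_adjust == "holm" else _bonferroni(praw)

    pairwise: dict[tuple[str, str], float] = {}
    not_different: set[frozenset[str]] = set()
    for (i, j), pv in zip(pairs, adj):
        pv = float(pv)
        pairwise[(names[i], names[j])] = pv
        pairwise[(names[j], names[i])] = pv
        if pv >= alpha:
            not_different.add(frozenset((names[i], names[j])))

    mr = {n: float(m) for n, m in zip(names, mean_ranks)}
    letters = compact_letter_display(names, not_different, mr)
    return GroupComparisonResult(
        statistic=h,
        df=k - 1,
        p_value=p,
        groups=names,
        mean_ranks=mr,
        pairwise=pairwise,
        letters=letters,
    )
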