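"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (per-site Python loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import math

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
CANONICAL = PURINES | PYRIMIDINES


def k2p_oracle(a: str, b: str) -> tuple[float, int]:
    """Per-site counting K2P with pairwise deletion (naive loop)."""
    assert len(a) == len(b)
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in CANONICAL or y not in CANONICAL:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan, 0
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan, n
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), n


def bcm_oracle(
    ids: list[str],
    dist: dict[tuple[str, str], float],
    labels: dict[str, str],
    threshold: float,
) -> dict[str, str]:
    """Best-close-match categories by direct enumeration.

    ``dist`` holds defined distances for unordered pairs; missing pairs
    are simply absent.
    """

    def d(i, j):
        return dist.get((i, j), dist.get((j, i)))

    out = {}
    for i in ids:
        neighbours = [(d(i, j), j) for j in ids if j != i and d(i, j) is not None]
        if not neighbours:
            out[i] = "no_id"
            continue
        best = min(v for v, _ in neighbours)
        if best > threshold:
            out[i] = "no_id"
            continue
        best_species = {labels[j] for v, j in neighbours if v == best}
        if best_species == {labels[i]}:
            out[i] = "correct"
        elif labels[i] not in best_species:
            out[i] = "incorrect"
        else:
            out[i] = "ambiguous"
    return out


def anova_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA sums of squares.

    Returns (F, between-group df is len-1; p not computed here).
    """
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ss_between = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ss_within = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_w


def tree_path_distance(tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two tips (skbio tree)."""
    na = tree.find(a)
    nb = tree.find(b)
    return na.distance(nb)
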