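"""Overlap between coding populations via 2x2 contingency tables and
Fisher's exact test (two-sided, by hypergeometric enumeration)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


@dataclass
class OverlapMatrix:
    pair: tuple[str, str]
    table: tuple[int, int, int, int]  # (both, A-only, B-only, neither)
    joint_count: int
    joint_percent: float
    p_value: float
    significant: bool


def contingency(set_a: set, set_b: set, universe: set) -> tuple[int, int, int, int]:
    """Counts (A and B, A only, B only, neither) over ``universe``."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    return both, a_only, b_only, neither


def fisher_overlap(table: tuple[int, int, int, int],
                   alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided Fisher exact p for a 2x2 table, by full enumeration.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    probs = dist.pmf(ks)
    p_obs = dist.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-9)].sum())
    p = min(p, 1.0)
    return p, p < alpha


def overlap_report(
    coding_sets: dict[str, set],
    universe: set,
    modulation_labels: dict | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[OverlapMatrix]:
    """All pairwise coding x coding (and modulation x coding) overlap tables.

    ``coding_sets`` maps category name -> neuron-id set; ``modulation_labels``
    maps neuron_id -> modulation-profile label, turning each profile into a
    set crossed against every coding category.  Restrict ``universe`` (and
    the sets) to generalization-session neurons before calling.  With
    ``bonferroni`` the per-cell level is divided by the number of cells.
    """
    if not universe:
        raise ValueError("empty universe")
    pairs = list(combinations(sorted(coding_sets), 2))
    mod_sets: dict[str, set] = {}
    if modulation_labels:
        for nid, lab in modulation_labels.items():
            mod_sets.setdefault(lab, set()).add(nid)
        mod_sets = {k: v & set(universe) for k, v in mod_sets.items()}
        pairs += [(m, c) for m in sorted(mod_sets) for c in sorted(coding_sets)]
    level = alpha / max(len(pairs), 1) if bonferroni else alpha
    out = []
    for name_a, name_b in pairs:
        set_a = mod_sets.get(name_a, coding_sets.get(name_a, set()))
        set_b = coding_sets[name_b]
        table = contingency(set_a, set_b, universe)
        p, _ = fisher_overlap(table)
        out.append(OverlapMatrix(
            pair=(name_a, name_b), table=table, joint_count=table[0],
            joint_percent=100.0 * table[0] / len(universe),
            p_value=p, significant=p < level))
    return out
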