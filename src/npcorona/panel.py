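"""Two-tier particle screening and maximum-coverage panel selection.

Tier one picks, for every candidate particle, the assay condition with the
largest detected protein set. Tier two selects the k-particle panel whose
union of detected protein IDs is largest — a maximum-coverage problem,
solved either exactly (exhaustive enumeration, guarded) or greedily (the
classic (1 − 1/e)-approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

from .errors import CapacityError
from .matrixio import IntensityTensor
from .precision import DetectionRule, detect

#: exhaustive search guard: C(n, k) combinations at most
EXACT_COMBINATION_GUARD = 200_000


@dataclass
class ScreenResult:
    """Detected protein sets per (particle, condition)."""

    detected: dict  # (np_id, condition) -> frozenset of protein IDs

    @property
    def np_ids(self) -> list[str]:
        return list(dict.fromkeys(np_id for np_id, _ in self.detected))

    def conditions_of(self, np_id: str) -> list[str]:
        return [c for n, c in self.detected if n == np_id]


@dataclass
class PanelResult:
    """Selected particle panel with coverage bookkeeping."""

    np_ids: list  # in selection order (greedy) or sorted (exact)
    coverage: int
    marginal_gains: list = field(default_factory=list)
    method: str = "exact"

    def __post_init__(self) -> None:
        if len(set(self.np_ids)) != len(self.np_ids):
            raise ValueError("selected particle IDs must be unique")


def best_condition_per_np(screen: ScreenResult) -> dict:
    """Condition with the largest detected set per particle; ties broken by
    the order conditions appear in the screen."""
    if not screen.detected:
        raise ValueError("empty screen")
    best: dict[str, tuple[str, int]] = {}
    for (np_id, condition), ids in screen.detected.items():
        size = len(ids)
        if np_id not in best or size > best[np_id][1]:
            best[np_id] = (condition, size)
    return {np_id: condition for np_id, (condition, _) in best.items()}


def select_panel(sets: dict, k: int, method: str = "exact") -> PanelResult:
    """Choose k particles maximizing unique protein coverage.

    ``exact`` enumerates all C(n, k) combinations (refusing beyond
    200,000 with a hint to use greedy); ``greedy`` repeatedly adds the
    particle with the largest marginal gain, ties broken by lexicographic
    particle ID. Unique protein IDs are counted, not protein groups.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sets):
        raise ValueError(f"k={k} exceeds the {len(sets)} available particles")
    sets = {np_id: frozenset(ids) for np_id, ids in sets.items()}
    if method == "exact":
        n_comb = comb(len(sets), k)
        if n_comb > EXACT_COMBINATION_GUARD:
            raise CapacityError(
                f"exact search over {n_comb} combinations exceeds the guard "
                f"({EXACT_COMBINATION_GUARD}); use method='greedy'"
            )
        best_ids, best_cov = None, -1
        for combo in combinations(sorted(sets), k):
            cov = len(frozenset().union(*(sets[i] for i in combo)))
            if cov > best_cov:  # first (lexicographically smallest) maximizer wins
                best_ids, best_cov = list(combo), cov
        covered: set = set()
        gains = []
        for np_id in best_ids:
            gains.append(len(sets[np_id] - covered))
            covered |= sets[np_id]
        return PanelResult(best_ids, best_cov, gains, method="exact")
    if method == "greedy":
        chosen: list = []
        covered = set()
        gains = []
        remaining = set(sets)
        for _ in range(k):
            best_id, best_gain = None, -1
            for np_id in sorted(remaining):
                gain = len(sets[np_id] - covered)
                if gain > best_gain:
                    best_id, best_gain = np_id, gain
            chosen.append(best_id)
            gains.append(best_gain)
            covered |= sets[best_id]
            remaining.discard(best_id)
        return PanelResult(chosen, len(covered), gains, method="greedy")
    raise ValueError(f"unknown method {method!r}")


def panel_pipeline(
    tensor: IntensityTensor,
    rule: DetectionRule,
    k: int,
    method: str = "exact",
) -> PanelResult:
    """detect → best condition per particle → maximum-coverage selection."""
    screen = ScreenResult(detect(tensor, rule))
    best = best_condition_per_np(screen)
    sets = {np_id: screen.detected[(np_id, cond)] for np_id, cond in best.items()}
    return select_panel(sets, k, method=method)
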