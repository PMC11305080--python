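"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by the dumbest correct
method available (closed-form geometry, naive substring comparison,
exhaustive enumeration) so the package code is always checked against an
implementation-independent reference.
"""

from __future__ import annotations

import numpy as np
import pytest

import epigraft as eg


# ---------------------------------------------------------------- oracles

def sphere_area(radius: float, probe: float) -> float:
    """Closed-form SASA of an isolated sphere."""
    return 4.0 * np.pi * (radius + probe) ** 2


def two_sphere_exposed(radius: float, probe: float, separation: float) -> float:
    """Closed-form exposed area of each of two equal spheres.

    Each extended sphere of radius R = radius + probe loses a spherical cap
    of height h = R - separation/2 (area 2*pi*R*h) to the other.
    """
    R = radius + probe
    if separation >= 2 * R:
        return sphere_area(radius, probe)
    h = R - separation / 2.0
    return sphere_area(radius, probe) - 2.0 * np.pi * R * h


def naive_scan(query: str, proteome, k: int = 9) -> list[tuple[int, str]]:
    """O(n*m) substring comparison: every query window vs every protein."""
    hits = []
    for start in range(len(query) - k + 1):
        window = query[start : start + k]
        if "X" in window:
            continue
        found = False
        for rec in proteome:
            seq = rec.sequence
            for t in range(len(seq) - k + 1):
                if seq[t : t + k] == window and "X" not in window:
                    found = True
        if found:
            hits.append((start + 1, window))
    return hits


def minimal_destroying_mutations(
    seq: str, index: eg.KmerIndex, immutable: set[int], max_size: int = 2
) -> int | None:
    """Exhaustive smallest number of point mutations that clears all matches.

    Tries all single mutations, then all pairs, over every position and
    replacement (legality — not creating new matches — included via the
    final rescan).  Returns None if no solution of size <= max_size exists.
    """
    from itertools import combinations

    def clean(s: str) -> bool:
        return not naive_scan(s, _index_records(index), index.k)

    if clean(seq):
        return 0
    mutable = [p for p in range(1, len(seq) + 1) if p not in immutable]
    options = [
        (p, aa) for p in mutable for aa in eg.humanness.AMINO_ACIDS if aa != seq[p - 1]
    ]
    for size in range(1, max_size + 1):
        for combo in combinations(options, size):
            positions = {p for p, _ in combo}
            if len(positions) < size:
                continue
            trial = list(seq)
            for p, aa in combo:
                trial[p - 1] = aa
            if clean("".join(trial)):
                return size
    return None


def _index_records(index: eg.KmerIndex):
    """Reconstruct minimal proteome records from an index (for rescanning)."""
    # one synthetic record per indexed window suffices for exact rescan
    return [
        eg.ProteomeRecord(id=f"w{i}", sequence=w)
        for i, w in enumerate(index.window_map)
    ]


def rigid_transform(coords: np.ndarray, seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return coords @ R.T + t


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def seed7():
    return eg.full_fixture(7)


@pytest.fixture
def planted_case():
    """Factory: small decoy proteome with query windows planted at will."""

    def make(seed: int, plant_at: list[int], query_len: int = 40,
             n_proteins: int = 15, protein_len: int = 60, k: int = 9):
        rng = np.random.default_rng(seed)
        query = "".join(rng.choice(list(eg.humanness.AMINO_ACIDS), size=query_len))
        proteome = eg.generate_proteome(n_proteins, (protein_len, protein_len),
                                        seed=seed + 10_000)
        spec = [
            (q, proteome[i % n_proteins].id, 5 + 11 * (i % 4))
            for i, q in enumerate(plant_at)
        ]
        proteome, truth = eg.plant_shared_windows(query, proteome, spec, k=k)
        return query, proteome, truth

    return make


@pytest.fixture
def oracles():
    """Bundle of the independent reference implementations."""
    return {
        "sphere_area": sphere_area,
        "two_sphere_exposed": two_sphere_exposed,
        "naive_scan": naive_scan,
        "minimal_mutations": minimal_destroying_mutations,
        "rigid_transform": rigid_transform,
    }
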