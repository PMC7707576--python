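"""Shared fixtures: random cognate matrices and an independent counting oracle."""

from __future__ import annotations

import numpy as np
import pytest

from lexirate import CognateMatrix, SisterPair, WordForm


def random_matrix(
    rng: np.random.Generator,
    n_langs: int = 4,
    n_concepts: int = 5,
    max_sets_per_cell: int = 4,
    min_sets_per_cell: int = 0,
    id_pool: int = 8,
    p_unattested: float = 0.15,
) -> CognateMatrix:
    """Random small cognate matrix with missing cells and synonym cells."""
    langs = [f"T{i}" for i in range(n_langs)]
    concepts = [f"c{j}" for j in range(n_concepts)]
    entries = []
    attested = []
    for lang in langs:
        for concept in concepts:
            if rng.random() < p_unattested:
                continue
            attested.append((lang, concept))
            k = int(rng.integers(min_sets_per_cell, max_sets_per_cell + 1))
            for cog in rng.choice(id_pool, size=k, replace=False):
                entries.append(WordForm(lang, concept, f"w{cog}", f"k{cog}"))
    return CognateMatrix.from_entries(
        entries, attested_cells=attested, languages=langs, concepts=concepts
    )


def brute_force_events(
    pair: SisterPair, matrix: CognateMatrix, background: list[str]
) -> dict[str, int]:
    """Literal classification of every (concept, cognate set) combination.

    Independent oracle: enumerates the full universe of cognate-set ids
    attested anywhere in the matrix against every concept, and applies
    the three classification rules verbatim, without any of the
    implementation's shortcuts.
    """
    a, b = pair.language_a, pair.language_b
    universe = sorted({e.cognate_set_id for e in matrix.entries})
    counts = {"gains_a": 0, "gains_b": 0, "losses_a": 0, "losses_b": 0}
    for concept in matrix.concepts:
        if not matrix.attested(a, concept) or not matrix.attested(b, concept):
            continue
        for cog in universe:
            in_a = cog in matrix.presence(a, concept)
            in_b = cog in matrix.presence(b, concept)
            if in_a and in_b:
                continue  # present in both: no information
            if not in_a and not in_b:
                continue  # absent from both: no information
            elsewhere = any(cog in matrix.presence(x, concept) for x in background)
            if in_a and elsewhere:
                counts["losses_b"] += 1
            elif in_b and elsewhere:
                counts["losses_a"] += 1
            elif in_a:
                counts["gains_a"] += 1
            else:
                counts["gains_b"] += 1
    return counts


def make_pair(a: str = "T0", b: str = "T1") -> SisterPair:
    return SisterPair(language_a=a, language_b=b, divergence_time=1000.0,
                      pair_path_length=2000.0, support=1.0, shared_nodes=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def fast_sampler():
    """Reduced MCMC settings for plumbing tests (not for calibration checks)."""
    from lexirate import SamplerConfig

    return SamplerConfig(chains=3, iterations=2000, warmup=500, seed=7)
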