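"""Shared fixtures: small deterministic genomes and one mid-size synthetic
scenario reused across modules (session scope keeps the suite fast)."""

from __future__ import annotations

import random

import numpy as np
import pytest

from straindiff.align import align_to_reference
from straindiff.io import SequenceRecord
from straindiff.simulate import (
    SimulationPlan,
    fragment_assembly,
    generate_reference,
    mutate_genome,
)


def random_dna(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate_seq(seq: str, rate: float, seed: int = 0) -> str:
    """Substitute a fixed fraction of positions (no indels)."""
    rng = np.random.default_rng(seed)
    arr = list(seq)
    k = int(round(rate * len(arr)))
    for p in rng.choice(len(arr), size=k, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, e - s)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


@pytest.fixture(scope="session")
def small_plan() -> SimulationPlan:
    return SimulationPlan(
        seed=42,
        n_chromosomes=2,
        chromosome_length=60_000,
        n_genes=30,
        transposon_counts={"Ty1": 1},
        n_tandem_repeat_loci=10,
        snv_count=120,
        indel_count=25,
    )


@pytest.fixture(scope="session")
def small_bundle(small_plan):
    return generate_reference(small_plan)


@pytest.fixture(scope="session")
def small_pair(small_plan, small_bundle):
    query, truth = mutate_genome(small_bundle, small_plan)
    return small_bundle, query, truth


@pytest.fixture(scope="session")
def small_contigs(small_plan, small_pair):
    bundle, query, truth = small_pair
    contigs, placements = fragment_assembly(query, truth, small_plan)
    return contigs, placements


@pytest.fixture(scope="session")
def small_blocks(small_pair, small_contigs):
    bundle, _query, _truth = small_pair
    contigs, _ = small_contigs
    return align_to_reference(contigs, bundle.records)
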