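import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nucshield import (
    BeadModel,
    GenomeSpec,
    assign_shells,
    build_bead_partition,
    cycle_shell_layout,
    generate_domains,
    generate_genome,
    scale_bead_radii,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """2-Mb uniform-composition genome."""
    sizes = {"chr1": 2_000_000}
    return generate_genome(GenomeSpec(sizes), seed=101), sizes


@pytest.fixture(scope="session")
def layered_model():
    """~120-bead model on 10 Mb with beads cycled evenly across shells.

    A synthetic layout (not an optimized placement): every shell holds an
    equal share of beads, which is what calibration and planted-recovery
    checks need.
    """
    sizes = {"chr1": 10_000_000}
    domains = generate_domains(sizes, 60, (50_000, 120_000), seed=1)
    beads = build_bead_partition(domains, sizes)
    model = BeadModel(beads=beads, radii=scale_bead_radii(beads))
    model = cycle_shell_layout(model, seed=1)
    assignment = assign_shells(model)
    return model, assignment, sizes


def brute_force_merge(intervals: list[tuple[str, int, int]], abutting: bool) -> set:
    """O(n^2) fixpoint merging — the oracle for merge_intervals."""
    items = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                overlap = a[1] < b[2] and b[1] < a[2]
                touch = a[2] == b[1] or b[2] == a[1]
                if overlap or (abutting and touch):
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return {tuple(t) for t in items}


def random_reads(rng: np.random.Generator, sizes: dict[str, int], n: int, length: int = 40):
    chroms = rng.choice(list(sizes), size=n)
    starts = np.array([rng.integers(0, sizes[c] - length) for c in chroms])
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + length,
            "name": ".",
            "score": 0,
            "strand": rng.choice(["+", "-"], size=n),
        }
    )
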