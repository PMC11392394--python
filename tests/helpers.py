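"""Shared test helpers."""

from __future__ import annotations

import math
from itertools import permutations

from ventalloc.cohort import Encounter

_DEFAULTS = dict(
    encounter_id="e0",
    age=50,
    sex="male",
    race_ethnicity="white_nh",
    covid_positive=False,
    sofa=3,
    elixhauser=0,
    charlson_points=0,
    survived=True,
    life_expectancy=None,
)


def make_encounter(**overrides) -> Encounter:
    kwargs = {**_DEFAULTS, **overrides}
    return Encounter(**kwargs)


def brute_force_expected_survival(bands, survived, capacity) -> float:
    """Exhaustive expectation of the pair-allocation survival rate.

    Independent enumeration over every permutation of a small cohort, applying
    the block rules directly: consecutive positions form pairs, the lower band
    wins a contested pair, round(c*m) beds are handed out with double-bed
    pairs first and zero-bed pairs last, and an odd leftover patient competes
    as a singleton. Assumes all bands are distinct (no tiebreaks needed).
    """
    m = len(bands)
    assert m <= 8, "enumeration is factorial; keep cohorts tiny"
    assert len(set(bands)) == m, "oracle requires distinct priorities"
    beds = min(m, int(math.floor(capacity * m + 0.5)))
    full_pairs, singleton = divmod(m, 2)
    n_pairs = full_pairs + singleton

    total_survivors = 0
    n_perms = 0
    for perm in permutations(range(m)):
        n_perms += 1
        pairs = [perm[2 * i : 2 * i + 2] for i in range(full_pairs)]
        alloc: set[int] = set()
        if beds >= n_pairs:
            extra = beds - n_pairs
            for pr in pairs[:extra]:
                alloc.update(pr)
            for pr in pairs:
                alloc.add(min(pr, key=lambda i: bands[i]))
            if singleton:
                alloc.add(perm[-1])
        else:
            k = min(beds, full_pairs)
            for pr in pairs[:k]:
                alloc.add(min(pr, key=lambda i: bands[i]))
            if singleton and beds > full_pairs:
                alloc.add(perm[-1])
        total_survivors += sum(1 for i in alloc if survived[i])
    return total_survivors / (n_perms * m)
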