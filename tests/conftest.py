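import numpy as np
import pytest

from haplometa import (
    Pedigree,
    PedigreeRecord,
    Variant,
    GenotypeMatrix,
)


@pytest.fixture
def nuclear_family() -> Pedigree:
    """Two founders with two offspring."""
    return Pedigree(
        [
            PedigreeRecord("F1", "dad", None, None, 1),
            PedigreeRecord("F1", "mom", None, None, 2),
            PedigreeRecord("F1", "kid1", "dad", "mom", 1),
            PedigreeRecord("F1", "kid2", "dad", "mom", 2),
        ]
    )


@pytest.fixture
def two_snv_variants() -> list[Variant]:
    return [
        Variant("v1", "1", 100, "a", "A"),
        Variant("v2", "1", 200, "b", "B"),
    ]


def make_genotypes(counts, variants=None) -> GenotypeMatrix:
    counts = np.asarray(counts, dtype=np.int8)
    q = counts.shape[1]
    if variants is None:
        variants = [
            Variant(f"v{j + 1}", "1", 100 * (j + 1), "a", "A") for j in range(q)
        ]
    ids = [f"S{i + 1}" for i in range(counts.shape[0])]
    return GenotypeMatrix(ids, variants, counts)


def kinship_oracle(pedigree: Pedigree):
    """Independent pairwise-recursive kinship (memoized, founders outbred)."""
    recs = {(r.family, r.individual): r for r in pedigree.records}
    cache: dict[tuple, float] = {}

    def depth(key):
        r = recs[key]
        if r.father is None:
            return 0
        return 1 + max(depth((r.family, r.father)), depth((r.family, r.mother)))

    def phi(a, b):
        if a[0] != b[0]:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        ra, rb = recs[a], recs[b]
        if a == b:
            if ra.father is None:
                val = 0.5
            else:
                val = 0.5 * (1 + phi((ra.family, ra.father), (ra.family, ra.mother)))
        else:
            # recurse on the individual further from the founders
            if depth(a) < depth(b):
                a, b, ra, rb = b, a, rb, ra
            if ra.father is None:
                val = 0.0
            else:
                val = 0.5 * (
                    phi((ra.family, ra.father), b) + phi((ra.family, ra.mother), b)
                )
        cache[key] = val
        return val

    ids = [(r.family, r.individual) for r in pedigree.records]
    n = len(ids)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 2.0 * phi(ids[i], ids[j])
    return out
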