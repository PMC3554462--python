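import random

import pytest

from locusconvert import GenomicInterval, IdentifierRecord, Registry


def make_random_store(rng: random.Random, n: int, chrom: str = "c", span: int = 300):
    """n random (interval, payload) pairs on one chromosome."""
    out = []
    for i in range(n):
        s = rng.randint(1, span)
        e = s + rng.randint(0, 40)
        out.append((GenomicInterval(chrom, s, e), f"id{rng.randint(0, n)}"))
    return out


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def brca2_registry():
    """One locus registered under three namespaces, plus an unrelated gene."""
    locus = GenomicInterval("chr13", 32_889_611, 32_973_805)
    reg = Registry()
    reg.register(IdentifierRecord("675", "entrez", (locus,)))
    reg.register(IdentifierRecord("ENSG00000139618", "ensembl_gene", (locus,)))
    reg.register(IdentifierRecord("NM_000059", "refseq", (locus,)))
    reg.register(
        IdentifierRecord("7157", "entrez", (GenomicInterval("chr17", 7_571_720, 7_590_868),))
    )
    return reg
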