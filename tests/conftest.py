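import numpy as np
import pytest

from capqc.digestmap import Digest, DigestMap
from capqc.enzymes import BUILTIN_ENZYMES
from capqc.pairclass import MappedRead, ReadPair


@pytest.fixture
def hindiii():
    return BUILTIN_ENZYMES["HindIII"]


@pytest.fixture
def dpnii():
    return BUILTIN_ENZYMES["DpnII"]


def make_map(bounds: dict[str, list[int]]) -> DigestMap:
    """Build a DigestMap from per-chromosome digest end coordinates.

    ``bounds["chr1"] = [400, 1200, 2000]`` yields digests (1,400),
    (401,1200), (1201,2000).
    """
    digests = []
    for chrom, ends in bounds.items():
        start = 1
        for idx, end in enumerate(ends, start=1):
            digests.append(Digest(chrom, start, end, idx, 0.5))
            start = end + 1
    return DigestMap(digests)


def mk_pair(
    chrom1, fp1, strand1, chrom2, fp2, strand2, name="p"
) -> ReadPair:
    return ReadPair(
        MappedRead(name, chrom1, fp1, strand1),
        MappedRead(name, chrom2, fp2, strand2),
    )


@pytest.fixture
def toy1_map(hindiii):
    """'ACGAAGCTTGG' digested with HindIII: digests (1,4) and (5,11)."""
    from capqc.digestmap import digest_genome

    return digest_genome([("toy1", "ACGAAGCTTGG")], [hindiii])


@pytest.fixture(scope="session")
def small_library():
    """A small simulated HindIII library shared across tests."""
    from capqc.simulate import SimConfig, simulate_library

    config = SimConfig(
        chromosome_lengths=(150_000, 150_000),
        n_valid_cis=200, n_valid_trans=200, n_self_ligated=200, n_unligated=200,
        seed=11,
    )
    return config, simulate_library(config)


def random_map(rng: np.random.Generator, n_chroms=3, mean_digest=800) -> DigestMap:
    """Random digest map with geometric-ish digest lengths."""
    bounds = {}
    for c in range(1, n_chroms + 1):
        ends, pos = [], 0
        for _ in range(rng.integers(5, 30)):
            pos += int(rng.integers(50, 2 * mean_digest))
            ends.append(pos)
        bounds[f"chr{c}"] = ends
    return make_map(bounds)
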