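import numpy as np
import pytest

from ibless.core_io import BreakProfile, GenomeSequence


@pytest.fixture
def small_genome():
    """Deterministic random 3 kb single-chromosome genome."""
    from ibless.simulate import simulate_genome

    return simulate_genome(3000, gc=0.5, seed=11)


def profile_from_positions(lengths, plus_positions=(), minus_positions=()):
    """Build a BreakProfile from explicit (chrom, pos) break lists."""
    plus = {c: np.zeros(n) for c, n in lengths.items()}
    minus = {c: np.zeros(n) for c, n in lengths.items()}
    for chrom, pos in plus_positions:
        plus[chrom][pos] += 1
    for chrom, pos in minus_positions:
        minus[chrom][pos] += 1
    return BreakProfile(plus, minus)


def write_fasta(path, chroms):
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n{seq}\n")
    return path
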