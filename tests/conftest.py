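import numpy as np
import pytest

import breakscape as bs


@pytest.fixture(scope="session")
def toy_genome() -> bs.GenomeModel:
    """Two small chromosomes for fast unit tests."""
    return bs.GenomeModel({"chrA": 10_000_000, "chrB": 5_000_000}, name="toy")


@pytest.fixture(scope="session")
def scaled_hg19() -> bs.GenomeModel:
    return bs.hg19().scaled(0.1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_track(chrom: str, log2: np.ndarray, spacing: int = 10_000, sample: str = "S") -> bs.ProbeTrack:
    """Probe track with evenly spaced probes carrying the given log2 ratios."""
    n = len(log2)
    start = np.arange(n, dtype=np.int64) * spacing
    end = start + 60
    track = bs.ProbeTrack(sample=sample)
    track.add_chromosome(chrom, start, end, np.asarray(log2, dtype=float))
    return track
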