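import numpy as np
import pytest

from stiffmorph.pipeline import analyze_dataset, profile_dataset

PAPER_SEED = 1


def make_disk(radius: int, pad: int = 2) -> np.ndarray:
    ax = np.arange(-radius - pad, radius + pad + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2


@pytest.fixture(scope="session")
def paper_run():
    """Full image-path run of the packaged paper-scale dataset (seed fixed)."""
    return profile_dataset("paper-scale", PAPER_SEED)


@pytest.fixture(scope="session")
def paper_analysis(paper_run):
    """Analysis stage (k selection, morphs, pruning, RF, stats) on that run."""
    # The dendrogram is cut at k = 3 (the workflow's final choice); the
    # validity-subsampling consensus k is still computed and reported.
    return analyze_dataset(paper_run.morphology_table, PAPER_SEED, k=3)


@pytest.fixture(scope="session")
def toy_cell():
    """A small irregular cell + nucleus + seeded marker channel (<= 25x25)."""
    rng = np.random.default_rng(11)
    cell = np.zeros((25, 25), dtype=bool)
    rr, cc = np.mgrid[0:25, 0:25]
    cell |= ((rr - 12) ** 2 / 81 + (cc - 11) ** 2 / 49) <= 1.0
    cell[5:9, 15:22] = True  # protrusion
    nucleus = ((rr - 13) ** 2 + (cc - 10) ** 2) <= 9
    channel = rng.integers(100, 5000, size=(25, 25)).astype(float)
    return cell, nucleus & cell, channel
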