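import numpy as np
import pytest

from c9screen.io import Marker, MarkerPanel


@pytest.fixture
def five_marker_panel() -> MarkerPanel:
    """Five markers at 1 kb spacing; locus between markers 2 and 3 (1-based).

    Genetic positions 0.1 cM apart so cM extents are easy to read off.
    """
    markers = [
        Marker(f"m{i + 1}", "9", 1000 * (i + 1), "A", "G", 0.2, 0.1 * i)
        for i in range(5)
    ]
    return MarkerPanel(markers=markers, locus_bp=2500, build_label="test")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_panel(rng: np.random.Generator, n_markers: int) -> MarkerPanel:
    """A small random panel with the locus placed between two random markers."""
    pos = np.sort(rng.choice(np.arange(1000, 100000), size=n_markers, replace=False))
    gpos = np.sort(rng.uniform(0, 1.0, size=n_markers))
    markers = [
        Marker(f"m{i}", "9", int(p), "A", "G", float(rng.uniform(0.05, 0.8)), float(g))
        for i, (p, g) in enumerate(zip(pos, gpos))
    ]
    locus = int(rng.integers(pos[0], pos[-1] + 1))
    return MarkerPanel(markers=markers, locus_bp=locus, build_label="rand")
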