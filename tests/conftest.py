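import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ramscreen.sequence_io import SequenceWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_window():
    """Build a SequenceWindow from a short fragment, padding with A to 2 kb."""

    def _make(fragment: str, half_width: int = 1000, pad: str = "A",
              enhancer_id="w0") -> SequenceWindow:
        total = 2 * half_width
        seq = (fragment + pad * total)[:total]
        return SequenceWindow(
            enhancer_id=enhancer_id, contig="chrT", start=0,
            sequence=seq, half_width=half_width,
        )

    return _make


def random_window(rng, half_width: int = 1000) -> SequenceWindow:
    seq = "".join(rng.choice(list("ACGT"), size=2 * half_width))
    return SequenceWindow(
        enhancer_id=int(rng.integers(1e6)), contig="chrR", start=0,
        sequence=seq, half_width=half_width,
    )


def naive_find_matches(pattern: str, window: SequenceWindow, both_strands=True):
    """Position-by-position scanning oracle, independent of the bitmask kernel."""
    from ramscreen.motifs import IUPAC_BASES, is_palindromic, reverse_complement

    def scan(pat):
        k, seq = len(pat), window.sequence
        hits = []
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in IUPAC_BASES[pat[j]] for j in range(k)):
                hits.append(i - window.half_width)
        return hits

    out = [(window.enhancer_id, r, "+") for r in scan(pattern)]
    if both_strands and not is_palindromic(pattern):
        out += [(window.enhancer_id, r, "-")
                for r in scan(reverse_complement(pattern))]
    return sorted(out)
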