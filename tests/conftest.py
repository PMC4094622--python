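import numpy as np
import pytest

from pirnascape.core import revcomp
from pirnascape.pipeline import run_pipeline


def brute_force_matches(query: str, references: dict[str, str], max_mm: int):
    """Independent O(len(query) * genome) matcher used as the oracle.

    Returns (ref, start, strand, mismatches) for every position on both
    strands with <= max_mm substitutions, no stratum filtering.
    """
    out = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for name, ref in references.items():
            for start in range(len(ref) - len(q) + 1):
                mm = sum(
                    1 for a, b in zip(q, ref[start : start + len(q)]) if a != b
                )
                if mm <= max_mm:
                    out.append((name, start, strand, mm))
    return out


def best_stratum(hits):
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted(h for h in hits if h[3] == best)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def default_run():
    """One full default-study pipeline run shared across the suite."""
    import time

    t0 = time.monotonic()
    result = run_pipeline(seed=1)
    result.elapsed_seconds = time.monotonic() - t0
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
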