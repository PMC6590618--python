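"""Shared fixtures: random valid backbones and the benchmark corpus."""

from __future__ import annotations

import numpy as np
import pytest

from sncontour.chaincode import FREEMAN_STEPS, ChainCode


def random_valid_chain(rng: np.random.Generator, n_codes: int) -> ChainCode:
    """Random single-width backbone chain code via a self-avoiding walk.

    Each step proposes Freeman codes in random order and keeps the first
    whose new pixel is distinct from, and at Chebyshev distance >= 2
    from, every pixel except its direct predecessor; dead ends restart.
    """
    while True:
        px = [(0, 0)]
        seen = {(0, 0)}
        codes: list[int] = []
        while len(codes) < n_codes:
            for c in rng.permutation(8):
                dx, dy = FREEMAN_STEPS[c]
                q = (px[-1][0] + int(dx), px[-1][1] + int(dy))
                if q in seen:
                    continue
                if any(max(abs(q[0] - p[0]), abs(q[1] - p[1])) < 2
                       for p in px[:-1]):
                    continue
                px.append(q)
                seen.add(q)
                codes.append(int(c))
                break
            else:
                break
        if len(codes) == n_codes:
            return ChainCode(np.array(codes, dtype=np.int64))


@pytest.fixture
def chain_factory():
    return random_valid_chain


@pytest.fixture(scope="session")
def benchmark_result():
    """Held-out benchmark at the package's standard protocol.

    Calibrates per resolution on the full 21-length training grid (2000
    samples per (l_c, r) case) and evaluates 4000 disjoint samples per
    reference cell; shared across acceptance tests because the corpus
    is expensive.
    """
    from sncontour.calibrate import calibrate_and_evaluate
    from sncontour.wlc import DEFAULT_LC_GRID

    return calibrate_and_evaluate(
        r_values=[5.1, 6.4, 7.7],
        lc_values=[340.0, 680.0, 1020.0],
        n_train=2000,
        n_eval=4000,
        master_seed=1,
        train_lc_values=DEFAULT_LC_GRID,
    )
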