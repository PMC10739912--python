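"""Hand-built transition tallies with closed-form absorption solutions.

These tiny chains are flow-conserving (inflow equals outflow at every
surface state) so they pass the same validation as simulated counts, and
their dressed-chain solutions are solvable by hand.
"""

from __future__ import annotations

import numpy as np

from .wos import TransitionCounts

_FIXTURES = {}


def _register(name):
    def deco(fn):
        _FIXTURES[name] = fn
        return fn
    return deco


def _counts_from_matrix(mat: np.ndarray, lam: float = 0.001) -> TransitionCounts:
    mat = np.asarray(mat, dtype=np.int64)
    M = mat.shape[0] - 2
    n_try = int(mat[0].sum())
    return TransitionCounts(
        counts=mat, block_counts=mat[None, :, :], M=M, n_try=n_try,
        config={"lam": lam, "D": 1.0, "r_b": 1.1, "M": M, "seed": 0,
                "n_try": n_try},
        body={"shape_kind": "sphere", "param_a": 1.0, "param_c": 0.0},
        source={"kind": "bulk", "n_inf": 1.0, "s": None, "phi_s": 1.0})


@_register("single_domain")
def single_domain() -> TransitionCounts:
    """One surface domain: p0 = [1], P = [[0.5]], p_esc = [0.5].

    With per-event absorption p* the dressed chain gives the geometric
    series f = p* / (1 - q* / 2); e.g. p* = 0.5 -> f = 2/3.
    """
    mat = [[0, 10, 0],
           [0, 10, 10],
           [0, 0, 0]]
    return _counts_from_matrix(mat)


@_register("two_domain_chain")
def two_domain_chain() -> TransitionCounts:
    """Two domains with unequal start weights and a common surface row.

    p0 = [0.5, 0.3, esc 0.2]; both surface rows are (2, 3, 4)/9, so
    P = [[2/9, 3/9], [2/9, 3/9]] and p_esc = [4/9, 4/9].  The dressed 2x2
    system is solvable by hand for any (p*_1, p*_2).
    """
    mat = [[0, 5, 3, 2],
           [0, 2, 3, 4],
           [0, 2, 3, 4],
           [0, 0, 0, 0]]
    return _counts_from_matrix(mat)


def make_fixture(name: str) -> TransitionCounts:
    """Build a named toy TransitionCounts for unit tests and demos."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: "
                         f"{sorted(_FIXTURES)}") from None


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)
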