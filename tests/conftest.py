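"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use different algorithms from the package: the
digestion oracle scans all substrings and validates their boundaries
(instead of concatenating fragments), and the Fisher oracle enumerates the
hypergeometric support in exact integer arithmetic (instead of floating
pmf evaluation).
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Independent oracles


def digest_oracle(
    seq: str,
    min_len: int = 7,
    max_len: int = 30,
    max_missed: int = 1,
    met_excision: bool = True,
) -> set[tuple[str, int, int, bool]]:
    """Exhaustive substring enumeration of tryptic peptides.

    A substring seq[a:b] is a valid peptide iff its C-terminus is a
    cleavage site or the protein end, its N-terminus is the protein start,
    follows a cleavage site, or is position 2 of a Met-starting protein
    (Met excision), and it contains at most ``max_missed`` internal K/R.
    Returns tuples (sequence, 1-based start, missed cleavages, met_excised).
    """
    n = len(seq)
    out = set()
    kr_prefix = [0]
    for ch in seq:  # kr_prefix[i] = number of K/R in seq[:i]
        kr_prefix.append(kr_prefix[-1] + (ch in "KR"))
    for a in range(n):
        for b in range(a + min_len, min(n, a + max_len) + 1):
            if not (b == n or seq[b - 1] in "KR"):
                continue
            internal = kr_prefix[b - 1] - kr_prefix[a]
            if internal > max_missed:
                continue
            if a == 0 or seq[a - 1] in "KR":
                out.add((seq[a:b], a + 1, internal, False))
            if met_excision and a == 1 and seq[0] == "M":
                out.add((seq[a:b], a + 1, internal, True))
    return out


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by exact integer enumeration over fixed margins.

    Table counts with equal margins are compared through their integer
    numerators C(r, k) * C(N - r, c - k); a table is included when its
    probability is at most (1 + 1e-7) times the observed one, evaluated in
    exact arithmetic as num_k * 10^7 <= num_obs * (10^7 + 1).
    """
    t = np.asarray(table, dtype=np.int64)
    a = int(t[0, 0])
    n_total = int(t.sum())
    r = int(t[0].sum())
    c = int(t[:, 0].sum())
    if r == 0 or c == 0 or r == n_total or c == n_total:
        return 1.0
    k_lo = max(0, r + c - n_total)
    k_hi = min(r, c)
    nums = [comb(r, k) * comb(n_total - r, c - k) for k in range(k_lo, k_hi + 1)]
    num_obs = nums[a - k_lo]
    total = comb(n_total, c)
    kept = sum(num for num in nums if num * 10**7 <= num_obs * (10**7 + 1))
    return kept / total


def spearman_oracle(x, y) -> float:
    """Spearman rho from the textbook rank-difference formula (no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n**2 - 1))


# ---------------------------------------------------------------------------
# Fixtures


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, max_len: int = 200) -> str:
    length = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240202)


@pytest.fixture(scope="session")
def small_study():
    """One small epitope-scenario study shared by read-only tests."""
    from pavprot import scenario_config, simulate_study

    return simulate_study(scenario_config("epitope", seed=7))
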