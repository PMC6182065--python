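import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pedigree():
    """1,2 founders; 3,4 full sibs from (1,2); 5 offspring of the full sibs."""
    return pd.DataFrame(
        {
            "animal": ["1", "2", "3", "4", "5"],
            "sire": ["0", "0", "1", "1", "3"],
            "dam": ["0", "0", "2", "2", "4"],
        }
    )


def random_pedigree(rng, n=15):
    """Random acyclic pedigree: parents drawn from earlier animals (or unknown)."""
    animals = [str(i + 1) for i in range(n)]
    sire, dam = [], []
    for i in range(n):
        pool = animals[:i]
        s = rng.choice(pool) if pool and rng.random() < 0.7 else "0"
        remaining = [a for a in pool if a != s]
        d = rng.choice(remaining) if remaining and rng.random() < 0.7 else "0"
        sire.append(s)
        dam.append(d)
    return pd.DataFrame({"animal": animals, "sire": sire, "dam": dam})


def kinship_oracle(ped: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Independent A-matrix oracle: top-down memoized coancestry recursion.

    f(i, j) for i != j (i younger) = (f(sire_i, j) + f(dam_i, j)) / 2 with
    unknown parents contributing 0; f(i, i) = (1 + f(sire_i, dam_i)) / 2.
    A = 2 f.
    """
    sire = dict(zip(ped["animal"], ped["sire"]))
    dam = dict(zip(ped["animal"], ped["dam"]))
    order = list(ped["animal"])
    pos = {a: i for i, a in enumerate(order)}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a == "0" or b == "0":
            return 0.0
        if a == b:
            return 0.5 * (1.0 + f(sire.get(a, "0"), dam.get(a, "0")))
        # recurse on the younger of the two (appears later in the table)
        if pos[a] < pos[b]:
            a, b = b, a
        return 0.5 * (f(sire.get(a, "0"), b) + f(dam.get(a, "0"), b))

    n = len(order)
    A = np.zeros((n, n))
    for i, ai in enumerate(order):
        for j, aj in enumerate(order):
            A[i, j] = 2.0 * f(ai, aj)
    return A, order


def pcit_bruteforce(R: np.ndarray) -> np.ndarray:
    """Exhaustive triple-loop PCIT oracle (mirrors the stated convention).

    For each unordered trio, the tolerance is the mean of the finite
    partial/direct ratios (zero direct correlations skipped); an edge is
    eliminated when both of its companion products bound it.
    """
    n = R.shape[0]
    mask = (R != 0)  # a zero correlation is never a significant edge
    np.fill_diagonal(mask, False)
    if n < 3:
        return mask

    def partial(rxy, rxz, ryz):
        den = (1 - rxz**2) * (1 - ryz**2)
        if den <= 0:
            return np.nan
        return (rxy - rxz * ryz) / np.sqrt(den)

    elim = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
                parts = [
                    (partial(rxy, rxz, ryz), rxy),
                    (partial(rxz, rxy, ryz), rxz),
                    (partial(ryz, rxy, rxz), ryz),
                ]
                ratios = []
                for p, d in parts:
                    if d != 0 and np.isfinite(p):
                        r = p / d
                        if np.isfinite(r):
                            ratios.append(r)
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    elim[x, y] = elim[y, x] = True
    mask &= ~elim
    return mask
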