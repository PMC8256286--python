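"""Shared fixtures and independent oracles.

The oracles here are deliberately written from scratch (frozen residue-mass
table, brute-force window scans, combinatorial tail sums) so they share no
code path with the implementation they check.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pandas as pd
import pytest

# ---------------------------------------------------------------- mass oracle
# hand-frozen monoisotopic residue masses (Da)
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_O = 18.010565
PROTON_O = 1.007276
CAM_O = 57.02146


def oracle_peptide_mass(seq: str, cam: bool = True) -> float:
    m = sum(RESIDUE_MONO[a] for a in seq) + WATER_O
    if cam:
        m += CAM_O * seq.count("C")
    return m


def oracle_by_ions(seq: str, cam: bool = True) -> dict[str, float]:
    """Singly protonated b/y ions from the frozen table."""
    res = [RESIDUE_MONO[a] + (CAM_O if cam and a == "C" else 0.0) for a in seq]
    out = {}
    for i in range(1, len(seq)):
        out[f"b{i}"] = sum(res[:i]) + PROTON_O
        out[f"y{i}"] = sum(res[-i:]) + WATER_O + PROTON_O
    return out


# --------------------------------------------------------------- motif oracle
def oracle_scan(seq: str) -> list[tuple[int, str]]:
    """Every-window brute force: (1-based position, kind) pairs."""
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    seq = seq.upper()
    hits = []
    for i in range(len(seq)):
        if i + 3 >= len(seq):
            break
        window = seq[i : i + 4]
        if any(ch not in standard for ch in window):
            continue
        if window[0] == "W" and window[3] == "W":
            hits.append((i + 1, "WxxW"))
        elif window[0] == "W" and window[3] == "C":
            hits.append((i + 1, "WxxC"))
    return hits


# ----------------------------------------------------------- hypergeom oracle
def oracle_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n), by explicit tail summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


# ------------------------------------------------------------------ fixtures
@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


def random_peptide(rng, min_len=2, max_len=25, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


@pytest.fixture
def toy_design():
    """Small design: 3 WT replicates, one KO with two clones of 2."""
    from cmannose import Design

    return Design(
        wt=("WT_1", "WT_2", "WT_3"),
        ko={"KO": {"C1": ("KO_C1_1", "KO_C1_2"), "C2": ("KO_C2_1", "KO_C2_2")}},
    )


@pytest.fixture
def toy_matrix(toy_design):
    """Hand-traced 6-group fixture: one survivor of the sequential filters.

    G1 contaminant, G2 reverse, G3 not extracellular, G4 single peptide,
    G5 detected only once, G6 clean.
    """
    from cmannose import LfqMatrix

    cols = list(toy_design.all_samples)
    full = [1e6] * len(cols)
    once = [1e6] + [np.nan] * (len(cols) - 1)
    intens = pd.DataFrame(
        [full, full, full, full, once, full],
        index=["G1", "G2", "G3", "G4", "G5", "G6"],
        columns=cols,
        dtype=float,
    )
    meta = pd.DataFrame(
        {
            "members": [("P1",), ("P2",), ("P3",), ("P4",), ("P5",), ("P6",)],
            "peptides": [5, 5, 5, 1, 5, 5],
            "contaminant": [True, False, False, False, False, False],
            "reverse": [False, True, False, False, False, False],
            "only_by_site": [False] * 6,
        },
        index=intens.index,
    )
    gocc = {
        "P1": frozenset({"extracellular region"}),
        "P2": frozenset({"extracellular region"}),
        "P4": frozenset({"extracellular space"}),
        "P5": frozenset({"extracellular matrix"}),
        "P6": frozenset({"extracellular region"}),
        # P3 annotated, but not extracellular
        "P3": frozenset({"cytoplasm"}),
    }
    return LfqMatrix(intens, meta, toy_design), gocc
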