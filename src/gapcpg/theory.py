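"""Analytic gap-current treatment: group-count prediction and connectivity
expectations.

On an infinite square lattice where every neuron connects with probability C
to each neuron within radius R through a junction of conductance g, and
every connected pair is assigned the same nominal voltage differential dV,
the population-average total gap-junction current is the product

    <I_gap,total> = C * N(R) * g * dV,

with N(R) the number of lattice sites within radius R of a site.  The
simulations place the boundaries between ungrouped / 3-group / 2-group /
1-group firing at average total currents of 0.09, 0.1 and 0.3 nA, so this
product maps any (C, R) pair to a predicted group count.  The cutoffs are
read off simulations, which makes the treatment explanatory rather than
predictive — they are inputs here.

Two unit modes are provided because the printed constants are mutually
inconsistent: "as_printed" uses g = 0.003 uS and dV = 0.3 V (0.9 nA per
junction), while the default "normalized" mode sets g*dV = 1/N_T nA so that
all-to-all coverage of the N_T neurons yields exactly 1.0 nA — the only
anchor consistent with the stated maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TheoryConstants",
    "neurons_within_radius",
    "avg_total_gap_current",
    "predict_group_count",
    "expected_connectivity",
    "prediction_grid",
]

DEFAULT_CUTOFFS = (0.09, 0.1, 0.3)  # nA: ungrouped | 3 | 2 | 1 groups


@dataclass(frozen=True)
class TheoryConstants:
    """Constants of the average-gap-current predictor.

    ``g`` (uS) and ``dV`` (V) are used verbatim in "as_printed" mode; in
    "normalized" mode the per-junction product is replaced by 1/n_total nA.
    """

    g: float = 0.003
    dV: float = 0.3
    cutoffs: tuple = DEFAULT_CUTOFFS
    n_total: int = 100
    mode: str = "normalized"

    def __post_init__(self) -> None:
        if self.g < 0 or self.dV < 0:
            raise ValueError("g and dV must be non-negative")
        if list(self.cutoffs) != sorted(self.cutoffs) or \
                len(set(self.cutoffs)) != len(self.cutoffs):
            raise ValueError("cutoffs must be strictly increasing")
        if self.mode not in ("normalized", "as_printed"):
            raise ValueError("mode must be 'normalized' or 'as_printed'")

    @property
    def per_junction_current(self) -> float:
        """Nominal current g*dV of one junction, in nA.

        as_printed: g [uS] times dV [V] is 0.9 nA per junction at the
        defaults; normalized: 1/n_total nA, the value that makes the
        all-to-all limit exactly 1 nA.
        """
        if self.mode == "normalized":
            return 1.0 / self.n_total
        return self.g * self.dV * 1000.0  # uS x V = 1000 nA


def neurons_within_radius(R: float) -> int:
    """Lattice sites within Euclidean distance R of a site, excluding it.

    Brute-force count over the bounding box of an infinite unit-spaced
    square lattice; R = 5 gives 80.
    """
    if R < 0:
        raise ValueError("R must be non-negative")
    m = int(math.floor(R))
    dx, dy = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1))
    inside = dx * dx + dy * dy <= R * R + 1e-12
    return int(inside.sum()) - 1  # exclude the origin


def avg_total_gap_current(C_prob: float, R: float | None,
                          constants: TheoryConstants = TheoryConstants()
                          ) -> float:
    """Population-average total gap current C * N(R) * g * dV in nA.

    ``R = None`` (or infinity) means all-to-all coverage, N = n_total, so
    normalized mode with C = 1 returns exactly 1.0 nA.
    """
    if not 0.0 <= C_prob <= 1.0:
        raise ValueError("C_prob must be in [0, 1]")
    if R is None or math.isinf(R):
        n_i = constants.n_total
    else:
        n_i = neurons_within_radius(R)
    return C_prob * n_i * constants.per_junction_current


def predict_group_count(I_avg: float,
                        cutoffs: tuple = DEFAULT_CUTOFFS) -> int:
    """Group count predicted from the average total gap current.

    Below the first cutoff firing is ungrouped (0); then 3, then 2 groups;
    above the last cutoff the whole population synchronizes into 1 group.
    Values exactly at a cutoff fall in the lower regime.
    """
    if I_avg < 0:
        raise ValueError("I_avg must be non-negative")
    c_ungrouped, c3, c2 = cutoffs
    if I_avg <= c_ungrouped:
        return 0
    if I_avg <= c3:
        return 3
    if I_avg <= c2:
        return 2
    return 1


def expected_connectivity(C_prob: float, S1: int, S2: int) -> dict:
    """Expected edge counts and connection fractions for a two-group split.

    For groups of sizes S1, S2 under per-pair wiring probability C, the
    expected counts are C(S1^2-S1)/2 within group 1, C(S2^2-S2)/2 within
    group 2, and C*S1*S2/2 in each direction between the groups.  The
    fraction table gives, for each receiving group, the share of its
    connections coming from each group; rows sum to one.  The larger group
    always has the larger internal share — the basis of the driver/follower
    asymmetry.
    """
    if S1 < 1 or S2 < 1:
        raise ValueError("group sizes must be >= 1")
    counts = {
        ("to_1", "from_1"): C_prob * (S1 ** 2 - S1) / 2.0,
        ("to_1", "from_2"): C_prob * S1 * S2 / 2.0,
        ("to_2", "from_1"): C_prob * S1 * S2 / 2.0,
        ("to_2", "from_2"): C_prob * (S2 ** 2 - S2) / 2.0,
    }
    denom = S1 + S2 - 1
    fractions = {
        ("to_1", "from_1"): (S1 - 1) / denom,
        ("to_1", "from_2"): S2 / denom,
        ("to_2", "from_1"): S1 / denom,
        ("to_2", "from_2"): (S2 - 1) / denom,
    }
    return {"counts": counts, "fractions": fractions}


def prediction_grid(C_values, R_values,
                    constants: TheoryConstants = TheoryConstants()
                    ) -> pd.DataFrame:
    """Predicted group count over a (connection probability, radius) grid.

    One row per (C, R) cell with the average total gap current and the
    predicted number of firing groups — the theoretical phase map.
    """
    rows = []
    for C in C_values:
        for R in R_values:
            I = avg_total_gap_current(C, R, constants)
            rows.append({"C_prob": C, "R": R, "I_avg_nA": I,
                         "predicted_groups":
                         predict_group_count(I, constants.cutoffs)})
    return pd.DataFrame(rows)
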