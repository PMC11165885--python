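"""Criterion weighting by the Analytic Hierarchy Process (AHP).

Each group compares every pair of weighted criteria on the Saaty 1–9
ratio scale (1 = equal importance, 9 = extreme importance; reciprocals
1/2 … 1/9 when the second criterion dominates). Only the upper triangle
is elicited — n(n−1)/2 judgments for n criteria — and the full positive
reciprocal matrix (n² cells: 9 for the 3-criterion risk stream, 16 for
the 4-criterion disease stream) is expanded from it, which keeps the
reciprocal identity a_ij·a_ji = 1 exact by construction.

Weights are the principal right eigenvector of the judgment matrix
(power iteration; guaranteed to converge for positive matrices by
Perron–Frobenius), normalised to sum 1; the row-geometric-mean method is
available as an alternative and agrees with the eigenvector on every
consistent matrix.

Consistency diagnostics follow the classic scheme: λmax is estimated as
the mean of (A·w)_i / w_i, the consistency index is
CI = (λmax − n)/(n − 1), and the consistency ratio CR = CI/RI(n) uses
Saaty's random-index table (RI(3)=0.58, RI(4)=0.90). CR > 0.10 flags the
matrix as unreliable; by default this is a prominent warning rather than
a hard failure, because live workshops resolve disagreement by consensus
rather than by re-elicitation. A strict mode upgrades it to an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

#: admissible judgment values: integers 1..9 and exact reciprocals 1/2..1/9
SCALE: tuple[Fraction, ...] = tuple(
    sorted([Fraction(k) for k in range(1, 10)]
           + [Fraction(1, k) for k in range(2, 10)])
)

#: Saaty random-index table; RI(n) for n <= 2 is 0 by convention
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: conventional acceptability threshold on the consistency ratio
CR_THRESHOLD = 0.10

POWER_TOL = 1e-12
POWER_MAX_ITER = 10_000


def parse_judgment(text: str) -> Fraction:
    """Parse a judgment value written as an integer or '1/k'; validate scale."""
    s = str(text).strip()
    try:
        if "/" in s:
            num, den = s.split("/")
            value = Fraction(int(num), int(den))
        else:
            value = Fraction(int(s))
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"judgment value '{text}' is not an integer or '1/k'") from exc
    if value not in SCALE:
        raise ValueError(
            f"judgment value '{text}' outside the admissible 1-9 scale "
            "(integers 1..9 or reciprocals 1/2..1/9)"
        )
    return value


def format_judgment(value: Fraction) -> str:
    return str(value.numerator) if value.denominator == 1 else \
        f"{value.numerator}/{value.denominator}"


@dataclass
class JudgmentSet:
    """Upper-triangle pairwise judgments of one group for one stream.

    Keys are (criterion_i, criterion_j) with i preceding j in catalogue
    order; the value states how much more important i is than j.
    """

    group: str
    stream: str
    judgments: dict[tuple[str, str], Fraction]


@dataclass
class JudgmentMatrix:
    """Full positive reciprocal matrix with exact rational entries."""

    criteria: list[str]
    entries: list[list[Fraction]]

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def n_cells(self) -> int:
        return self.n * self.n

    def to_array(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.entries],
                        dtype=float)


@dataclass
class WeightVector:
    criteria: list[str]
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float
    inconsistent: bool  # True when CR > CR_THRESHOLD
    method: str
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.criteria, self.weights.tolist()))


def expand_matrix(jset: JudgmentSet, criteria_order: list[str]) -> JudgmentMatrix:
    """Expand elicited upper-triangle judgments into the full n×n matrix.

    Diagonal is 1; the lower triangle is the exact reciprocal of the
    stored upper triangle. Missing or surplus pairs are errors.
    """
    n = len(criteria_order)
    index = {c: i for i, c in enumerate(criteria_order)}
    expected_pairs = {
        (criteria_order[i], criteria_order[j])
        for i in range(n) for j in range(i + 1, n)
    }
    given = set(jset.judgments)
    missing = expected_pairs - given
    if missing:
        pair = sorted(missing)[0]
        raise ValueError(
            f"group '{jset.group}' ({jset.stream}): missing judgment for "
            f"pair {pair} ({len(missing)} of {len(expected_pairs)} missing)"
        )
    surplus = given - expected_pairs
    if surplus:
        raise ValueError(
            f"group '{jset.group}' ({jset.stream}): unexpected judgment "
            f"pair(s) {sorted(surplus)}"
        )
    entries = [[Fraction(1)] * n for _ in range(n)]
    for (ci, cj), v in jset.judgments.items():
        if v not in SCALE:
            raise ValueError(
                f"group '{jset.group}': judgment {ci} vs {cj} = {v} outside scale"
            )
        i, j = index[ci], index[cj]
        entries[i][j] = v
        entries[j][i] = 1 / v
    return JudgmentMatrix(list(criteria_order), entries)


def _check_matrix(matrix: JudgmentMatrix) -> None:
    n = matrix.n
    for i in range(n):
        if matrix.entries[i][i] != 1:
            raise ValueError(f"diagonal entry a[{i}][{i}] != 1")
        for j in range(n):
            if matrix.entries[i][j] <= 0:
                raise ValueError(f"non-positive entry a[{i}][{j}]")
            if matrix.entries[i][j] * matrix.entries[j][i] != 1:
                raise ValueError(f"reciprocity violated at ({i},{j})")


def consistency(matrix: JudgmentMatrix, weights: np.ndarray,
                ri_table: dict[int, float] | None = None,
                ) -> tuple[float, float, float, bool, list[str]]:
    """λmax, CI, CR and the CR>0.1 flag for weights extracted from *matrix*.

    λmax is the mean over rows of (A·w)_i / w_i — exact for the principal
    eigenvector, and the standard estimate for geometric-mean weights.
    """
    ri_table = RANDOM_INDEX if ri_table is None else ri_table
    a = matrix.to_array()
    n = matrix.n
    notes: list[str] = []
    lambda_max = float(np.mean((a @ weights) / weights))
    if n < 3:
        notes.append("consistency is trivial for n < 3; CR reported as 0")
        return lambda_max, 0.0, 0.0, False, notes
    ci = (lambda_max - n) / (n - 1)
    cr = ci / ri_table[n]
    flagged = cr > CR_THRESHOLD
    if flagged:
        notes.append(
            f"consistency ratio {cr:.3f} exceeds {CR_THRESHOLD}; judgments "
            "should be revisited or resolved by consensus"
        )
    return lambda_max, ci, cr, flagged, notes


def compute_weights(matrix: JudgmentMatrix, method: str = "eigenvector",
                    ri_table: dict[int, float] | None = None) -> WeightVector:
    """Extract criterion weights from a reciprocal judgment matrix.

    ``eigenvector`` (default): principal right eigenvector via power
    iteration. ``geometric-mean``: normalised row geometric means. Both
    return positive weights summing to 1, with consistency diagnostics.
    """
    _check_matrix(matrix)
    a = matrix.to_array()
    n = matrix.n
    if method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(POWER_MAX_ITER):
            w_new = a @ w
            w_new /= w_new.sum()
            if np.max(np.abs(w_new - w)) < POWER_TOL:
                w = w_new
                break
            w = w_new
        else:
            raise RuntimeError(
                f"power iteration did not converge in {POWER_MAX_ITER} iterations"
            )
    elif method == "geometric-mean":
        w = np.exp(np.mean(np.log(a), axis=1))
        w /= w.sum()
    else:
        raise ValueError(f"unknown weight method '{method}'")
    lambda_max, ci, cr, flagged, notes = consistency(matrix, w, ri_table)
    return WeightVector(list(matrix.criteria), w, lambda_max, ci, cr,
                        flagged, method, notes)
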