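"""Partition scheme, screening subproblems, and pattern basis functions.

A *pattern* is a product of up to three binary predictors (or the constant
1); it takes the value 1 on a subject exactly when all of its constituent
variables equal 1.  The logistic model is expressed in this pattern basis.
To make the full basis tractable for large ``p``, the variables are divided
into ``k`` partitions of ``g`` variables each, and each screening subproblem
only carries the patterns whose variables fall in a small group of
partitions; together the subproblems cover every pattern up to the working
order at least once (pairs and triples exactly once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BinaryDataset",
    "Pattern",
    "PartitionScheme",
    "SubproblemSpec",
    "DesignMatrix",
    "CoverageReport",
    "CONSTANT",
    "make_partition",
    "enumerate_subproblems",
    "patterns_for_subproblem",
    "pattern_count",
    "enumerate_all_patterns",
    "build_design",
    "verify_coverage",
]

#: Largest pattern list a single call will materialize.
DEFAULT_PATTERN_CAP = 5_000_000


@dataclass(frozen=True, order=True)
class Pattern:
    """A basis function: the product of 0-3 binary variables.

    ``variables`` holds 0-based column indices, strictly increasing.  The
    empty tuple is the constant basis ``B == 1``.
    """

    variables: tuple[int, ...]

    def __post_init__(self) -> None:
        v = tuple(int(i) for i in self.variables)
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"pattern variables must be strictly increasing: {v}")
        if any(i < 0 for i in v):
            raise ValueError(f"pattern variables must be non-negative: {v}")
        if len(v) > 3:
            raise ValueError("patterns of order > 3 are not supported")
        object.__setattr__(self, "variables", v)

    @property
    def order(self) -> int:
        return len(self.variables)

    @property
    def is_constant(self) -> bool:
        return not self.variables

    def label(self) -> str:
        """Human-readable 1-based label, e.g. ``X50`` or ``X150*X250``."""
        if self.is_constant:
            return "1"
        return "*".join(f"X{i + 1}" for i in self.variables)

    @classmethod
    def from_label(cls, text: str) -> "Pattern":
        text = text.strip()
        if text in ("1", ""):
            return cls(())
        parts = text.split("*")
        idx = []
        for part in parts:
            part = part.strip()
            if not part.startswith("X"):
                raise ValueError(f"cannot parse pattern term {part!r}")
            idx.append(int(part[1:]) - 1)
        return cls(tuple(sorted(idx)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label()


CONSTANT = Pattern(())


@dataclass
class BinaryDataset:
    """Subjects-by-variables binary data with a binary response."""

    y: np.ndarray
    X: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.ascontiguousarray(np.asarray(self.y).ravel(), dtype=np.float64)
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one subject and one variable")
        if self.y.shape[0] != n:
            raise ValueError("response length does not match X")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("response entries must be 0/1")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("predictor entries must be 0/1")
        if not self.names:
            self.names = [f"X{j + 1}" for j in range(p)]
        if len(self.names) != p:
            raise ValueError("names length does not match X")
        if len(set(self.names)) != p:
            raise ValueError("variable names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PartitionScheme:
    """Contiguous blocking of ``p`` variables into ``k`` partitions.

    Partition labels run 1..k.  Every partition has ``g`` variables except
    possibly the last, which may be smaller when ``p`` is not divisible.
    """

    p: int
    g: int

    @property
    def k(self) -> int:
        return -(-self.p // self.g)

    def label_of(self, j: int) -> int:
        """Partition label (1-based) of variable index ``j`` (0-based)."""
        if not 0 <= j < self.p:
            raise IndexError(f"variable index {j} out of range for p={self.p}")
        return j // self.g + 1

    def members(self, s: int) -> range:
        """0-based variable indices in partition ``s`` (1-based label)."""
        if not 1 <= s <= self.k:
            raise IndexError(f"partition label {s} out of range for k={self.k}")
        lo = (s - 1) * self.g
        return range(lo, min(lo + self.g, self.p))

    def size(self, s: int) -> int:
        return len(self.members(s))


def make_partition(p: int, g: int) -> PartitionScheme:
    """Divide ``p`` variables into contiguous partitions of size ``g``."""
    if p <= 0 or g <= 0:
        raise ValueError(f"p and g must be positive (got p={p}, g={g})")
    return PartitionScheme(p=int(p), g=int(min(g, p)))


# Type tags for screening subproblems.  For order 2 a subproblem is either a
# pair of distinct partitions ("cross-pair") or a single partition
# ("within").  For order 3 the four tags name the equality pattern of the
# sorted partition-label triple.
Q2_TAGS = ("cross-pair", "within")
Q3_TAGS = ("s1<s2<s3", "s1=s2<s3", "s1<s2=s3", "s1=s2=s3")


@dataclass(frozen=True, order=True)
class SubproblemSpec:
    order: int
    type_tag: str
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("subproblem order must be 2 or 3")
        if list(self.labels) != sorted(self.labels):
            raise ValueError("labels must be sorted non-decreasing")
        valid = Q2_TAGS if self.order == 2 else Q3_TAGS
        if self.type_tag not in valid:
            raise ValueError(f"unknown type tag {self.type_tag!r} for order {self.order}")

    def id(self) -> str:
        return f"q{self.order}:{self.type_tag}:" + ",".join(map(str, self.labels))


def _q3_tag(labels: tuple[int, int, int]) -> str:
    a, b, c = labels
    if a == b == c:
        return "s1=s2=s3"
    if a == b:
        return "s1=s2<s3"
    if b == c:
        return "s1<s2=s3"
    return "s1<s2<s3"


def enumerate_subproblems(scheme: PartitionScheme, order: int) -> list[SubproblemSpec]:
    """All screening subproblems for a scheme, in lexicographic label order.

    Order 2: one spec per unordered pair of distinct partitions plus one
    per single partition.  Order 3: one spec per size-3 multiset of
    partition labels, tagged by its equality pattern.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    k = scheme.k
    specs: list[SubproblemSpec] = []
    if order == 2:
        for s1, s2 in itertools.combinations(range(1, k + 1), 2):
            specs.append(SubproblemSpec(2, "cross-pair", (s1, s2)))
        for s in range(1, k + 1):
            specs.append(SubproblemSpec(2, "within", (s,)))
    else:
        for labels in itertools.combinations_with_replacement(range(1, k + 1), 3):
            specs.append(SubproblemSpec(3, _q3_tag(labels), labels))
    specs.sort(key=lambda sp: (sp.labels, sp.type_tag))
    return specs


def _pairs_within(members: Sequence[int]) -> Iterable[tuple[int, ...]]:
    return itertools.combinations(members, 2)


def patterns_for_subproblem(
    spec: SubproblemSpec, scheme: PartitionScheme, cap: int = DEFAULT_PATTERN_CAP
) -> list[Pattern]:
    """Pattern list of one screening subproblem (constant basis included).

    Order 2, cross-pair (s1, s2): the constant, the mains of both
    partitions, and all g*g products of one variable from each — in total
    g^2 + 2g + 1 patterns for equal partition sizes g.  Order 2, within
    (s,): the constant, the mains of s, and all within-partition pairs —
    1 + g(g+1)/2 patterns.

    Order 3 subproblems carry all size-3 products whose sorted
    partition-label multiset equals ``spec.labels``; lower-order patterns
    are attached to exactly one subproblem so that the whole enumeration
    covers each subset exactly once: mains and within-partition pairs sit
    in the (s,s,s) subproblem, and a cross-pair {a,b} with a<b sits in the
    (a,a,b) subproblem.
    """
    out: list[Pattern] = [CONSTANT]
    if spec.order == 2:
        if spec.type_tag == "cross-pair":
            s1, s2 = spec.labels
            m1, m2 = scheme.members(s1), scheme.members(s2)
            _check_cap(1 + len(m1) + len(m2) + len(m1) * len(m2), cap)
            out.extend(Pattern((j,)) for j in m1)
            out.extend(Pattern((j,)) for j in m2)
            out.extend(Pattern((a, b)) for a in m1 for b in m2)
        else:
            (s,) = spec.labels
            m = scheme.members(s)
            _check_cap(1 + len(m) + comb(len(m), 2), cap)
            out.extend(Pattern((j,)) for j in m)
            out.extend(Pattern(pair) for pair in _pairs_within(m))
        return out

    a, b, c = spec.labels
    tag = spec.type_tag
    ma, mb, mc = (scheme.members(s) for s in (a, b, c))
    if tag == "s1=s2=s3":
        m = ma
        _check_cap(1 + len(m) + comb(len(m), 2) + comb(len(m), 3), cap)
        out.extend(Pattern((j,)) for j in m)
        out.extend(Pattern(pair) for pair in _pairs_within(m))
        out.extend(Pattern(t) for t in itertools.combinations(m, 3))
    elif tag == "s1=s2<s3":
        # triples {i<j in a} x {l in c}; plus the cross-pairs {a, c}
        _check_cap(1 + len(ma) * len(mc) + comb(len(ma), 2) * len(mc), cap)
        out.extend(Pattern((i, l)) for i in ma for l in mc)
        out.extend(
            Pattern((i, j, l)) for i, j in _pairs_within(ma) for l in mc
        )
    elif tag == "s1<s2=s3":
        _check_cap(1 + len(ma) * comb(len(mb), 2), cap)
        out.extend(
            Pattern((i, j, l)) for i in ma for j, l in _pairs_within(mb)
        )
    else:  # s1<s2<s3
        _check_cap(1 + len(ma) * len(mb) * len(mc), cap)
        out.extend(
            Pattern((i, j, l)) for i in ma for j in mb for l in mc
        )
    return out


def _check_cap(count: int, cap: int) -> None:
    if count > cap:
        raise ValueError(
            f"refusing to materialize {count} patterns (cap {cap}); "
            "reduce the partition size g"
        )


def pattern_count(p: int, q: int) -> int:
    """Number of patterns up to order ``q`` on ``p`` variables.

    Equals ``sum(comb(p, v) for v in 0..q)``; for q=2 this is
    ``1 + p(p+1)/2``.
    """
    if q not in (1, 2, 3):
        raise ValueError("q must be 1, 2 or 3")
    return sum(comb(p, v) for v in range(q + 1))


def enumerate_all_patterns(
    p: int, order: int, cap: int = DEFAULT_PATTERN_CAP
) -> list[Pattern]:
    """All patterns up to ``order`` on ``p`` variables, constant first."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if p <= 0:
        raise ValueError("p must be positive")
    total = pattern_count(p, order)
    _check_cap(total, cap)
    out = [CONSTANT]
    for nu in range(1, order + 1):
        out.extend(Pattern(t) for t in itertools.combinations(range(p), nu))
    return out


@dataclass
class DesignMatrix:
    """Pattern design: binary columns, one per pattern, constant included."""

    columns: list[Pattern]
    values: sp.csc_matrix
    orders: np.ndarray  # order of each column (0 for the constant)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def constant_index(self) -> int:
        return int(np.flatnonzero(self.orders == 0)[0])

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


def build_design(data: BinaryDataset, patterns: Sequence[Pattern]) -> DesignMatrix:
    """Evaluate each pattern on every subject.

    Column ``l`` at row ``i`` is the product of the pattern's variables at
    subject ``i``; the constant pattern yields an all-ones column.  There
    must be exactly one constant pattern in the list.
    """
    patterns = list(patterns)
    if sum(pat.is_constant for pat in patterns) != 1:
        raise ValueError("pattern list must contain exactly one constant pattern")
    if len(set(patterns)) != len(patterns):
        raise ValueError("duplicate patterns in design")
    n, p = data.X.shape
    for pat in patterns:
        if pat.variables and pat.variables[-1] >= p:
            raise IndexError(f"pattern {pat.label()} out of range for p={p}")
    # Build column-major dense 0/1 values, then the CSC structure directly
    # (data are implicit ones).
    dense = np.empty((len(patterns), n), dtype=np.uint8)
    X = data.X.astype(np.uint8, copy=False)
    for col, pat in enumerate(patterns):
        if pat.is_constant:
            dense[col] = 1
        else:
            v = X[:, pat.variables[0]]
            for j in pat.variables[1:]:
                v = v & X[:, j]
            dense[col] = v
    cols, rows = np.nonzero(dense)
    indptr = np.zeros(len(patterns) + 1, dtype=np.int64)
    np.cumsum(np.bincount(cols, minlength=len(patterns)), out=indptr[1:])
    values = sp.csc_matrix(
        (np.ones(rows.shape[0]), rows.astype(np.int32), indptr),
        shape=(n, len(patterns)),
    )
    orders = np.array([pat.order for pat in patterns], dtype=np.int64)
    return DesignMatrix(columns=patterns, values=values, orders=orders)


@dataclass
class CoverageReport:
    """Which variable subsets the screening enumeration covers, and how often."""

    order: int
    main_multiplicity: dict[int, int]
    pair_multiplicity: dict[tuple[int, int], int]
    triple_multiplicity: dict[tuple[int, int, int], int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_coverage(scheme: PartitionScheme, order: int) -> CoverageReport:
    """Check the exactly-once coverage of pairs (and triples for q=3).

    Every variable must appear as a main effect in at least one subproblem,
    every unordered pair in exactly one, and, for order 3, every unordered
    triple in exactly one.
    """
    p = scheme.p
    mains: dict[int, int] = {j: 0 for j in range(p)}
    pairs: dict[tuple[int, int], int] = {}
    triples: dict[tuple[int, int, int], int] = {}
    for spec in enumerate_subproblems(scheme, order):
        for pat in patterns_for_subproblem(spec, scheme):
            if pat.order == 1:
                mains[pat.variables[0]] += 1
            elif pat.order == 2:
                pairs[pat.variables] = pairs.get(pat.variables, 0) + 1
            elif pat.order == 3:
                triples[pat.variables] = triples.get(pat.variables, 0) + 1
    violations: list[str] = []
    for j, m in mains.items():
        if m < 1:
            violations.append(f"main X{j + 1} never covered")
    for pair in itertools.combinations(range(p), 2):
        m = pairs.get(pair, 0)
        if m != 1:
            violations.append(f"pair {pair} covered {m} times")
    if order == 3:
        for t in itertools.combinations(range(p), 3):
            m = triples.get(t, 0)
            if m != 1:
                violations.append(f"triple {t} covered {m} times")
    return CoverageReport(
        order=order,
        main_multiplicity=mains,
        pair_multiplicity=pairs,
        triple_multiplicity=triples,
        violations=violations,
    )
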