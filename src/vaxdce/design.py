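"""Experimental design for discrete choice experiments.

A DCE presents respondents with repeated choice tasks, each offering a
small number of hypothetical alternatives ("profiles") described by
attributes with discrete levels, usually alongside an opt-out.  This
module builds the design side of such a study:

* :class:`AttributeSpec` / :class:`StudyDesignSpec` — the attribute/level
  universe and task structure;
* :func:`enumerate_full_factorial` — every possible profile;
* :func:`build_choice_design` — an orthogonal main-effects choice design
  (one task per run of a strength-2 orthogonal array, second alternative
  by a level-shift pairing rule);
* :func:`block_design` — partition tasks into questionnaire versions;
* :func:`design_diagnostics` — balance/orthogonality quality control;
* :func:`johnson_orme_min_n` — the Johnson–Orme sample-size rule of thumb.

Orthogonal arrays are generated from scratch for run sizes that are
powers of two: a factor with 2^k levels is represented by a k-dimensional
subspace of GF(2)^m characters, and pairwise trivially-intersecting
subspaces yield a strength-2 (main-effects orthogonal) array.  This
covers the mixed 4/2-level structures typical of vaccine DCEs.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignInfeasibleError, InvalidSpecError

CATEGORICAL = "categorical-dummy"
CONTINUOUS = "continuous"

CONSTANT_NAME = "const"
OPTOUT_ID = "optout"


def _slug(text: str) -> str:
    return re.sub(r"\W+", "_", str(text)).strip("_")


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of a choice alternative.

    Parameters
    ----------
    name:
        Text label, unique within a study.
    levels:
        Ordered level labels (at least two, unique).
    coding:
        ``"categorical-dummy"`` (indicator per non-reference level) or
        ``"continuous"`` (a single numeric column).
    reference_level:
        For categorical attributes, the omitted level (defaults to the
        first level).
    numeric_values:
        For continuous attributes, one numeric value per level (e.g.
        prices in CN¥).
    """

    name: str
    levels: tuple[str, ...]
    coding: str = CATEGORICAL
    reference_level: str | None = None
    numeric_values: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if len(self.levels) < 2:
            raise InvalidSpecError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise InvalidSpecError(f"attribute {self.name!r} has duplicate levels")
        if self.coding not in (CATEGORICAL, CONTINUOUS):
            raise InvalidSpecError(f"unknown coding {self.coding!r}")
        if self.coding == CATEGORICAL:
            ref = self.reference_level if self.reference_level is not None else self.levels[0]
            if ref not in self.levels:
                raise InvalidSpecError(
                    f"reference level {ref!r} not among levels of {self.name!r}"
                )
            object.__setattr__(self, "reference_level", str(ref))
        else:
            if self.numeric_values is None or len(self.numeric_values) != len(self.levels):
                raise InvalidSpecError(
                    f"continuous attribute {self.name!r} needs one numeric value per level"
                )
            object.__setattr__(
                self, "numeric_values", tuple(float(v) for v in self.numeric_values)
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(str(level))
        except ValueError:
            raise InvalidSpecError(f"unknown level {level!r} for attribute {self.name!r}")

    def numeric_value(self, level: str) -> float:
        if self.coding != CONTINUOUS:
            raise InvalidSpecError(f"attribute {self.name!r} is not continuous")
        return self.numeric_values[self.level_index(level)]

    def column_names(self) -> list[str]:
        """Model-matrix column names this attribute contributes, in level order."""
        if self.coding == CONTINUOUS:
            return [_slug(self.name)]
        return [
            f"{_slug(self.name)}_{_slug(lv)}"
            for lv in self.levels
            if lv != self.reference_level
        ]

    def dummy_columns(self) -> list[tuple[str, str]]:
        """(level, column name) pairs for the non-reference levels."""
        if self.coding == CONTINUOUS:
            return []
        return [
            (lv, f"{_slug(self.name)}_{_slug(lv)}")
            for lv in self.levels
            if lv != self.reference_level
        ]


@dataclass(frozen=True)
class StudyDesignSpec:
    """The attribute universe and task structure of a DCE study."""

    attributes: tuple[AttributeSpec, ...]
    n_alternatives_per_task: int = 2
    include_optout: bool = True
    n_tasks: int = 32
    n_blocks: int = 4

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if not self.attributes:
            raise InvalidSpecError("study needs at least one attribute")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise InvalidSpecError("attribute names must be unique")
        if self.n_alternatives_per_task < 2:
            raise InvalidSpecError("need >=2 designed alternatives per task")
        if self.n_tasks % self.n_blocks != 0:
            raise InvalidSpecError(
                f"n_tasks={self.n_tasks} not divisible by n_blocks={self.n_blocks}"
            )

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise InvalidSpecError(f"no attribute named {name!r}")

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def coefficient_columns(self, include_constant: bool = True) -> list[str]:
        """Ordered model-matrix columns: constant, dummies, then continuous terms.

        Dummy columns follow the attribute order of the spec and the level
        order within each attribute; continuous attributes (price) come in
        spec order after their categorical position.  The resulting order is
        fixed and shared by the coder, the simulator and the estimator.
        """
        cols = [CONSTANT_NAME] if include_constant else []
        for a in self.attributes:
            cols.extend(a.column_names())
        return cols

    @property
    def n_profiles(self) -> int:
        return math.prod(a.n_levels for a in self.attributes)


@dataclass(frozen=True)
class Profile:
    """One fully-specified alternative: a level for every attribute."""

    assignment: tuple[tuple[str, str], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Profile":
        return cls(tuple((str(k), str(v)) for k, v in mapping.items()))

    def level(self, attribute: str) -> str:
        for name, lv in self.assignment:
            if name == attribute:
                return lv
        raise KeyError(attribute)

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)


def validate_profile(profile: Profile, spec: StudyDesignSpec) -> None:
    got = profile.as_dict()
    for a in spec.attributes:
        if a.name not in got:
            raise InvalidSpecError(f"profile missing attribute {a.name!r}")
        if got[a.name] not in a.levels:
            raise InvalidSpecError(
                f"profile level {got[a.name]!r} unknown for attribute {a.name!r}"
            )
    extra = set(got) - set(spec.attribute_names)
    if extra:
        raise InvalidSpecError(f"profile has unknown attributes {sorted(extra)}")


@dataclass(frozen=True)
class ChoiceTask:
    task_id: int
    block_id: int
    profiles: tuple[Profile, ...]


@dataclass(frozen=True)
class ChoiceDesign:
    """A set of choice tasks with block assignments and provenance."""

    tasks: tuple[ChoiceTask, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "tasks", tuple(self.tasks))
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise InvalidSpecError("task ids must be unique")
        for t in self.tasks:
            if len(set(t.profiles)) != len(t.profiles):
                raise InvalidSpecError(
                    f"task {t.task_id} contains two identical profiles"
                )

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def block_ids(self) -> list[int]:
        return sorted({t.block_id for t in self.tasks})

    def tasks_in_block(self, block_id: int) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.block_id == block_id]

    def to_frame(self, spec: StudyDesignSpec) -> pd.DataFrame:
        """One row per task × alternative, level labels as values."""
        rows = []
        for t in self.tasks:
            for j, p in enumerate(t.profiles, start=1):
                row = {"task_id": t.task_id, "block_id": t.block_id, "alt_id": f"designed-{j}"}
                row.update({a.name: p.level(a.name) for a in spec.attributes})
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spec: StudyDesignSpec,
                   provenance: str = "loaded") -> "ChoiceDesign":
        tasks = []
        for task_id, grp in frame.groupby("task_id", sort=True):
            grp = grp.sort_values("alt_id")
            block = int(grp["block_id"].iloc[0])
            profiles = tuple(
                Profile.from_mapping({a.name: r[a.name] for a in spec.attributes})
                for _, r in grp.iterrows()
            )
            tasks.append(ChoiceTask(int(task_id), block, profiles))
        return cls(tuple(tasks), provenance)


# ---------------------------------------------------------------------------
# Full factorial


def enumerate_full_factorial(spec: StudyDesignSpec) -> list[Profile]:
    """Every combination of attribute levels, exactly once.

    The count equals the product of the level counts (e.g. five 4-level
    and two 2-level attributes give 4^5 × 2^2 = 4096 profiles).
    """
    if not spec.attributes:
        raise InvalidSpecError("study needs at least one attribute")
    for a in spec.attributes:
        if a.n_levels == 0:
            raise InvalidSpecError(f"attribute {a.name!r} has no levels")
    names = spec.attribute_names
    return [
        Profile(tuple(zip(names, combo)))
        for combo in itertools.product(*(a.levels for a in spec.attributes))
    ]


# ---------------------------------------------------------------------------
# Orthogonal main-effects arrays over GF(2)^m

def _bit_dot(a: int, x: int) -> int:
    return bin(a & x).count("1") & 1


def _assign_subspaces(dims: Sequence[int], m: int) -> list[tuple[int, ...]] | None:
    """Assign to each factor a dims[i]-dimensional subspace of GF(2)^m characters.

    Subspaces must pairwise intersect only in zero, which is exactly the
    condition for any two factor columns of the induced array to be
    mutually balanced (strength 2).  Returns generator tuples, or None if
    the backtracking search fails.
    """
    n_points = (1 << m) - 1
    order = sorted(range(len(dims)), key=lambda i: -dims[i])
    used: set[int] = set()
    gens: dict[int, tuple[int, ...]] = {}

    def rec(pos: int) -> bool:
        if pos == len(order):
            return True
        k = dims[order[pos]]
        if k == 1:
            for c in range(1, n_points + 1):
                if c in used:
                    continue
                used.add(c)
                gens[order[pos]] = (c,)
                if rec(pos + 1):
                    return True
                used.remove(c)
        elif k == 2:
            for a in range(1, n_points + 1):
                if a in used:
                    continue
                for b in range(a + 1, n_points + 1):
                    if b in used or (a ^ b) in used or (a ^ b) < b:
                        continue
                    triple = {a, b, a ^ b}
                    used.update(triple)
                    gens[order[pos]] = (a, b)
                    if rec(pos + 1):
                        return True
                    used.difference_update(triple)
        else:  # pragma: no cover - not needed for <=4-level attributes
            raise DesignInfeasibleError(
                "only 2- and 4-level factors are supported by the GF(2) builder"
            )
        return False

    if rec(0):
        return [gens[i] for i in range(len(dims))]
    return None


def _orthogonal_array(level_counts: Sequence[int], n_runs: int) -> np.ndarray:
    """Strength-2 orthogonal array with the given column level counts.

    ``n_runs`` must be a power of two and every level count a power of two
    (vaccine DCEs use 4- and 2-level attributes).  Returns an integer array
    of level indices with shape (n_runs, n_factors).
    """
    m = int(round(math.log2(n_runs)))
    if 2 ** m != n_runs:
        raise DesignInfeasibleError(f"run size {n_runs} is not a power of two")
    dims = []
    for L in level_counts:
        k = int(round(math.log2(L)))
        if 2 ** k != L:
            raise DesignInfeasibleError(
                f"level count {L} is not a power of two; the GF(2) array "
                "builder cannot accommodate it"
            )
        dims.append(k)
    dof = sum(L - 1 for L in level_counts)
    if dof > n_runs - 1:
        raise DesignInfeasibleError(
            f"main effects need {dof} degrees of freedom but a {n_runs}-run "
            f"array offers only {n_runs - 1}"
        )
    gens = _assign_subspaces(dims, m)
    if gens is None:
        raise DesignInfeasibleError(
            f"no strength-2 array of {n_runs} runs found for level counts "
            f"{tuple(level_counts)} ({dof} main-effect degrees of freedom)"
        )
    arr = np.zeros((n_runs, len(level_counts)), dtype=int)
    for j, g in enumerate(gens):
        for x in range(n_runs):
            idx = 0
            for a in g:
                idx = (idx << 1) | _bit_dot(a, x)
            arr[x, j] = idx
    return arr


def minimum_run_size(spec: StudyDesignSpec) -> int:
    """Smallest power-of-two run size with a strength-2 array for the spec."""
    level_counts = [a.n_levels for a in spec.attributes]
    dof = sum(L - 1 for L in level_counts)
    m = max(1, math.ceil(math.log2(dof + 1)),
            math.ceil(math.log2(max(level_counts))))
    while m <= 16:
        dims = [int(round(math.log2(L))) for L in level_counts]
        if all(2 ** d == L for d, L in zip(dims, level_counts)):
            if _assign_subspaces(dims, m) is not None:
                return 2 ** m
        else:
            raise DesignInfeasibleError(
                "non-power-of-two level counts are not supported"
            )
        m += 1
    raise DesignInfeasibleError("no feasible run size below 2^16")  # pragma: no cover


def build_choice_design(
    spec: StudyDesignSpec,
    run_size: int | str = "auto",
    seed: int = 12345,
    pairing: str = "shift",
) -> ChoiceDesign:
    """Orthogonal main-effects choice design, one task per array run.

    The first alternative of each task is the orthogonal-array row.  Further
    alternatives are built by the pairing rule:

    * ``"shift"`` (default): alternative *j* takes alternative 1's level
      index plus ``j-1`` modulo the level count, attribute by attribute
      (the cyclic/shifted design).  This preserves level balance and
      guarantees no two alternatives in a task are identical.
    * ``"random"``: a seeded random non-zero cyclic offset per attribute
      per alternative — a level permutation of the base array, so balance
      and orthogonality are preserved.
    """
    level_counts = [a.n_levels for a in spec.attributes]
    if run_size == "auto":
        n_runs = minimum_run_size(spec)
    else:
        n_runs = int(run_size)
    arr = _orthogonal_array(level_counts, n_runs)

    rng = np.random.default_rng(seed)
    offsets: list[list[int]] = []  # per extra alternative, per attribute
    for j in range(1, spec.n_alternatives_per_task):
        if pairing == "shift":
            offsets.append([j % L if j % L else 1 for L in level_counts])
        elif pairing == "random":
            offsets.append([int(rng.integers(1, L)) for L in level_counts])
        else:
            raise InvalidSpecError(f"unknown pairing rule {pairing!r}")

    names = spec.attribute_names
    tasks = []
    for r in range(n_runs):
        profiles = [
            Profile(tuple(
                (names[a_i], spec.attributes[a_i].levels[arr[r, a_i]])
                for a_i in range(len(names))
            ))
        ]
        for off in offsets:
            profiles.append(Profile(tuple(
                (names[a_i],
                 spec.attributes[a_i].levels[(arr[r, a_i] + off[a_i]) % level_counts[a_i]])
                for a_i in range(len(names))
            )))
        tasks.append(ChoiceTask(task_id=r + 1, block_id=1, profiles=tuple(profiles)))
    provenance = (
        f"OA({n_runs}, {'x'.join(str(L) for L in level_counts)}) strength-2 via "
        f"GF(2)^{int(math.log2(n_runs))} subspace assignment; pairing={pairing}; seed={seed}"
    )
    return ChoiceDesign(tuple(tasks), provenance)


# ---------------------------------------------------------------------------
# Blocking


def _block_imbalance(levels: np.ndarray, assign: np.ndarray, n_blocks: int,
                     level_counts: Sequence[int]) -> float:
    score = 0.0
    n_tasks = levels.shape[0]
    for j, L in enumerate(level_counts):
        expected = n_tasks / n_blocks / L
        for b in range(n_blocks):
            counts = np.bincount(levels[assign == b, j], minlength=L)
            score += float(np.sum((counts - expected) ** 2))
    return score


def block_design(design: ChoiceDesign, n_blocks: int, seed: int = 12345,
                 spec: StudyDesignSpec | None = None) -> ChoiceDesign:
    """Partition tasks into equal-sized questionnaire versions.

    Starts from a seeded random equal split and hill-climbs with pairwise
    swaps to maximise within-block level balance of the first alternatives
    (a squared-deviation-from-uniform criterion).  Raises if the task count
    is not divisible by ``n_blocks``.
    """
    n_tasks = design.n_tasks
    if n_tasks % n_blocks != 0:
        raise InvalidSpecError(
            f"{n_tasks} tasks cannot be split into {n_blocks} equal blocks"
        )
    rng = np.random.default_rng(seed)
    assign = np.repeat(np.arange(n_blocks), n_tasks // n_blocks)
    rng.shuffle(assign)

    if spec is not None:
        attrs = spec.attributes
        level_counts = [a.n_levels for a in attrs]
        levels = np.array([
            [a.level_index(t.profiles[0].level(a.name)) for a in attrs]
            for t in design.tasks
        ])
        best = _block_imbalance(levels, assign, n_blocks, level_counts)
        improved = True
        while improved and best > 1e-9:
            improved = False
            for i in range(n_tasks):
                for j in range(i + 1, n_tasks):
                    if assign[i] == assign[j]:
                        continue
                    assign[i], assign[j] = assign[j], assign[i]
                    score = _block_imbalance(levels, assign, n_blocks, level_counts)
                    if score < best - 1e-12:
                        best = score
                        improved = True
                    else:
                        assign[i], assign[j] = assign[j], assign[i]

    tasks = tuple(
        replace(t, block_id=int(assign[i]) + 1) for i, t in enumerate(design.tasks)
    )
    return ChoiceDesign(tasks, design.provenance + f"; blocked into {n_blocks} (seed={seed})")


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass(frozen=True)
class DesignDiagnostics:
    level_counts: dict[str, dict[str, int]]
    max_abs_correlation: float
    balanced: bool
    passed: bool
    tolerance: float

    def __str__(self):  # pragma: no cover - cosmetic
        flag = "PASS" if self.passed else "FAIL"
        return (f"DesignDiagnostics(max |corr| = {self.max_abs_correlation:.4f}, "
                f"balanced = {self.balanced}) -> {flag}")


def design_diagnostics(design: ChoiceDesign, spec: StudyDesignSpec,
                       tolerance: float = 1e-8) -> DesignDiagnostics:
    """Balance and orthogonality report over all designed profiles.

    Reports per-attribute level counts, the maximum absolute pairwise
    Pearson correlation between main-effects columns belonging to
    *different* attributes (within-attribute dummies are mechanically
    correlated), and a pass flag at the given tolerance.
    """
    if design.n_tasks == 0:
        raise InvalidSpecError("design is empty")
    profiles = [p for t in design.tasks for p in t.profiles]

    level_counts: dict[str, dict[str, int]] = {}
    for a in spec.attributes:
        counts = {lv: 0 for lv in a.levels}
        for p in profiles:
            counts[p.level(a.name)] += 1
        level_counts[a.name] = counts
    balanced = all(
        max(c.values()) - min(c.values()) <= 1 for c in level_counts.values()
    )

    # main-effects coding: dummies for categorical, numeric for continuous
    cols: list[np.ndarray] = []
    owner: list[str] = []
    for a in spec.attributes:
        if a.coding == CONTINUOUS:
            cols.append(np.array([a.numeric_value(p.level(a.name)) for p in profiles], float))
            owner.append(a.name)
        else:
            for lv, _ in a.dummy_columns():
                cols.append(np.array([1.0 if p.level(a.name) == lv else 0.0 for p in profiles]))
                owner.append(a.name)
    max_corr = 0.0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if owner[i] == owner[j]:
                continue
            si, sj = np.std(cols[i]), np.std(cols[j])
            if si == 0 or sj == 0:
                continue
            r = float(np.corrcoef(cols[i], cols[j])[0, 1])
            max_corr = max(max_corr, abs(r))
    passed = balanced and max_corr <= tolerance
    return DesignDiagnostics(level_counts, max_corr, balanced, passed, tolerance)


# ---------------------------------------------------------------------------
# Sample size


def johnson_orme_min_n(c: int, t: int, a: int) -> int:
    """Johnson–Orme minimum sample size, ``floor(500·c / (t·a))``.

    ``c`` is the largest number of levels of any attribute, ``t`` the
    number of choice tasks per respondent and ``a`` the number of
    alternatives per task.  With c=4, t=8, a=3 the rule gives 83.
    """
    for name, v in (("c", c), ("t", t), ("a", a)):
        if int(v) != v or v <= 0:
            raise InvalidSpecError(f"{name} must be a positive integer, got {v!r}")
    return (500 * int(c)) // (int(t) * int(a))
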