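"""Experimental design for the insurance discrete choice experiment.

Builds the blocked, D-efficient paired-alternative design: full-factorial
profile enumeration, the MNL D-error criterion, a coordinate-exchange
optimizer with dominance repair and greedy level-balanced blocking, and the
dominance-based quality-control (QC) choice set.

Each choice set offers two insurance packages plus an opt-out; the opt-out
enters the efficiency computation as a third alternative whose utility is a
fixed ASC prior (default 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear-continuous"
DUMMY = "dummy-categorical"
QC_BLOCK = "QC"

__all__ = [
    "Attribute",
    "AttributeDictionary",
    "ChoiceSet",
    "ChoiceDesign",
    "DesignNotIdentifiedError",
    "default_attributes",
    "default_priors",
    "enumerate_profiles",
    "code_profile",
    "coded_columns",
    "d_error",
    "generate_design",
    "is_dominated",
    "make_qc_set",
    "design_to_frame",
    "design_from_frame",
]


class DesignNotIdentifiedError(ValueError):
    """Raised when the design information matrix is singular."""


@dataclass(frozen=True)
class Attribute:
    """One DCE attribute.

    ``unit_scale`` is the divisor applied to raw levels before they enter
    utility (e.g. deductibles in RMB divided by 10 000 so the coefficient is
    per 10 000 RMB).  ``hypothesized_sign`` drives the dominance partial
    order: "+" means higher levels are preferred, "-" lower,
    "reference-relative" means non-reference levels are preferred to the
    reference but are mutually incomparable unless ``ordered_nonref``.
    """

    name: str
    levels: tuple
    coding: str
    hypothesized_sign: str
    reference_level: object = None
    unit_scale: float = 1.0
    ordered_nonref: bool = False  # non-reference levels form an increasing chain

    def __post_init__(self):
        if self.coding not in (LINEAR, DUMMY):
            raise ValueError(f"unknown coding {self.coding!r} for {self.name}")
        if self.unit_scale <= 0:
            raise ValueError(f"unit_scale must be > 0 for {self.name}")
        if self.coding == LINEAR:
            vals = [float(v) for v in self.levels]
            if sorted(vals) != vals or len(set(vals)) != len(vals):
                raise ValueError(
                    f"linear attribute {self.name} needs strictly ordered numeric levels"
                )
        else:
            if self.reference_level is None:
                raise ValueError(f"dummy attribute {self.name} needs a reference level")
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"reference level {self.reference_level!r} not among levels of {self.name}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def nonreference_levels(self):
        return [l for l in self.levels if l != self.reference_level]

    def compare(self, a, b):
        """Dominance comparison of level ``a`` against level ``b``.

        Returns -1 if a is strictly worse, 0 if equivalent/weakly ordered
        without strict preference, +1 if strictly better, None if the two
        levels are incomparable.
        """
        if a == b:
            return 0
        if self.coding == LINEAR:
            fa, fb = float(a), float(b)
            better = fa > fb if self.hypothesized_sign == "+" else fa < fb
            return 1 if better else -1
        # dummy-coded: reference is worse than any alternative level
        if a == self.reference_level:
            return -1
        if b == self.reference_level:
            return 1
        if self.ordered_nonref:
            # chain order by position, but only weakly (no strict preference
            # between two non-reference levels)
            return 0
        return None


@dataclass(frozen=True)
class AttributeDictionary:
    """Ordered collection of DCE attributes."""

    attributes: tuple

    def __post_init__(self):
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self):
        return len(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self):
        return [a.name for a in self.attributes]

    def validate_huimin(self) -> None:
        """Assert the five-attribute insurance layout (3,3,3,3,4 levels)."""
        counts = sorted(a.n_levels for a in self.attributes)
        if len(self.attributes) != 5 or counts != [3, 3, 3, 3, 4]:
            raise ValueError(
                "expected 5 attributes with level counts (3,3,3,3,4), got "
                f"{[a.n_levels for a in self.attributes]}"
            )


def default_attributes() -> AttributeDictionary:
    """The five insurance attributes and levels of the Huimin DCE.

    Premium in RMB/year; deductibles in RMB, scaled to 10 000-RMB units in
    utility; reimbursement in percentage points; government involvement and
    value-added services dummy-coded against their base levels.
    """
    return AttributeDictionary(
        (
            Attribute("premium", (130.0, 170.0, 210.0), LINEAR, "-"),
            Attribute(
                "government",
                ("commercial", "moderate", "strong"),
                DUMMY,
                "reference-relative",
                reference_level="commercial",
                ordered_nonref=True,
            ),
            Attribute(
                "deductible", (120_000.0, 150_000.0, 180_000.0), LINEAR, "-", unit_scale=10_000.0
            ),
            Attribute("reimbursement", (50.0, 65.0, 80.0), LINEAR, "+"),
            Attribute(
                "value_added",
                ("basic", "expanded1", "expanded2", "expanded3"),
                DUMMY,
                "reference-relative",
                reference_level="basic",
            ),
        )
    )


def coded_columns(attrs: AttributeDictionary):
    """Names of the coded utility columns, in design-matrix order."""
    cols = []
    for a in attrs:
        if a.coding == LINEAR:
            cols.append(a.name)
        else:
            cols.extend(f"{a.name}:{l}" for l in a.nonreference_levels())
    return cols


def code_profile(profile: dict, attrs: AttributeDictionary) -> np.ndarray:
    """Code one profile into the utility design vector (linear scaled, dummies)."""
    out = []
    for a in attrs:
        level = profile[a.name]
        if a.coding == LINEAR:
            out.append(float(level) / a.unit_scale)
        else:
            out.extend(1.0 if level == l else 0.0 for l in a.nonreference_levels())
    return np.asarray(out)


def default_priors(attrs: AttributeDictionary) -> np.ndarray:
    """Pilot-style prior coefficients on the coded columns, used for efficiency."""
    table = {
        "premium": -0.007,
        "government:moderate": 0.764,
        "government:strong": 0.880,
        "deductible": -0.036,
        "reimbursement": 0.049,
        "value_added:expanded1": 0.604,
        "value_added:expanded2": 0.742,
        "value_added:expanded3": 0.899,
    }
    return np.array([table.get(c, 0.0) for c in coded_columns(attrs)])


def enumerate_profiles(attrs: AttributeDictionary):
    """Full factorial of attribute levels; one dict per profile."""
    names = attrs.names
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(a.levels for a in attrs))
    ]


def is_dominated(profile_a: dict, profile_b: dict, attrs: AttributeDictionary) -> bool:
    """True iff ``profile_a`` is weakly worse than ``profile_b`` on every
    attribute under the hypothesized signs and strictly worse on at least one."""
    any_strict = False
    for a in attrs:
        cmp = a.compare(profile_a[a.name], profile_b[a.name])
        if cmp is None or cmp > 0:
            return False
        if cmp < 0:
            any_strict = True
    return any_strict


@dataclass
class ChoiceSet:
    """A paired choice set: two insurance profiles plus an opt-out."""

    set_id: int
    block_id: object  # int block or the string "QC"
    alternatives: list  # two profile dicts
    opt_out_present: bool = True

    def __post_init__(self):
        if len(self.alternatives) != 2:
            raise ValueError("a choice set holds exactly 2 insurance profiles")
        if self.alternatives[0] == self.alternatives[1]:
            raise ValueError("the two insurance profiles must differ")

    @property
    def is_qc(self) -> bool:
        return self.block_id == QC_BLOCK


@dataclass
class ChoiceDesign:
    """A blocked design: experimental sets plus (optionally) one QC set."""

    choice_sets: list
    priors: np.ndarray
    attrs: AttributeDictionary
    d_error: float = np.nan
    blocks: dict = field(default_factory=dict)

    @property
    def experimental_sets(self):
        return [s for s in self.choice_sets if not s.is_qc]

    @property
    def qc_sets(self):
        return [s for s in self.choice_sets if s.is_qc]

    def block_of(self, block_id):
        return [s for s in self.choice_sets if s.block_id == block_id]


def make_qc_set(attrs: AttributeDictionary, set_id: int = 0) -> ChoiceSet:
    """QC set: alternative 1 dominates alternative 2 (best vs worst levels)."""
    best, worst = {}, {}
    for a in attrs:
        if a.coding == LINEAR:
            lv = sorted(float(l) for l in a.levels)
            if a.hypothesized_sign == "+":
                best[a.name], worst[a.name] = lv[-1], lv[0]
            else:
                best[a.name], worst[a.name] = lv[0], lv[-1]
        else:
            worst[a.name] = a.reference_level
            best[a.name] = a.nonreference_levels()[-1 if a.ordered_nonref else 0]
    qc = ChoiceSet(set_id=set_id, block_id=QC_BLOCK, alternatives=[best, worst])
    assert is_dominated(worst, best, attrs)
    return qc


# ---------------------------------------------------------------------------
# D-error
# ---------------------------------------------------------------------------

def _information_matrix(design: ChoiceDesign, priors: np.ndarray, asc_prior: float = 0.0):
    attrs = design.attrs
    K = len(priors)
    info = np.zeros((K, K))
    for s in design.experimental_sets:
        X = np.vstack(
            [code_profile(p, attrs) for p in s.alternatives]
            + ([np.zeros(K)] if s.opt_out_present else [])
        )
        u = X @ priors
        if s.opt_out_present:
            u[-1] = asc_prior
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        info += X.T @ (np.diag(p) - np.outer(p, p)) @ X
    return info


def d_error(design: ChoiceDesign, priors: np.ndarray, asc_prior: float = 0.0) -> float:
    """MNL D-error det(I)^(-1/K); lower is better. QC sets are excluded."""
    priors = np.asarray(priors, float)
    info = _information_matrix(design, priors, asc_prior)
    K = len(priors)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        raise DesignNotIdentifiedError("design information matrix is singular")
    return float(np.exp(-logdet / K))


# ---------------------------------------------------------------------------
# Coordinate exchange
# ---------------------------------------------------------------------------

def _pair_ok(a, b, attrs):
    return a != b and not is_dominated(a, b, attrs) and not is_dominated(b, a, attrs)


def _distinct_set_counts(sets, attr):
    """How many distinct sets contain each level of ``attr``."""
    counts = {l: 0 for l in attr.levels}
    for s in sets:
        present = {p[attr.name] for p in s.alternatives}
        for l in present:
            counts[l] += 1
    return counts


def _initial_design(attrs, n_sets, min_level_sets, rng, attempts=25):
    """Random paired sets with per-attribute level columns balanced enough
    that every level occurs in at least ``min_level_sets`` distinct sets.

    Each attempt shuffles balanced level pools into pairs and repairs
    invalid (identical/dominated) pairs by count-preserving swaps; returns
    None only if every attempt fails.
    """
    for _ in range(attempts):
        columns = {}
        for a in attrs:
            pool = list(a.levels) * min_level_sets
            extra = rng.integers(0, a.n_levels, size=max(0, 2 * n_sets - len(pool)))
            pool += [a.levels[i] for i in extra]
            pool = np.array(pool[: 2 * n_sets], dtype=object)
            rng.shuffle(pool)
            columns[a.name] = list(pool)
        pairs = [
            [
                {a.name: columns[a.name][2 * i] for a in attrs},
                {a.name: columns[a.name][2 * i + 1] for a in attrs},
            ]
            for i in range(n_sets)
        ]
        def n_bad():
            return sum(not _pair_ok(p[0], p[1], attrs) for p in pairs)

        ok = False
        current = n_bad()
        for _ in range(100 * n_sets):
            if current == 0:
                ok = True
                break
            bad = [p for p in pairs if not _pair_ok(p[0], p[1], attrs)]
            p = bad[int(rng.integers(len(bad)))]
            a = attrs.attributes[rng.integers(len(attrs))]
            other = pairs[int(rng.integers(n_sets))]
            if other is p:
                continue
            k1, k2 = int(rng.integers(2)), int(rng.integers(2))
            p[k1][a.name], other[k2][a.name] = other[k2][a.name], p[k1][a.name]
            after = n_bad()
            if after > current:           # undo swaps that make things worse
                p[k1][a.name], other[k2][a.name] = other[k2][a.name], p[k1][a.name]
            else:
                current = after
        ok = ok or n_bad() == 0
        if ok:
            return [
                ChoiceSet(set_id=i + 1, block_id=0, alternatives=pair)
                for i, pair in enumerate(pairs)
            ]
    return None


def _coordinate_exchange(design, priors, rng, asc_prior, min_level_sets=0):
    """Sweep sets x alternatives x attributes, accepting strict improvements.

    Moves that would leave any attribute level in fewer than
    ``min_level_sets`` distinct sets (needed for per-block level coverage)
    are rejected.  Returns the improved D-error and its monotone trace.
    """
    attrs = design.attrs
    best = d_error(design, priors, asc_prior)
    trace = [best]
    sets = design.experimental_sets
    improved = True
    while improved:
        improved = False
        for s in sets:
            for alt_idx in (0, 1):
                for a in attrs:
                    current = s.alternatives[alt_idx][a.name]
                    other = s.alternatives[1 - alt_idx]
                    for level in a.levels:
                        if level == current:
                            continue
                        cand = dict(s.alternatives[alt_idx])
                        cand[a.name] = level
                        if not _pair_ok(cand, other, attrs):
                            continue
                        old = s.alternatives[alt_idx]
                        s.alternatives[alt_idx] = cand
                        if min_level_sets:
                            cnt = _distinct_set_counts(sets, a)
                            if cnt[current] < min_level_sets:
                                s.alternatives[alt_idx] = old
                                continue
                        try:
                            val = d_error(design, priors, asc_prior)
                        except DesignNotIdentifiedError:
                            val = np.inf
                        if val < best - 1e-12:
                            best = val
                            trace.append(best)
                            improved = True
                        else:
                            s.alternatives[alt_idx] = old
    return best, trace


def _greedy_blocks(design, n_blocks, attrs):
    """Assign experimental sets to blocks, greedily balancing level counts.

    Sets are processed in set_id order; each goes to the non-full block whose
    squared deviation from perfect per-block level balance grows least (ties:
    lowest block id).  A repair pass then swaps sets between blocks until every
    block covers every level, raising if no swap helps.
    """
    sets = sorted(design.experimental_sets, key=lambda s: s.set_id)
    per_block = len(sets) // n_blocks
    levels = [(a.name, l) for a in attrs for l in a.levels]
    level_idx = {kl: i for i, kl in enumerate(levels)}

    def set_counts(s):
        c = np.zeros(len(levels))
        for p in s.alternatives:
            for a in attrs:
                c[level_idx[(a.name, p[a.name])]] += 1
        return c

    counts = {s.set_id: set_counts(s) for s in sets}
    # perfect balance: each level appears (2*per_block*sets_with_attr)/n_levels
    target = np.zeros(len(levels))
    for a in attrs:
        for l in a.levels:
            target[level_idx[(a.name, l)]] = 2.0 * per_block / a.n_levels

    block_counts = [np.zeros(len(levels)) for _ in range(n_blocks)]
    assignment = {}
    members = [[] for _ in range(n_blocks)]
    for s in sets:
        best_b, best_obj = None, np.inf
        for b in range(n_blocks):
            if len(members[b]) >= per_block:
                continue
            obj = float(np.sum((block_counts[b] + counts[s.set_id] - target) ** 2))
            if obj < best_obj - 1e-12:
                best_obj, best_b = obj, b
        assignment[s.set_id] = best_b
        members[best_b].append(s.set_id)
        block_counts[best_b] += counts[s.set_id]

    # local search on pairwise swaps: squared balance deviation plus a large
    # penalty per missing (block, level); accept strictly improving swaps
    PENALTY = 1e4

    def block_obj(c):
        return float(np.sum((c - target) ** 2)) + PENALTY * float(np.sum(c < 0.5))

    objs = [block_obj(c) for c in block_counts]
    for _ in range(100):
        best_gain, best_swap = 1e-9, None
        for b1 in range(n_blocks):
            for b2 in range(b1 + 1, n_blocks):
                for sid1 in members[b1]:
                    for sid2 in members[b2]:
                        c1 = block_counts[b1] - counts[sid1] + counts[sid2]
                        c2 = block_counts[b2] - counts[sid2] + counts[sid1]
                        gain = objs[b1] + objs[b2] - block_obj(c1) - block_obj(c2)
                        if gain > best_gain:
                            best_gain = gain
                            best_swap = (b1, sid1, b2, sid2, c1, c2)
        if best_swap is None:
            break
        b1, sid1, b2, sid2, c1, c2 = best_swap
        members[b1][members[b1].index(sid1)] = sid2
        members[b2][members[b2].index(sid2)] = sid1
        block_counts[b1], block_counts[b2] = c1, c2
        objs[b1], objs[b2] = block_obj(c1), block_obj(c2)

    for b in range(n_blocks):
        missing = np.flatnonzero(block_counts[b] < 0.5)
        if len(missing):
            raise ValueError(
                f"level-coverage constraint infeasible in block {b + 1}: "
                f"level {levels[missing[0]]} cannot be covered"
            )

    for b in range(n_blocks):
        for sid in members[b]:
            assignment[sid] = b
    for s in sets:
        s.block_id = assignment[s.set_id] + 1
    return {b + 1: sorted(members[b]) for b in range(n_blocks)}


def generate_design(
    attrs: AttributeDictionary,
    n_sets: int = 24,
    n_blocks: int = 4,
    priors: np.ndarray | None = None,
    seed: int = 20230901,
    n_restarts: int = 20,
    asc_prior: float = 0.0,
    include_qc: bool = True,
) -> ChoiceDesign:
    """D-efficient blocked design via coordinate exchange with dominance repair.

    Random start, sweep over sets x alternatives x attributes accepting strict
    D-error improvements, over ``n_restarts`` restarts; greedy level-balanced
    blocking; optional appended QC set (excluded from efficiency).
    """
    if n_sets % n_blocks:
        raise ValueError("n_sets must be divisible by n_blocks")
    if priors is None:
        priors = default_priors(attrs)
    priors = np.asarray(priors, float)
    rng = np.random.default_rng(seed)

    min_level_sets = n_blocks if n_blocks > 1 else 1
    best_design, best_val, best_trace = None, np.inf, None
    for _ in range(n_restarts):
        sets = _initial_design(attrs, n_sets, min_level_sets, rng)
        if sets is None:
            continue
        cand = ChoiceDesign(choice_sets=sets, priors=priors, attrs=attrs)
        try:
            d_error(cand, priors, asc_prior)
        except DesignNotIdentifiedError:
            continue
        val, trace = _coordinate_exchange(cand, priors, rng, asc_prior, min_level_sets)
        if val < best_val:
            best_design, best_val, best_trace = cand, val, trace
    if best_design is None:
        raise DesignNotIdentifiedError("no identified starting design found")

    blocks = _greedy_blocks(best_design, n_blocks, attrs)
    if include_qc:
        qc = make_qc_set(attrs, set_id=n_sets + 1)
        best_design.choice_sets.append(qc)
    best_design.d_error = best_val
    best_design.blocks = blocks
    best_design.exchange_trace = best_trace
    return best_design


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def design_to_frame(design: ChoiceDesign) -> pd.DataFrame:
    rows = []
    for s in design.choice_sets:
        for alt_id, prof in enumerate(s.alternatives, start=1):
            row = {
                "set_id": s.set_id,
                "block_id": s.block_id,
                "alt_id": alt_id,
                "is_qc": int(s.is_qc),
            }
            row.update(prof)
            rows.append(row)
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame, attrs: AttributeDictionary,
                      priors: np.ndarray | None = None) -> ChoiceDesign:
    if priors is None:
        priors = default_priors(attrs)
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        grp = grp.sort_values("alt_id")
        is_qc = bool(grp["is_qc"].iloc[0])
        block = QC_BLOCK if is_qc else int(grp["block_id"].iloc[0])
        alts = []
        for _, r in grp.iterrows():
            prof = {}
            for a in attrs:
                v = r[a.name]
                prof[a.name] = float(v) if a.coding == LINEAR else v
            alts.append(prof)
        sets.append(ChoiceSet(set_id=int(set_id), block_id=block, alternatives=alts))
    design = ChoiceDesign(choice_sets=sets, priors=np.asarray(priors, float), attrs=attrs)
    blocks = {}
    for s in design.experimental_sets:
        blocks.setdefault(s.block_id, []).append(s.set_id)
    design.blocks = {b: sorted(v) for b, v in blocks.items()}
    try:
        design.d_error = d_error(design, design.priors)
    except DesignNotIdentifiedError:
        design.d_error = np.nan
    return design
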