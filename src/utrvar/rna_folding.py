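"""Equilibrium base-pair probabilities under a simplified nearest-neighbor model.

The engine is a McCaskill-style inside/outside dynamic program over
pseudoknot-free secondary structures: Watson-Crick and GU pairs, stacking
energies, affine hairpin and interior/bulge penalties (interior loops capped
at ``maxloop`` unpaired bases), and an affine multiloop term.  An exhaustive
enumeration oracle computes the same quantities exactly for short sequences
and shares the energy function, so the two routes must agree to numerical
precision.

Energies are kcal/mol; Boltzmann factors use RT at the model temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair-type indices; -1 = not pairable
PAIR_TYPES = ("CG", "GC", "AU", "UA", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

PAIR_TABLE = np.full((4, 4), -1, dtype=np.int64)
for _p, _i in _PAIR_INDEX.items():
    PAIR_TABLE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _i

# Nearest-neighbor stack free energies, kcal/mol at 37 C.  Key is the
# 5'->3' step XW over 3'<-5' YZ written as (outer pair XY, inner pair WZ);
# symmetry S[out, in] = S[flip(in), flip(out)] completes the table.
_STACK_STEPS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08,
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93,
    ("UA", "CG"): -2.11,
    ("UA", "GC"): -2.35,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27,
    ("GU", "AU"): -1.27,
    ("GU", "UA"): -1.36,
    ("GU", "CG"): -2.11,
    ("GU", "GC"): -2.51,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): -1.29,
    ("UG", "AU"): -1.00,
    ("UG", "UA"): -0.55,
    ("UG", "CG"): -1.53,
    ("UG", "GC"): -1.41,
    ("UG", "GU"): -0.30,
    ("UG", "UG"): -0.50,
}


def _flip(pair: str) -> str:
    return pair[1] + pair[0]


def _build_stack_table() -> np.ndarray:
    table = np.zeros((6, 6))
    for (out, inn), e in _STACK_STEPS.items():
        table[_PAIR_INDEX[out], _PAIR_INDEX[inn]] = e
    # enforce strand-flip symmetry by averaging (values above are already
    # close; averaging makes the table exactly self-consistent)
    sym = table.copy()
    for out in PAIR_TYPES:
        for inn in PAIR_TYPES:
            a = table[_PAIR_INDEX[out], _PAIR_INDEX[inn]]
            b = table[_PAIR_INDEX[_flip(inn)], _PAIR_INDEX[_flip(out)]]
            sym[_PAIR_INDEX[out], _PAIR_INDEX[inn]] = 0.5 * (a + b)
    return sym


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbor energy model.

    Parameters
    ----------
    stack : 6x6 array of stacking free energies indexed by
        (outer pair type, inner pair type) over CG, GC, AU, UA, GU, UG.
    hairpin_a, hairpin_b : affine hairpin-loop penalty a + b * loop_len.
    interior_a, interior_b : affine interior/bulge penalty in the total
        number of unpaired loop bases.
    multiloop_a, multiloop_b : affine multiloop penalty
        a + b * n_branches (the closing helix counts as a branch).
    duplex_init : intermolecular duplex initiation penalty (used by the
        miRNA hybridization stage).
    temperature : Kelvin.
    min_hairpin : minimum unpaired bases in a hairpin loop.
    maxloop : maximum total unpaired bases in an interior loop.
    """

    stack: np.ndarray = field(default_factory=_build_stack_table)
    hairpin_a: float = 4.8
    hairpin_b: float = 0.15
    interior_a: float = 2.0
    interior_b: float = 0.4
    multiloop_a: float = 3.4
    multiloop_b: float = 0.4
    duplex_init: float = 4.1
    temperature: float = 310.15
    min_hairpin: int = 3
    maxloop: int = 30

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("stack energies must be finite")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    def hairpin_energy(self, loop_len: int) -> float:
        return self.hairpin_a + self.hairpin_b * loop_len

    def interior_energy(self, unpaired: int) -> float:
        return self.interior_a + self.interior_b * unpaired

    def multiloop_energy(self, branches: int) -> float:
        return self.multiloop_a + self.multiloop_b * branches

    @classmethod
    def zero(cls) -> "EnergyModel":
        """All energies zero: every structure equally likely (uniform ensemble)."""
        return cls(
            stack=np.zeros((6, 6)),
            hairpin_a=0.0,
            hairpin_b=0.0,
            interior_a=0.0,
            interior_b=0.0,
            multiloop_a=0.0,
            multiloop_b=0.0,
            duplex_init=0.0,
        )

    @classmethod
    def from_tsv(cls, path, **overrides) -> "EnergyModel":
        """Load scalar parameters and the stack table from a small TSV.

        Rows are either ``param <name> <value>`` or
        ``stack <outer> <inner> <value>``.
        """
        params: dict[str, float] = {}
        stack = np.zeros((6, 6))
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields or fields[0].startswith("#"):
                    continue
                if fields[0] == "param":
                    params[fields[1]] = float(fields[2])
                elif fields[0] == "stack":
                    stack[_PAIR_INDEX[fields[1]], _PAIR_INDEX[fields[2]]] = float(
                        fields[3]
                    )
        ints = {"min_hairpin", "maxloop"}
        kwargs = {k: (int(v) if k in ints else v) for k, v in params.items()}
        kwargs.update(overrides)
        return cls(stack=stack, **kwargs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name in (
                "hairpin_a",
                "hairpin_b",
                "interior_a",
                "interior_b",
                "multiloop_a",
                "multiloop_b",
                "duplex_init",
                "temperature",
                "min_hairpin",
                "maxloop",
            ):
                fh.write(f"param\t{name}\t{getattr(self, name)}\n")
            for a in PAIR_TYPES:
                for b in PAIR_TYPES:
                    fh.write(
                        f"stack\t{a}\t{b}\t{self.stack[_PAIR_INDEX[a], _PAIR_INDEX[b]]}\n"
                    )


DEFAULT_MODEL = EnergyModel()


@dataclass
class BasePairMatrix:
    """Symmetric matrix of equilibrium pair probabilities for one window."""

    n: int
    p: np.ndarray
    too_short: bool = False

    def __post_init__(self) -> None:
        if self.p.shape != (self.n, self.n):
            raise ValueError("matrix shape must be (n, n)")

    def validate(self, min_hairpin: int = 3, tol: float = 1e-9) -> None:
        """Raise if any BasePairMatrix invariant is violated."""
        p = self.p
        if not np.allclose(p, p.T, atol=tol):
            raise ValueError("pair-probability matrix not symmetric")
        if p.min() < -tol or p.max() > 1 + tol:
            raise ValueError("pair probabilities outside [0, 1]")
        for i in range(self.n):
            lo = max(0, i - min_hairpin)
            hi = min(self.n, i + min_hairpin + 1)
            if np.any(p[i, lo:hi] > tol):
                raise ValueError("pairs inside the minimum hairpin span")
        sums = p.sum(axis=1)
        if np.any(sums > 1 + 1e-9 + tol):
            raise ValueError("row sum exceeds 1")


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc} in RNA sequence") from exc


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inside(ptype, stack_w, hairpin_w, interior_w, wml_close, wml_branch, sc, minhp, maxloop):
    n = ptype.shape[0]
    qb = np.zeros((n, n))
    qm1 = np.zeros((n, n))
    qm = np.zeros((n, n))
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            # paired (i, j)
            if ptype[i, j] >= 0 and d > minhp:
                u = d - 1
                val = hairpin_w[u] * sc ** (d + 1)
                kmax = min(i + 1 + maxloop, j - 1 - minhp)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + minhp + 1, j - 1 - (maxloop - u1))
                    for l in range(lmin, j):
                        if ptype[k, l] >= 0:
                            u2 = j - l - 1
                            if u1 == 0 and u2 == 0:
                                w = stack_w[ptype[i, j], ptype[k, l]]
                            else:
                                w = interior_w[u1 + u2]
                            val += w * qb[k, l] * sc ** (u1 + u2 + 2)
                s = 0.0
                for k in range(i + 2, j - 1):
                    s += qm[i + 1, k - 1] * qm1[k, j - 1]
                val += wml_close * s * sc * sc
                qb[i, j] = val
            # qm1: one branch starting at i, trailing unpaired to j
            prev = qm1[i, j - 1] if d > 0 else 0.0
            qm1[i, j] = prev * sc + wml_branch * qb[i, j]
            # qm: >= 1 branch, decomposed on the start of the last branch
            m = 0.0
            for k in range(i, j + 1):
                q1 = qm1[k, j]
                if q1 > 0.0:
                    left = sc ** (k - i)
                    if k > i:
                        left += qm[i, k - 1]
                    m += left * q1
            qm[i, j] = m
    # exterior
    qf = np.zeros(n + 1)
    qf[0] = 1.0
    for j in range(1, n + 1):
        val = qf[j - 1] * sc
        for k in range(1, j + 1):
            b = qb[k - 1, j - 1]
            if b > 0.0:
                val += qf[k - 1] * b
        qf[j] = val
    qr = np.zeros(n + 2)
    qr[n] = 1.0
    qr[n + 1] = 1.0
    for i in range(n - 1, -1, -1):
        val = qr[i + 1] * sc
        for j in range(i, n):
            b = qb[i, j]
            if b > 0.0:
                val += b * qr[j + 1]
        qr[i] = val
    return qb, qm1, qm, qf, qr


@njit(cache=True)
def _outside(ptype, qb, qm, qf, qr, stack_w, interior_w, wml_close, wml_branch, sc, minhp, maxloop):
    n = ptype.shape[0]
    q_total = qf[n]
    prob = np.zeros((n, n))
    oi = np.zeros((n, n))  # accumulated interior-loop outside contributions
    c_acc = np.zeros((n, n))  # C[h, j'] = sum_q PO[h,q] * QM[j'+1, q-1]
    rs_acc = np.zeros((n, n))  # Rs[h, j'] = sum_q PO[h,q] * sc^(q-j'-1)
    for d in range(n - 1, minhp, -1):
        for i in range(n - d):
            j = i + d
            if ptype[i, j] < 0 or qb[i, j] <= 0.0:
                continue
            po = qf[i] * qr[j + 1]
            po += oi[i, j]
            # (i, j) as one branch of an enclosing multiloop
            s = 0.0
            for h in range(i):
                gap = i - h - 1
                s += sc ** gap * c_acc[h, j]
                if gap >= 1:
                    s += qm[h + 1, i - 1] * (rs_acc[h, j] + c_acc[h, j])
            po += wml_close * wml_branch * s * sc * sc
            prob[i, j] = qb[i, j] * po / q_total
            # push interior-loop contributions onto inner pairs
            kmax = min(i + 1 + maxloop, j - 1 - minhp)
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                lmin = max(k + minhp + 1, j - 1 - (maxloop - u1))
                for l in range(lmin, j):
                    if ptype[k, l] >= 0:
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            w = stack_w[ptype[i, j], ptype[k, l]]
                        else:
                            w = interior_w[u1 + u2]
                        oi[k, l] += po * w * sc ** (u1 + u2 + 2)
            # push multiloop accumulators for inner pairs ending at j' < j
            for jp in range(i + 1, j):
                rs_acc[i, jp] += po * sc ** (j - jp - 1)
                if jp + 1 <= j - 2:
                    c_acc[i, jp] += po * qm[jp + 1, j - 1]
    return prob


def compute_pair_probabilities(
    seq: str, model: EnergyModel = DEFAULT_MODEL
) -> BasePairMatrix:
    """Base-pair probability matrix of the Boltzmann ensemble of ``seq``.

    Deterministic; returns an all-zero matrix flagged ``too_short`` when the
    sequence cannot form any pair.
    """
    n = len(seq)
    if n < model.min_hairpin + 2:
        return BasePairMatrix(n=n, p=np.zeros((n, n)), too_short=True)
    enc = encode(seq)
    ptype = PAIR_TABLE[enc[:, None], enc[None, :]]
    beta = 1.0 / model.rt
    stack_w = np.exp(-beta * model.stack)
    hairpin_w = np.exp(
        -beta * (model.hairpin_a + model.hairpin_b * np.arange(n + 1, dtype=float))
    )
    interior_w = np.exp(
        -beta
        * (
            model.interior_a
            + model.interior_b * np.arange(model.maxloop + 1, dtype=float)
        )
    )
    wml_close = math.exp(-beta * (model.multiloop_a + model.multiloop_b))
    wml_branch = math.exp(-beta * model.multiloop_b)

    # per-nucleotide rescaling keeps the partition function in double range;
    # retry with a stronger/weaker scale on overflow/underflow
    e_scale = -0.25 if n > 80 else 0.0
    for _ in range(8):
        sc = math.exp(beta * e_scale)  # weight carried by each nucleotide
        qb, qm1, qm, qf, qr = _inside(
            ptype, stack_w, hairpin_w, interior_w, wml_close, wml_branch, sc,
            model.min_hairpin, model.maxloop,
        )
        q = qf[n]
        if not math.isfinite(q):
            e_scale -= 0.25
            continue
        if q <= 0.0 or q < 1e-250:
            e_scale += 0.25
            continue
        prob = _outside(
            ptype, qb, qm, qf, qr, stack_w, interior_w, wml_close, wml_branch, sc,
            model.min_hairpin, model.maxloop,
        )
        p = prob + prob.T
        np.clip(p, 0.0, 1.0, out=p)
        return BasePairMatrix(n=n, p=p)
    raise FloatingPointError("partition function could not be rescaled into range")


def positional_profile(bpm: BasePairMatrix) -> np.ndarray:
    """Per-position probability of being paired: p_k = sum_l P_kl."""
    return bpm.p.sum(axis=1)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

ENUMERATION_CAP = 20


def _enumerate_matchings(enc: tuple[int, ...], minhp: int):
    """All pseudoknot-free pair sets over the encoded sequence."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i >= j:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + minhp + 1, j + 1):
            if PAIR_TABLE[enc[i], enc[k]] >= 0:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    return rec(0, len(enc) - 1)


def structure_energy(
    pairs: tuple[tuple[int, int], ...], enc: np.ndarray, model: EnergyModel
) -> float:
    """Loop-decomposition energy of one structure; +inf if a loop is illegal."""
    energy = 0.0
    pairs = tuple(sorted(pairs))
    for i, j in pairs:
        # direct children: pairs inside (i, j) not nested in a sibling
        children = []
        k = None
        for a, b in pairs:
            if i < a and b < j:
                if k is None or a > k:
                    children.append((a, b))
                    k = b
        if not children:
            energy += model.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            a, b = children[0]
            u = (a - i - 1) + (j - b - 1)
            if u == 0:
                pi = PAIR_TABLE[enc[i], enc[j]]
                pk = PAIR_TABLE[enc[a], enc[b]]
                energy += model.stack[pi, pk]
            else:
                if u > model.maxloop:
                    return math.inf
                energy += model.interior_energy(u)
        else:
            energy += model.multiloop_energy(len(children) + 1)
    return energy


def enumerate_structures(
    seq: str, model: EnergyModel = DEFAULT_MODEL
) -> BasePairMatrix:
    """Exact pair probabilities by Boltzmann-weighted exhaustive enumeration.

    Test oracle only: refuses sequences longer than ``ENUMERATION_CAP``.
    """
    n = len(seq)
    if n > ENUMERATION_CAP:
        raise ValueError(f"enumeration limited to length <= {ENUMERATION_CAP}")
    if n < model.min_hairpin + 2:
        return BasePairMatrix(n=n, p=np.zeros((n, n)), too_short=True)
    enc = encode(seq)
    beta = 1.0 / model.rt
    total = 0.0
    weight_sum = np.zeros((n, n))
    for pairs in _enumerate_matchings(tuple(enc), model.min_hairpin):
        e = structure_energy(pairs, enc, model)
        if not math.isfinite(e):
            continue
        w = math.exp(-beta * e)
        total += w
        for i, j in pairs:
            weight_sum[i, j] += w
    p = weight_sum / total
    p = p + p.T
    return BasePairMatrix(n=n, p=p)


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    """Number of pseudoknot-free structures (Nussinov-style counting)."""
    n = len(seq)
    enc = encode(seq)
    count = {}

    def rec(i: int, j: int) -> int:
        if i >= j:
            return 1
        if (i, j) in count:
            return count[(i, j)]
        total = rec(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if PAIR_TABLE[enc[i], enc[k]] >= 0:
                total += rec(i + 1, k - 1) * rec(k + 1, j)
        count[(i, j)] = total
        return total

    return rec(0, n - 1)


# ---------------------------------------------------------------------------
# duplex hybridization energy (used by the miRNA stage)
# ---------------------------------------------------------------------------


def duplex_energy(
    columns: list[tuple[str | None, str | None]],
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Free energy of an intermolecular duplex given alignment columns.

    ``columns`` lists (mirna_base, target_base) pairs 5'->3' along the
    miRNA; ``None`` marks a gap on that strand.  Paired columns are those
    whose two bases can form a Watson-Crick or GU pair; runs of adjacent
    paired columns contribute stacking terms, and the unpaired bases
    between two paired columns contribute an affine interior/bulge
    penalty.  The duplex initiation penalty is always added.
    """
    paired: list[tuple[int, int, int]] = []  # (column index, ptype, unpaired before)
    unpaired = 0
    for idx, (mb, tb) in enumerate(columns):
        pt = -1
        if mb is not None and tb is not None:
            pt = PAIR_TABLE[BASE_INDEX[mb], BASE_INDEX[tb]]
        if pt >= 0:
            paired.append((idx, pt, unpaired))
            unpaired = 0
        else:
            unpaired += int(mb is not None) + int(tb is not None)
    if not paired:
        return math.inf
    energy = model.duplex_init
    for k in range(1, len(paired)):
        _, pt, gap = paired[k]
        prev_pt = paired[k - 1][1]
        if gap == 0:
            energy += model.stack[prev_pt, pt]
        else:
            energy += model.interior_energy(gap)
    return energy
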