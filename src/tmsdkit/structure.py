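"""Single-strand secondary-structure ensembles and the toehold intermediate.

The engine works on the space of *nested* Watson-Crick structures (no
pseudoknots, no G.T wobble) with a minimum hairpin-loop size of 3 unpaired
bases.  A structure's free energy is the sum of nearest-neighbor stacking
terms over helically stacked pair steps plus optional per-pair terms; loop
penalties and dangling ends are deliberately omitted so that an exhaustive
enumeration oracle can score every structure exactly.

Three routes through the same structure space are provided:

* :func:`enumerate_structures` — exhaustive enumeration, the testing oracle
  for short strands;
* :func:`partition_pair_probabilities` — McCaskill-style inside/outside
  dynamic programming for Boltzmann pair probabilities;
* :func:`mfe_structure` — minimum-free-energy structure with deterministic
  tie-breaking (fewest pairs, then lexicographically smallest pair list).

The toehold-binding intermediate of a displacement reaction is modelled as a
two-state duplex: an equilibrium constant from the nearest-neighbor duplex
free energy, a bound fraction from equal-concentration mass action, and a
per-base interstrand pairing probability that discounts toehold bases already
occupied by intramolecular folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .strands import COMPLEMENT, DisplacementSystem, is_watson_crick

__all__ = [
    "EnergyModel",
    "default_energy_model",
    "SecondaryStructure",
    "PairProbabilityMatrix",
    "IntermediateState",
    "enumerate_structures",
    "structure_energy",
    "partition_pair_probabilities",
    "mfe_structure",
    "duplex_delta_g",
    "intermediate_state",
    "read_pair_probabilities",
    "write_pair_probabilities",
]

R_KCAL = 1.987204e-3  # gas constant, kcal/(mol K)

# Unified nearest-neighbor DNA stacking free energies at 37 C (kcal/mol),
# SantaLucia & Hicks 2004, keyed by the 5'->3' top-strand dinucleotide of a
# stacked Watson-Crick pair step.
SANTALUCIA_STACKS_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}


def _pair_key(a: str, b: str) -> str:
    return "".join(sorted((a, b)))


@dataclass(frozen=True)
class EnergyModel:
    """Energetic parameters of the nested-structure model.

    stack_energies are keyed by the 5'->3' top-strand dinucleotide of a
    stacked pair step; pair_energies by the sorted base pair ("AT", "CG").
    ``temperature`` sets kT; the tabulated stack free energies are treated as
    fixed model parameters (no enthalpy/entropy split).
    """

    stack_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(SANTALUCIA_STACKS_DG37)
    )
    pair_energies: Mapping[str, float] = field(default_factory=dict)
    min_loop: int = 3
    temperature: float = 298.15  # K
    duplex_init_penalty: float = 1.96  # kcal/mol, bimolecular initiation

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.min_loop < 0:
            raise ValueError("min_loop must be nonnegative")

    @property
    def kT(self) -> float:
        return R_KCAL * self.temperature

    def pair_energy(self, a: str, b: str) -> float:
        return self.pair_energies.get(_pair_key(a, b), 0.0)

    def stack_energy(self, seq: str, i: int, j: int) -> float:
        """Energy of the stack between pairs (i, j) and (i+1, j-1)."""
        return self.stack_energies.get(seq[i] + seq[i + 1], 0.0)


def default_energy_model(temperature: float = 298.15) -> EnergyModel:
    """Nearest-neighbor stacking model at the given temperature (K)."""
    return EnergyModel(temperature=temperature)


def _pairable(seq: str, i: int, j: int, min_loop: int) -> bool:
    return j - i - 1 >= min_loop and is_watson_crick(seq[i], seq[j])


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs with its model energy."""

    n: int
    pairs: tuple[tuple[int, int], ...]
    energy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair near ({i}, {j})")
            seen.update((i, j))
        for (i, j), (a, b) in zip(self.pairs, self.pairs[1:]):
            # sorted order: crossing iff i < a <= j < b
            if a <= j < b:
                raise ValueError(f"pseudoknotted pairs ({i},{j}) and ({a},{b})")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def paired_indices(self) -> set[int]:
        return {k for ij in self.pairs for k in ij}

    def hairpin_loop_bases(self) -> int:
        """Number of unpaired bases enclosed by hairpin-closing pairs."""
        paired = self.paired_indices()
        total = 0
        for i, j in self.pairs:
            if not any(i < k < j for k in paired):
                total += j - i - 1
        return total

    def dot_bracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def structure_energy(
    seq: str, pairs: Iterable[tuple[int, int]], model: EnergyModel
) -> float:
    """Energy of an explicit pair set: per-pair terms + stacked-step terms."""
    pair_set = set(pairs)
    e = 0.0
    for i, j in pair_set:
        e += model.pair_energy(seq[i], seq[j])
        if (i + 1, j - 1) in pair_set:
            e += model.stack_energy(seq, i, j)
    return e


def enumerate_structures(
    seq: str, model: EnergyModel | None = None, cap: int = 20
) -> list[SecondaryStructure]:
    """Exhaustively enumerate all nested WC structures of a short strand.

    This is the module's testing oracle; it refuses strands longer than
    ``cap`` because the structure count grows exponentially.
    """
    model = model or default_energy_model()
    n = len(seq)
    if n > cap:
        raise ValueError(f"enumeration capped at {cap} nt (got {n})")
    min_loop = model.min_loop
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def enum(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i + 1 < min_loop + 2:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if _pairable(seq, i, k, min_loop):
                for inner in enum(i + 1, k - 1):
                    for rest in enum(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        memo[key] = out
        return out

    return [
        SecondaryStructure(n=n, pairs=p, energy=structure_energy(seq, p, model))
        for p in enum(0, n - 1)
    ]


# ---------------------------------------------------------------------------
# pair probabilities (inside/outside DP)


@dataclass(frozen=True)
class PairProbabilityMatrix:
    """Equilibrium base-pairing probabilities of a single strand."""

    n: int
    p: np.ndarray  # (n, n) symmetric
    p_unpaired: np.ndarray  # (n,)
    free_energy: float = 0.0  # -kT ln Z, model units

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        pu = np.asarray(self.p_unpaired, dtype=float)
        if p.shape != (self.n, self.n) or pu.shape != (self.n,):
            raise ValueError("dimension mismatch in pair-probability matrix")
        tol = 1e-6
        if np.any(p < -tol) or np.any(p > 1 + tol):
            raise ValueError("pair probability outside [0, 1]")
        if np.any(pu < -tol) or np.any(pu > 1 + tol):
            raise ValueError("unpaired probability outside [0, 1]")
        if not np.allclose(p, p.T, atol=1e-9):
            raise ValueError("pair-probability matrix is not symmetric")
        if np.any(np.abs(p.sum(axis=1) + pu - 1.0) > 1e-6):
            raise ValueError("row sums plus unpaired probability do not reach 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "p_unpaired", pu)

    @property
    def p_paired(self) -> np.ndarray:
        return 1.0 - self.p_unpaired


def _inside_tables(seq: str, model: EnergyModel):
    """Inside partition-function tables (left-anchored decomposition)."""
    n = len(seq)
    kT = model.kT
    min_loop = model.min_loop
    q = np.zeros((n, n))  # Boltzmann weight of pair (i, j)
    sw = np.ones((n, n))  # weight of the stack between (i,j) and (i+1,j-1)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if _pairable(seq, i, j, min_loop):
                q[i, j] = math.exp(-model.pair_energy(seq[i], seq[j]) / kT)
                sw[i, j] = math.exp(-model.stack_energy(seq, i, j) / kT)

    zb = np.zeros((n, n))
    wfull = np.ones((n, n))  # W on [i, j]; empty/negative intervals read as 1

    def w(i: int, j: int) -> float:
        return 1.0 if i > j else wfull[i, j]

    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if q[i, j] > 0.0:
                w_in = w(i + 1, j - 1)
                zb_in = zb[i + 1, j - 1] if i + 1 < j - 1 else 0.0
                zb[i, j] = q[i, j] * (w_in + (sw[i, j] - 1.0) * zb_in)
            total = w(i + 1, j)
            for k in range(i + min_loop + 1, j + 1):
                if zb[i, k] > 0.0:
                    total += zb[i, k] * w(k + 1, j)
            wfull[i, j] = total
    return q, sw, zb, wfull, w


def partition_pair_probabilities(
    seq: str, model: EnergyModel | None = None
) -> PairProbabilityMatrix:
    """Boltzmann pair probabilities over all nested WC structures.

    Inside pass: standard interval partition functions with a stacking
    correction on the closing pair.  Outside pass: the exterior weight of a
    pair (i, j) sums over its innermost enclosing pair (a, b), whose strips
    decompose into independent local intervals; the only cross term with the
    interior is the (i-1, j+1) stack.
    """
    model = model or default_energy_model()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    q, sw, zb, wfull, w = _inside_tables(seq, model)
    z = w(0, n - 1)

    qe = np.zeros((n, n))  # q(a,b) * exterior(a,b), filled in row order
    ext = np.zeros((n, n))
    for i in range(n):
        left = np.array([w(a + 1, i - 1) for a in range(i)])
        for j in range(i + 1, n):
            e = w(0, i - 1) * w(j + 1, n - 1)
            if i > 0 and j < n - 1:
                right = np.array([w(j + 1, b - 1) for b in range(j + 1, n)])
                e += left @ qe[:i, j + 1 :] @ right
                # adjacent enclosing pair stacks onto (i, j)
                e += (sw[i - 1, j + 1] - 1.0) * qe[i - 1, j + 1]
            ext[i, j] = e
            qe[i, j] = q[i, j] * e

    p = np.zeros((n, n))
    upper = zb * ext / z
    p = upper + upper.T
    p_unpaired = 1.0 - p.sum(axis=1)
    return PairProbabilityMatrix(
        n=n, p=p, p_unpaired=p_unpaired, free_energy=-model.kT * math.log(z)
    )


# ---------------------------------------------------------------------------
# MFE


_EMPTY = (0.0, 0, ())


def _combine(a, b):
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def mfe_structure(seq: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy nested structure.

    Ties are broken deterministically: fewest pairs first, then the
    lexicographically smallest sorted pair list.
    """
    model = model or default_energy_model()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    min_loop = model.min_loop

    vb: dict[tuple[int, int], tuple | None] = {}
    vm: dict[tuple[int, int], tuple] = {}
    vmno: dict[tuple[int, int], tuple] = {}

    def get_vm(i, j, table):
        return table.get((i, j), _EMPTY)

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # -- vb: i pairs j
            best_b = None
            if _pairable(seq, i, j, min_loop):
                e_pair = model.pair_energy(seq[i], seq[j])
                cands = []
                inner_b = vb.get((i + 1, j - 1))
                if inner_b is not None:
                    cands.append(
                        (
                            e_pair + model.stack_energy(seq, i, j) + inner_b[0],
                            1 + inner_b[1],
                            ((i, j),) + inner_b[2],
                        )
                    )
                inner = get_vm(i + 1, j - 1, vmno)
                cands.append((e_pair + inner[0], 1 + inner[1], ((i, j),) + inner[2]))
                best_b = min(cands)
            vb[(i, j)] = best_b
            # -- vm / vmno: best on [i, j]
            cands_m = [get_vm(i + 1, j, vm)]
            cands_no = [get_vm(i + 1, j, vm)]
            for k in range(i + min_loop + 1, j + 1):
                b = vb.get((i, k))
                if b is not None:
                    cand = _combine(b, get_vm(k + 1, j, vm))
                    cands_m.append(cand)
                    if k != j:
                        cands_no.append(cand)
            vm[(i, j)] = min(cands_m)
            vmno[(i, j)] = min(cands_no)

    energy, _, pairs = vm[(0, n - 1)]
    return SecondaryStructure(n=n, pairs=pairs, energy=energy)


# ---------------------------------------------------------------------------
# toehold intermediate


@dataclass(frozen=True)
class IntermediateState:
    """Two-state toehold-duplex intermediate of the displacement reaction."""

    theta: float  # bound fraction of the toehold duplex
    interstrand_pair_prob: np.ndarray  # per toehold base, 5'->3' on invader
    complex_conc: float  # M
    delta_g: float  # standard duplex free energy, model units
    binding_k: float  # association constant, 1/M

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0 + 1e-12:
            raise ValueError("bound fraction outside [0, 1]")


def duplex_delta_g(seq: str, model: EnergyModel) -> float:
    """Standard free energy of the full WC duplex of *seq* with its complement.

    Nearest-neighbor stack sum over all steps, per-pair terms, plus the
    bimolecular initiation penalty.
    """
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 bases")
    dg = model.duplex_init_penalty
    for i in range(len(seq) - 1):
        dg += model.stack_energies.get(seq[i : i + 2], 0.0)
    for b in seq:
        dg += model.pair_energy(b, COMPLEMENT[b])
    return dg


def _bound_fraction(k_assoc: float, c0: float) -> float:
    """theta for A + B -> AB at equal initial concentrations c0."""
    x = k_assoc * c0
    if x <= 0.0:
        return 0.0
    if x < 1e-8:  # series expansion avoids catastrophic cancellation
        return x - 3.0 * x**2
    return ((1.0 + 2.0 * x) - math.sqrt(1.0 + 4.0 * x)) / (2.0 * x)


def intermediate_state(
    system: DisplacementSystem,
    model: EnergyModel | None = None,
    c0: float = 5.0e-8,
    ppm: PairProbabilityMatrix | None = None,
    binding_k: float | None = None,
) -> IntermediateState:
    """Two-state toehold hybridization between invader and substrate overhang.

    K comes from the nearest-neighbor duplex free energy of the toehold
    (overridable via ``binding_k`` for hypothetical/non-complementary cases);
    theta solves the equal-concentration mass-action quadratic; each toehold
    base's interstrand probability is theta discounted by the base's
    intramolecular pairing probability in the invader ensemble.
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    model = model or default_energy_model()
    t = system.toehold_len
    if binding_k is None:
        dg = duplex_delta_g(system.toehold, model)
        k_assoc = math.exp(-dg / model.kT)
    else:
        k_assoc = binding_k
        dg = -model.kT * math.log(binding_k) if binding_k > 0 else math.inf
    theta = _bound_fraction(k_assoc, c0)
    if ppm is None:
        ppm = partition_pair_probabilities(system.invader.sequence, model)
    p_intra = ppm.p_paired[:t]
    return IntermediateState(
        theta=theta,
        interstrand_pair_prob=theta * (1.0 - p_intra),
        complex_conc=theta * c0,
        delta_g=dg,
        binding_k=k_assoc,
    )


# ---------------------------------------------------------------------------
# ppairs-style import/export


def write_pair_probabilities(ppm: PairProbabilityMatrix, path: str | Path) -> None:
    """Write a ppairs-style text file (1-based; row n+1 = unpaired)."""
    lines = [str(ppm.n)]
    for i in range(ppm.n):
        for j in range(i + 1, ppm.n):
            if ppm.p[i, j] > 0.0:
                lines.append(f"{i + 1} {j + 1} {ppm.p[i, j]:.17g}")
        lines.append(f"{i + 1} {ppm.n + 1} {ppm.p_unpaired[i]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pair_probabilities(path: str | Path) -> PairProbabilityMatrix:
    """Parse a ppairs-style text file into a validated matrix.

    Format: a header line with n, then lines ``i j p`` with 1-based indices;
    j = n+1 encodes the unpaired probability of base i.  Missing unpaired
    rows are inferred as 1 minus the row sum.
    """
    text = Path(path).read_text()
    rows = [ln.strip() for ln in text.splitlines()]
    rows = [ln for ln in rows if ln and not ln.startswith(("%", "#"))]
    if not rows:
        raise ValueError("empty ppairs file")
    try:
        n = int(rows[0])
    except ValueError as exc:
        raise ValueError(f"bad ppairs header {rows[0]!r}") from exc
    if n <= 0:
        raise ValueError("ppairs header must be a positive length")
    p = np.zeros((n, n))
    pu = np.full(n, np.nan)
    for ln in rows[1:]:
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"malformed ppairs line {ln!r}")
        try:
            i, j, prob = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed ppairs line {ln!r}") from exc
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"probability outside [0, 1] on line {ln!r}")
        if not (1 <= i <= n and 1 <= j <= n + 1 and i != j):
            raise ValueError(f"indices out of range on line {ln!r}")
        if j == n + 1:
            pu[i - 1] = prob
        else:
            p[i - 1, j - 1] = prob
            p[j - 1, i - 1] = prob
    row_sums = p.sum(axis=1)
    if np.any(row_sums > 1.0 + 1e-6):
        raise ValueError("pair probabilities in a row sum to more than 1")
    pu = np.where(np.isnan(pu), 1.0 - row_sums, pu)
    return PairProbabilityMatrix(n=n, p=p, p_unpaired=pu)
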