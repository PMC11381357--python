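"""The 16 sequence/structure/intermediate variables (X1..X16).

Each displacement system is summarized by sixteen variables built from the
invader strand's equilibrium ensemble, its MFE structure, and the two-state
toehold intermediate.  They fall into three groups:

* free bases and free hydrogen-bonding sites (X1, X2, X4, X5, X8), using the
  per-base H-bond capacity h(A)=h(T)=2, h(G)=h(C)=3;
* primary/secondary-structure composition of the invader (X3, X6, X7, X9,
  X10, X11, X12, X13);
* the toehold intermediate (X14, X15, X16).

Ensemble-weighted quantities use pairing probabilities rather than integer
MFE counts, so e.g. X11 (hydrogen bonds tied up by intramolecular pairing)
is generally non-integer.  The exact identity X5 = X7 - 2*X11 follows from
counting each pair's H-bonds on both partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .strands import DisplacementSystem
from .structure import (
    EnergyModel,
    IntermediateState,
    PairProbabilityMatrix,
    SecondaryStructure,
    default_energy_model,
    intermediate_state,
    mfe_structure,
    partition_pair_probabilities,
)

__all__ = [
    "HBOND_CAPACITY",
    "hbond_capacity",
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_features",
    "featurize_system",
    "features_to_frame",
    "rank_by_key",
    "design_rule_report",
]

#: Hydrogen bonds a base contributes in a Watson-Crick pair.
HBOND_CAPACITY = {"A": 2, "T": 2, "G": 3, "C": 3}

FEATURE_NAMES = tuple(f"X{i}" for i in range(1, 17))

FEATURE_DESCRIPTIONS: Mapping[str, str] = {
    "X1": "free bases in the toehold",
    "X2": "free H-bond sites in the toehold",
    "X3": "G/C count in the toehold",
    "X4": "free bases in the invader",
    "X5": "free H-bond sites in the invader",
    "X6": "total H-bond capacity of the toehold",
    "X7": "total H-bond capacity of the invader",
    "X8": "free bases in the branch-migration region",
    "X9": "ensemble H-bond pairs touching the branch-migration region",
    "X10": "ensemble free energy of the invader (model units)",
    "X11": "ensemble intramolecular H-bond count of the invader",
    "X12": "bases in MFE hairpin loops",
    "X13": "pair count of the MFE structure",
    "X14": "H-bonds in the toehold intermediate",
    "X15": "intermediate content (complex concentration, M)",
    "X16": "standard free energy of the toehold duplex (model units)",
}


def hbond_capacity(base: str) -> int:
    """H-bond capacity of a single base: A/T -> 2, G/C -> 3."""
    try:
        return HBOND_CAPACITY[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}") from None


@dataclass(frozen=True)
class FeatureVector:
    """The sixteen variables of one displacement system, in X1..X16 order."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 16:
            raise ValueError("a feature vector has exactly 16 entries")

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def compute_features(
    system: DisplacementSystem,
    ppm: PairProbabilityMatrix,
    mfe: SecondaryStructure,
    inter: IntermediateState,
) -> FeatureVector:
    """Assemble X1..X16 from a system and its precomputed ensemble objects.

    ``ppm`` and ``mfe`` describe the invader strand; ``inter`` the two-state
    toehold intermediate.  Deterministic; depends only on sequences and the
    supplied ensemble, never on strand ids.
    """
    inv = system.invader.sequence
    n = len(inv)
    t = system.toehold_len
    if ppm.n != n:
        raise ValueError(f"pair-probability matrix is {ppm.n} nt, invader is {n} nt")
    if mfe.n != n:
        raise ValueError(f"MFE structure is {mfe.n} nt, invader is {n} nt")
    if len(inter.interstrand_pair_prob) != t:
        raise ValueError("intermediate state does not match the toehold length")

    h = np.array([HBOND_CAPACITY[b] for b in inv], dtype=float)
    p_free = ppm.p_unpaired

    x1 = float(p_free[:t].sum())
    x2 = float((h[:t] * p_free[:t]).sum())
    x3 = float(sum(b in "GC" for b in inv[:t]))
    x4 = float(p_free.sum())
    x5 = float((h * p_free).sum())
    x6 = float(h[:t].sum())
    x7 = float(h.sum())
    x8 = float(p_free[t:].sum())

    iu, ju = np.triu_indices(n, k=1)
    pij = ppm.p[iu, ju]
    touches_branch = (iu >= t) | (ju >= t)
    x9 = float(pij[touches_branch].sum())
    x10 = float(ppm.free_energy)
    # WC pairing means both partners share one capacity, so h_pair = h[i]
    x11 = float((pij * h[iu]).sum())
    x12 = float(mfe.hairpin_loop_bases())
    x13 = float(mfe.n_pairs)
    x14 = float((h[:t] * inter.interstrand_pair_prob).sum())
    x15 = float(inter.complex_conc)
    x16 = float(inter.delta_g)

    return FeatureVector(
        values=(
            x1, x2, x3, x4, x5, x6, x7, x8,
            x9, x10, x11, x12, x13, x14, x15, x16,
        )
    )


def featurize_system(
    system: DisplacementSystem,
    model: EnergyModel | None = None,
    c0: float = 5.0e-8,
    ppm: PairProbabilityMatrix | None = None,
) -> FeatureVector:
    """Run ensemble, MFE and intermediate for one system and featurize it.

    ``ppm`` may be supplied (e.g. imported from an external ppairs file) to
    replace the builtin partition-function engine for the invader ensemble.
    """
    model = model or default_energy_model()
    if ppm is None:
        ppm = partition_pair_probabilities(system.invader.sequence, model)
    mfe = mfe_structure(system.invader.sequence, model)
    inter = intermediate_state(system, model, c0=c0, ppm=ppm)
    return compute_features(system, ppm, mfe, inter)


def features_to_frame(
    ids: Sequence[str], vectors: Sequence[FeatureVector]
) -> pd.DataFrame:
    """Feature table with sample_id plus the fixed X1..X16 column order."""
    df = pd.DataFrame([fv.values for fv in vectors], columns=list(FEATURE_NAMES))
    df.insert(0, "sample_id", list(ids))
    return df


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0.0:
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def rank_by_key(
    vectors: Sequence[FeatureVector] | pd.DataFrame,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Order near-identical designs by the X2/X5/X11 key.

    Score = z(X2) + z(X5) - z(X11) within the given set: many free H-bond
    sites in the toehold and the whole invader, and few sites consumed by
    intramolecular pairing, predict fast displacement.  Returns a frame
    sorted fastest-first with ``score``, ``rank`` and a ``tied`` flag; ties
    keep input order.
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors
        ids = df["sample_id"].tolist() if "sample_id" in df else list(df.index)
        x2 = df["X2"].to_numpy(float)
        x5 = df["X5"].to_numpy(float)
        x11 = df["X11"].to_numpy(float)
    else:
        vectors = list(vectors)
        if not vectors:
            raise ValueError("rank_by_key needs at least one feature vector")
        ids = list(ids) if ids is not None else [str(i) for i in range(len(vectors))]
        x2 = np.array([fv["X2"] for fv in vectors])
        x5 = np.array([fv["X5"] for fv in vectors])
        x11 = np.array([fv["X11"] for fv in vectors])
    if len(x2) == 0:
        raise ValueError("rank_by_key needs at least one feature vector")

    score = _zscore(x2) + _zscore(x5) - _zscore(x11)
    out = pd.DataFrame({"sample_id": ids, "score": score})
    # stable sort keeps input order within ties
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    rounded = np.round(out["score"].to_numpy(), 12)
    counts = pd.Series(rounded).value_counts()
    out["tied"] = [counts[v] > 1 for v in rounded]
    return out


def design_rule_report(
    system: DisplacementSystem,
    fv: FeatureVector,
    mfe: SecondaryStructure,
    max_toehold_len: int = 6,
    min_gc_fraction: float = 0.5,
    max_occluded_toehold_bases: int = 2,
) -> dict:
    """Check a design against the three fast-displacement rules.

    (i) use the full toehold length budget; (ii) keep the toehold G/C-rich
    so it offers many H-bond sites; (iii) avoid intramolecular pairing that
    occludes toehold bases in the invader's MFE structure.  Thresholds are
    configurable; the report is JSON-serializable.
    """
    t = system.toehold_len
    gc_fraction = fv["X3"] / t
    occluded = sum(1 for i, j in mfe.pairs for k in (i, j) if k < t)
    rules = {
        "toehold_length": {
            "passed": t >= max_toehold_len,
            "value": t,
            "threshold": max_toehold_len,
            "explanation": (
                f"toehold has {t} bases of the {max_toehold_len}-base budget; "
                "longer toeholds accelerate displacement up to saturation"
            ),
        },
        "gc_content": {
            "passed": gc_fraction >= min_gc_fraction,
            "value": gc_fraction,
            "threshold": min_gc_fraction,
            "explanation": (
                f"toehold G/C fraction is {gc_fraction:.2f}; G/C pairs "
                "contribute three H-bonds each and stabilize the intermediate"
            ),
        },
        "toehold_occlusion": {
            "passed": occluded <= max_occluded_toehold_bases,
            "value": occluded,
            "threshold": max_occluded_toehold_bases,
            "explanation": (
                f"{occluded} toehold base(s) paired intramolecularly in the "
                f"invader MFE structure ({int(fv['X13'])} pairs total); "
                "occluded toeholds slow nucleation"
            ),
        },
    }
    return {
        "sample_id": system.system_id,
        "all_passed": all(r["passed"] for r in rules.values()),
        "rules": rules,
    }
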