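"""Synthetic TMSD study generator.

Emulates the study design end-to-end so every downstream stage is testable
without raw instrument data: random 6-nt toeholds on a fixed 16-nt
branch-migration region, a planted monotone dependence of log10 k on the
X2/X5/X11 key variables, second-order fluorescence traces with linear
calibration, a constant background and additive Gaussian read noise, and
four-temperature Arrhenius series (15/20/25/30 C).

Randomness is split per-system from a master seed (numpy SeedSequence
spawning), so extending ``n_systems`` never perturbs earlier systems.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .kinetics import R_GAS, KineticTrace
from .strands import DNA_ALPHABET, DisplacementSystem

__all__ = [
    "DEFAULT_BRANCH_SEQ",
    "SyntheticConfig",
    "system_rng",
    "gen_systems",
    "planted_log_rate",
    "simulate_trace",
    "arrhenius_rate",
    "simulate_temperature_series",
    "simulate_standard_curve",
    "simulate_background_reading",
    "write_systems_csv",
    "write_systems_fasta",
    "write_traces_csv",
]

#: Default fixed branch-migration 16-mer: the canonical branch-migration
#: domain of the Zhang & Winfree (2009) toehold-exchange system.  The region
#: is a config field so any experimental branch sequence can be substituted.
DEFAULT_BRANCH_SEQ = "CCACATACATCATATT"

BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    The planted rate model is log10 k = b0 + sum_f beta_f X_f + eps with
    eps ~ Normal(0, noise_sd_log10k); its default coefficients reproduce the
    observed monotonicity (faster with higher X2/X5, slower with higher X11)
    and place the planted rates across the three kinetic classes at
    c0 = 50 nM.
    """

    n_systems: int = 100
    toehold_len: int = 6
    branch_seq: str = DEFAULT_BRANCH_SEQ
    seed: int = 0
    planted_coeffs: Mapping[str, float] = field(
        default_factory=lambda: {"X2": 0.08, "X5": 0.05, "X11": -0.15}
    )
    planted_intercept: float = 4.0
    noise_sd_log10k: float = 0.25
    c0: float = 5.0e-8  # M; 50 nM after 1:1 mixing of 100 nM stocks
    calibration: tuple[float, float] = (10.0, 0.0)  # slope a.u./nM, intercept a.u.
    background: float = 50.0  # a.u.
    trace_noise_sd: float = 5.0  # a.u., ~1% of the 50 nM amplitude
    dt: float = 5.0  # s
    duration: float = 7200.0  # s
    temps_c: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0)
    ea: float = 60000.0  # J/mol
    ln_a: float = 37.0

    def __post_init__(self) -> None:
        if self.n_systems < 0:
            raise ValueError("n_systems must be nonnegative")
        if self.toehold_len < 1:
            raise ValueError("toehold_len must be at least 1")
        bad = set(self.branch_seq) - DNA_ALPHABET
        if bad or not self.branch_seq:
            raise ValueError(f"branch_seq must be nonempty over ACGT (bad: {sorted(bad)})")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if not self.temps_c:
            raise ValueError("temps_c must be nonempty")
        if self.ea < 0:
            raise ValueError("activation energy must be nonnegative")
        unknown = set(self.planted_coeffs) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names in planted_coeffs: {sorted(unknown)}")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = dataclasses.asdict(self)
        doc["planted_coeffs"] = dict(self.planted_coeffs)
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        doc = json.loads(Path(path).read_text())
        doc["calibration"] = tuple(doc["calibration"])
        doc["temps_c"] = tuple(doc["temps_c"])
        return cls(**doc)


def system_rng(cfg: SyntheticConfig, idx: int, stream: int) -> np.random.Generator:
    """Independent per-system random stream derived from the master seed.

    Streams: 0 toehold sequence, 1 planted-rate noise, 2 trace noise.
    Spawn keys make each (system, stream) pair independent, so extending
    ``n_systems`` never perturbs earlier systems.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx, stream))
    )


def gen_systems(cfg: SyntheticConfig) -> list[DisplacementSystem]:
    """Random-toehold displacement systems on the fixed branch region.

    Each invader is a uniform random toehold (5' end) followed by the branch
    sequence; substrate and incumbent follow by complementarity.
    Deterministic given ``cfg.seed``.
    """
    systems = []
    for idx in range(cfg.n_systems):
        rng = system_rng(cfg, idx, 0)
        toehold = "".join(rng.choice(list(BASES), size=cfg.toehold_len))
        systems.append(
            DisplacementSystem.from_invader(
                f"syn{idx:04d}", toehold + cfg.branch_seq, cfg.toehold_len
            )
        )
    return systems


def planted_log_rate(
    fv: FeatureVector,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Planted ground-truth rate constant (1/(M s)) for a feature vector.

    log10 k = intercept + sum of coefficient * feature + Gaussian noise.
    With ``noise_sd_log10k == 0`` (or no rng) the value is a deterministic
    function of the features.
    """
    log10k = cfg.planted_intercept
    for name, beta in cfg.planted_coeffs.items():
        log10k += beta * fv[name]
    if rng is not None and cfg.noise_sd_log10k > 0:
        log10k += rng.normal(0.0, cfg.noise_sd_log10k)
    return float(10.0**log10k)


def simulate_trace(
    k: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    temperature: float = 25.0,
    sample_id: str = "",
) -> KineticTrace:
    """Second-order fluorescence trace for rate constant *k*.

    c(t) = c0 (k c0 t) / (1 + k c0 t); intensity = slope * c(nM) + intercept
    + background + Normal(0, trace_noise_sd).  Pass ``rng=None`` for a
    noise-free trace.
    """
    if k < 0:
        raise ValueError("rate constant must be nonnegative")
    times = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    kt = k * cfg.c0 * times
    conc_nm = cfg.c0 * 1e9 * kt / (1.0 + kt)
    slope, intercept = cfg.calibration
    intensities = slope * conc_nm + intercept + cfg.background
    if rng is not None and cfg.trace_noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensities = intensities + rng.normal(0.0, cfg.trace_noise_sd, times.size)
    return KineticTrace(
        times=times,
        intensities=intensities,
        temperature=temperature,
        sample_id=sample_id,
    )


def arrhenius_rate(cfg: SyntheticConfig, temp_c: float) -> float:
    """k(T) = exp(lnA - Ea / (R T)) at a Celsius temperature."""
    return float(np.exp(cfg.ln_a - cfg.ea / (R_GAS * (temp_c + 273.15))))


def simulate_temperature_series(
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "",
) -> dict[float, KineticTrace]:
    """One trace per configured temperature with Arrhenius-scaled rates."""
    if not cfg.temps_c:
        raise ValueError("temps_c must be nonempty")
    if rng is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return {
        t: simulate_trace(
            arrhenius_rate(cfg, t), cfg, rng=rng, temperature=t, sample_id=sample_id
        )
        for t in cfg.temps_c
    }


STANDARD_CURVE_CONCS_NM = (10.0, 25.0, 50.0, 75.0, 100.0)


def simulate_standard_curve(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence readings of the reporter-duplex dilution series.

    The dilutions contain no quencher, so readings follow the calibration
    line alone (plus read noise when an rng is given).
    """
    concs = np.asarray(STANDARD_CURVE_CONCS_NM)
    slope, intercept = cfg.calibration
    intensities = slope * concs + intercept
    if rng is not None and cfg.trace_noise_sd > 0:
        intensities = intensities + rng.normal(0.0, cfg.trace_noise_sd, concs.size)
    return concs, intensities


def simulate_background_reading(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> float:
    """Reading of the quenched starting duplex alone (zero product)."""
    reading = cfg.background + cfg.calibration[1]
    if rng is not None and cfg.trace_noise_sd > 0:
        reading += float(rng.normal(0.0, cfg.trace_noise_sd))
    return float(reading)


# ---------------------------------------------------------------------------
# serialization


def write_systems_csv(systems: Sequence[DisplacementSystem], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.system_id for s in systems],
            "invader": [s.invader.sequence for s in systems],
            "substrate": [s.substrate.sequence for s in systems],
            "incumbent": [s.incumbent.sequence for s in systems],
            "toehold_len": [s.toehold_len for s in systems],
        }
    ).to_csv(path, index=False)


def write_systems_fasta(systems: Sequence[DisplacementSystem], path: str | Path) -> None:
    """FASTA triplets: >{id}_I / _F / _Q records per system."""
    with open(path, "w") as fh:
        for s in systems:
            for strand in (s.invader, s.substrate, s.incumbent):
                fh.write(f">{strand.id} toehold_len={s.toehold_len}\n")
                fh.write(strand.sequence + "\n")


def write_traces_csv(traces: Sequence[KineticTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.times,
                "intensity": tr.intensities,
                "temp_C": tr.temperature,
                "sample_id": tr.sample_id,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
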