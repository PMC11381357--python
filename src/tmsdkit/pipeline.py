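"""End-to-end study pipeline: simulate/load -> fit -> featurize -> train.

Artifacts (CSV tables, JSON reports, a manifest with config hash and file
checksums) are written to an output directory and regenerate bit-identically
from the same (inputs, config, seed).  All randomness flows from one master
seed; stage and per-sample streams are derived, never ambient.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import features as feat
from . import kinetics as kin
from . import mleval, synthetic
from .strands import DisplacementSystem, DnaStrand
from .structure import (
    EnergyModel,
    default_energy_model,
    intermediate_state,
    mfe_structure,
    partition_pair_probabilities,
    read_pair_probabilities,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_sequences",
    "load_traces",
    "build_labeled_dataset",
]

log = logging.getLogger("tmsdkit")


@dataclass(frozen=True)
class PipelineConfig:
    """Study configuration: paths, generator settings, analysis settings."""

    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    mode: str = "synthetic"  # synthetic | data
    sequences_path: str | None = None
    traces_path: str | None = None
    ppairs_dir: str | None = None
    out_dir: str = "tmsd_out"
    # kinetics settings
    f_star: float = 0.95
    t_fast: float = 1000.0
    t_slow: float = 3600.0
    replicates: int = 3
    n_arrhenius_systems: int = 3
    # ml settings
    split_frac: float = 0.8
    cv_folds: int = 5
    n_trees: int = 500
    models: tuple[str, ...] = mleval.MODEL_SPECS
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "data"):
            raise ValueError("mode must be 'synthetic' or 'data'")
        if not 0 < self.t_fast < self.t_slow:
            raise ValueError("thresholds must satisfy 0 < t_fast < t_slow")
        if not 0 < self.f_star < 1:
            raise ValueError("f_star must lie in (0, 1)")
        if self.mode == "data":
            if self.sequences_path is None:
                raise ValueError("config key 'sequences_path' is required in data mode")
            if self.traces_path is None:
                raise ValueError("config key 'traces_path' is required in data mode")

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    def energy_model(self) -> EnergyModel:
        return default_energy_model(self.temperature_k)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["synthetic"]["planted_coeffs"] = dict(self.synthetic.planted_coeffs)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        doc = dict(doc)
        if "synthetic" in doc and isinstance(doc["synthetic"], Mapping):
            syn = dict(doc["synthetic"])
            for key in ("calibration", "temps_c"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            doc["synthetic"] = synthetic.SyntheticConfig(**syn)
        if "models" in doc:
            doc["models"] = tuple(doc["models"])
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(doc or {})

    def config_hash(self) -> str:
        doc = self.to_dict()
        doc.pop("out_dir", None)  # identical studies may land in different dirs
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# loaders


def load_sequences(path: str | Path) -> list[DisplacementSystem]:
    """Read displacement systems from a CSV table or FASTA triplets.

    CSV columns: id, invader, substrate, incumbent [, toehold_len].  FASTA
    records come in triplets named {id}_I, {id}_F, {id}_Q with an optional
    ``toehold_len=N`` tag in the invader description.  Complementarity
    violations are collected and reported per row with offending positions.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, str, int]] = []
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        records = {rec.id: rec for rec in SeqIO.parse(str(path), "fasta")}
        ids = sorted({rid[:-2] for rid in records if rid.endswith("_I")})
        for sid in ids:
            try:
                inv, sub, inc = (records[f"{sid}_{x}"] for x in "IFQ")
            except KeyError as exc:
                raise ValueError(f"incomplete FASTA triplet for {sid!r}: {exc}")
            toehold_len = 6
            for token in inv.description.split():
                if token.startswith("toehold_len="):
                    toehold_len = int(token.split("=", 1)[1])
            rows.append(
                (sid, str(inv.seq), str(sub.seq), str(inc.seq), toehold_len)
            )
    else:
        df = pd.read_csv(path, dtype={"id": str})
        for col in ("id", "invader", "substrate", "incumbent"):
            if col not in df.columns:
                raise ValueError(f"sequence table is missing column {col!r}")
        for _, r in df.iterrows():
            rows.append(
                (
                    r["id"],
                    r["invader"],
                    r["substrate"],
                    r["incumbent"],
                    int(r.get("toehold_len", 6)),
                )
            )

    systems, errors = [], []
    for sid, inv, sub, inc, t_len in rows:
        try:
            systems.append(
                DisplacementSystem(
                    invader=DnaStrand(f"{sid}_I", inv, "invader"),
                    substrate=DnaStrand(f"{sid}_F", sub, "substrate"),
                    incumbent=DnaStrand(f"{sid}_Q", inc, "incumbent"),
                    toehold_len=t_len,
                )
            )
        except ValueError as exc:
            errors.append(f"{sid}: {exc}")
    if errors:
        raise ValueError("invalid displacement systems:\n" + "\n".join(errors))
    return systems


def load_traces(path: str | Path) -> list[kin.KineticTrace]:
    """Read kinetic traces from CSV (time_s, intensity, temp_C, sample_id).

    Rows are grouped by (sample_id, temp_C) and sorted by time within each
    group; duplicate (sample, temperature, time) rows are an error.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "intensity", "temp_C", "sample_id"):
        if col not in df.columns:
            raise ValueError(f"trace table is missing column {col!r}")
    dup = df.duplicated(subset=["sample_id", "temp_C", "time_s"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "temp_C", "time_s"]].iloc[0].tolist()
        raise ValueError(f"duplicate trace row (sample, temp, time) = {first}")
    traces = []
    for (sid, temp), grp in df.groupby(["sample_id", "temp_C"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            kin.KineticTrace(
                times=grp["time_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                temperature=float(temp),
                sample_id=str(sid),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# stages


class _EnsembleCache:
    """Memoize per-invader ensemble objects (the branch region is shared)."""

    def __init__(self, model: EnergyModel):
        self.model = model
        self._store: dict[str, tuple] = {}

    def get(self, seq: str):
        if seq not in self._store:
            self._store[seq] = (
                partition_pair_probabilities(seq, self.model),
                mfe_structure(seq, self.model),
            )
        return self._store[seq]


def featurize_systems(
    systems: Sequence[DisplacementSystem],
    model: EnergyModel,
    c0: float,
    ppairs_dir: str | Path | None = None,
    cache: _EnsembleCache | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Feature table for a list of systems (optionally with imported ppairs).

    Returns the table plus the per-system ensemble objects needed by the
    design-rule report.
    """
    cache = cache or _EnsembleCache(model)
    vectors, ensembles = [], {}
    for s in systems:
        seq = s.invader.sequence
        ppm, mfe = cache.get(seq)
        if ppairs_dir is not None:
            candidate = Path(ppairs_dir) / f"{s.system_id}.ppairs"
            if candidate.exists():
                ppm = read_pair_probabilities(candidate)
        inter = intermediate_state(s, model, c0=c0, ppm=ppm)
        vectors.append(feat.compute_features(s, ppm, mfe, inter))
        ensembles[s.system_id] = (ppm, mfe, inter)
    table = feat.features_to_frame([s.system_id for s in systems], vectors)
    return table, ensembles


def simulate_study(
    cfg: PipelineConfig,
) -> tuple[list[DisplacementSystem], pd.DataFrame, dict, pd.DataFrame]:
    """Generate systems, features, planted rates and fitted-rate table.

    Returns (systems, feature table, ensembles, rate-fit table).  The rate
    table carries both the planted ground truth (k_true) and the constant
    recovered from simulated noisy traces via the calibration route (k).
    """
    scfg = cfg.synthetic
    model = cfg.energy_model()
    systems = synthetic.gen_systems(scfg)
    features_df, ensembles = featurize_systems(
        systems, model, scfg.c0, cfg.ppairs_dir
    )

    calib_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scfg.seed, spawn_key=(0xCA11B,))
    )
    concs, readings = synthetic.simulate_standard_curve(scfg, calib_rng)
    calib = kin.fit_standard_curve(concs, readings)
    background = synthetic.simulate_background_reading(scfg, calib_rng) - calib.intercept

    records = []
    for idx, system in enumerate(systems):
        fv = feat.FeatureVector(
            tuple(features_df.loc[idx, list(feat.FEATURE_NAMES)].astype(float))
        )
        k_true = synthetic.planted_log_rate(fv, scfg, synthetic.system_rng(scfg, idx, 1))
        trace_rng = synthetic.system_rng(scfg, idx, 2)
        fits = []
        for _ in range(max(1, cfg.replicates)):
            trace = synthetic.simulate_trace(
                k_true, scfg, rng=trace_rng, sample_id=system.system_id
            )
            conc = kin.trace_to_concentration(trace, calib, background)
            fits.append(
                kin.fit_rate_constant(trace.times, conc, scfg.c0, cfg.f_star)
            )
        k_hat = kin.fit_replicates(fits)
        if k_hat > 0:
            t_eq = kin.time_to_equilibrium(k_hat, scfg.c0, cfg.f_star)
            rate_class = kin.classify_rate(t_eq, (cfg.t_fast, cfg.t_slow))
        else:
            t_eq, rate_class = float("inf"), 2
            log.warning("no reaction detected for %s", system.system_id)
        records.append(
            {
                "sample_id": system.system_id,
                "k": k_hat,
                "k_true": k_true,
                "sse": float(np.mean([f.sse for f in fits])),
                "t_eq": t_eq,
                "rate_class": rate_class,
                "invader_len": len(system.invader),
            }
        )
    rates_df = pd.DataFrame.from_records(records)
    return systems, features_df, ensembles, rates_df


def build_labeled_dataset(
    features_df: pd.DataFrame, rates_df: pd.DataFrame
) -> mleval.LabeledDataset:
    return mleval.assemble_dataset(features_df, rates_df)


def _arrhenius_stage(cfg: PipelineConfig, systems) -> pd.DataFrame:
    """Temperature-series simulation + Arrhenius fits for a few systems."""
    scfg = cfg.synthetic
    concs, readings = synthetic.simulate_standard_curve(scfg, None)
    calib = kin.fit_standard_curve(concs, readings)
    background = synthetic.simulate_background_reading(scfg, None) - calib.intercept
    rows = []
    for idx, system in enumerate(systems[: cfg.n_arrhenius_systems]):
        series = synthetic.simulate_temperature_series(
            scfg, rng=synthetic.system_rng(scfg, idx, 3), sample_id=system.system_id
        )
        k_by_t = {}
        for temp, trace in series.items():
            conc = kin.trace_to_concentration(trace, calib, background)
            fit = kin.fit_rate_constant(trace.times, conc, scfg.c0, cfg.f_star)
            if fit.k > 0:
                k_by_t[temp] = fit.k
        if len(k_by_t) >= 2:
            arr = kin.arrhenius_fit(k_by_t)
            rows.append(
                {
                    "sample_id": system.system_id,
                    "Ea_J_per_mol": arr.ea,
                    "lnA": arr.ln_a,
                    "r_squared": arr.r_squared,
                    "n_temperatures": arr.n_temperatures,
                }
            )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole study and write the artifact bundle.

    Synthetic mode simulates everything from the master seed; data mode
    loads sequences and traces from the configured paths.  On failure,
    partially written outputs from this run are removed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def emit_json(obj, name: str) -> Path:
        p = out / name
        _write_json(obj, p)
        written.append(p)
        return p

    try:
        model = cfg.energy_model()
        if cfg.mode == "synthetic":
            systems, features_df, ensembles, rates_df = simulate_study(cfg)
            synthetic.write_systems_csv(systems, out / "systems.csv")
            written.append(out / "systems.csv")
            arr_df = _arrhenius_stage(cfg, systems)
            if len(arr_df):
                emit_csv(arr_df, "arrhenius.csv")
        else:
            systems = load_sequences(cfg.sequences_path)
            features_df, ensembles = featurize_systems(
                systems, model, cfg.synthetic.c0, cfg.ppairs_dir
            )
            traces = load_traces(cfg.traces_path)
            rates_df = _fit_loaded_traces(cfg, systems, traces)

        emit_csv(features_df, "features.csv")
        emit_csv(rates_df, "rate_fits.csv")

        ds = build_labeled_dataset(features_df, rates_df)
        emit_csv(ds.frame, "dataset.csv")

        importance = mleval.feature_importance(ds, cfg.n_trees, cfg.seed)
        emit_json(importance.as_dict(), "importance.json")
        corr = mleval.pearson_correlations(ds)
        corr.to_csv(out / "correlations.csv")
        written.append(out / "correlations.csv")

        class_counts = ds.frame["rate_class"].value_counts()
        cv_folds = int(min(cfg.cv_folds, class_counts.min()))
        if cv_folds < cfg.cv_folds:
            log.warning("reducing CV folds to %d (smallest class)", cv_folds)
        reports = {}
        for spec in cfg.models:
            rep = mleval.train_and_evaluate(
                ds, spec, cfg.split_frac, max(cv_folds, 2), cfg.seed
            )
            reports[spec] = rep.to_dict()
        emit_json(reports, "eval_report.json")

        ranking = feat.rank_by_key(features_df)
        emit_csv(ranking, "ranking.csv")

        rules = [
            feat.design_rule_report(s, _fv_from_row(features_df, i), ensembles[s.system_id][1])
            for i, s in enumerate(systems)
        ]
        emit_json(rules, "design_rules.json")

        # the recorded config omits the output location so that identical
        # studies written to different directories hash identically
        emit_json(
            {k: v for k, v in cfg.to_dict().items() if k != "out_dir"},
            "config.json",
        )
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "inputs": [
                p for p in (cfg.sequences_path, cfg.traces_path, cfg.ppairs_dir) if p
            ],
            "outputs": {
                p.name: _sha256(p) for p in sorted(written, key=lambda q: q.name)
            },
        }
        emit_json(manifest, "manifest.json")
        return {
            "out_dir": str(out),
            "manifest": manifest,
            "dataset": ds,
            "importance": importance,
            "reports": reports,
        }
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _fv_from_row(features_df: pd.DataFrame, idx: int) -> feat.FeatureVector:
    return feat.FeatureVector(
        tuple(features_df.loc[idx, list(feat.FEATURE_NAMES)].astype(float))
    )


def _fit_loaded_traces(cfg, systems, traces) -> pd.DataFrame:
    """Fit rate constants for externally measured traces (data mode).

    Calibration parameters come from the config's synthetic block, which in
    data mode doubles as the instrument description.
    """
    scfg = cfg.synthetic
    slope, intercept = scfg.calibration
    calib = kin.CalibrationCurve(slope=slope, intercept=intercept, r_squared=1.0)
    by_sample: dict[str, list] = {}
    for tr in traces:
        by_sample.setdefault(tr.sample_id, []).append(tr)
    lens = {s.system_id: len(s.invader) for s in systems}
    records = []
    for sid, trs in sorted(by_sample.items()):
        fits = []
        for tr in trs:
            conc = kin.trace_to_concentration(tr, calib, scfg.background)
            fits.append(kin.fit_rate_constant(tr.times, conc, scfg.c0, cfg.f_star))
        k_hat = kin.fit_replicates(fits)
        t_eq = (
            kin.time_to_equilibrium(k_hat, scfg.c0, cfg.f_star)
            if k_hat > 0
            else float("inf")
        )
        records.append(
            {
                "sample_id": sid,
                "k": k_hat,
                "sse": float(np.mean([f.sse for f in fits])),
                "t_eq": t_eq,
                "rate_class": kin.classify_rate(t_eq, (cfg.t_fast, cfg.t_slow))
                if k_hat > 0
                else 2,
                "invader_len": lens.get(sid, -1),
            }
        )
    return pd.DataFrame.from_records(records)
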