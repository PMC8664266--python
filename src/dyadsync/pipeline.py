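"""Config-driven end-to-end runs.

``run_contrast`` drives preprocess -> interbrain -> permstats for a
two-condition within-dyad contrast and writes a connectivity table, a
stats report and a provenance log. ``run_brain_behavior`` correlates
neural and behavioral change scores at a target electrode pair.

Inputs come either from a manifest of recording files (TSV or EDF, plus
behavior CSVs) or from a named synthetic scenario.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, behavior, interbrain, io, permstats, preprocess, synth
from .datatypes import BandSpec, MatchedDyadEpochs, PairGrid, Recording

__all__ = ["RunConfig", "ConfigError", "scenario_config", "run_contrast", "run_brain_behavior"]

SCENARIOS = ("null", "c4p8-contrast", "engagement")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    conditions: tuple[str, str] = ("blank", "BO")
    scenario: str | None = None
    n_dyads: int = 10
    manifest: list[dict[str, Any]] = field(default_factory=list)
    band: BandSpec = field(default_factory=BandSpec)
    grid: PairGrid = field(default_factory=PairGrid)
    low: float = 1.0
    high: float = 50.0
    reject: bool = True
    ica_template: str | None = None  # "ocular" or None
    min_seconds: float = 60.0
    cap_seconds: float | None = 90.0
    min_epochs: int = 20
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    target_pair: tuple[str, str] = ("C4", "P8")
    out_dir: str = "results"
    sim_overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ConfigError("exactly two contrast conditions are required")
        if self.scenario is None and not self.manifest:
            raise ConfigError("either a synth scenario or a manifest is required")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.manifest:
            present: dict[str, set[str]] = {}
            for entry in self.manifest:
                for key in ("dyad_id", "condition", "infant", "adult"):
                    if key not in entry:
                        raise ConfigError(f"manifest entry missing {key!r}: {entry}")
                for key in ("infant", "adult", "gaze", "affect"):
                    if key in entry and not Path(entry[key]).exists():
                        raise ConfigError(f"manifest file does not exist: {entry[key]}")
                present.setdefault(entry["dyad_id"], set()).add(entry["condition"])
            for dyad, conds in present.items():
                missing = set(self.conditions) - conds
                if missing:
                    raise ConfigError(f"dyad {dyad!r} missing condition(s) {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "band" in kwargs and isinstance(kwargs["band"], dict):
            kwargs["band"] = BandSpec(**kwargs["band"])
        if "grid" in kwargs and isinstance(kwargs["grid"], dict):
            kwargs["grid"] = PairGrid(**kwargs["grid"])
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        if "target_pair" in kwargs:
            kwargs["target_pair"] = tuple(kwargs["target_pair"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        """Stable hash of the configuration for provenance logging."""
        blob = json.dumps(_jsonify(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def scenario_config(
    name: str,
    n_dyads: int = 10,
    seed: int = 0,
    conditions: tuple[str, str] = ("blank", "BO"),
    **overrides: Any,
) -> synth.SimulationConfig:
    """Preset simulation configs for the named scenarios.

    * ``null`` — coupling identical across conditions (global null for
      the contrast, nonzero baseline coupling at C4->P8);
    * ``c4p8-contrast`` — coupling differs between conditions only at
      (adult C4, infant P8);
    * ``engagement`` — the contrast plus a shared per-dyad latent that
      shifts both coupling and the attention target, so neural and
      behavioral change scores correlate.
    """
    a, b = conditions
    if name == "null":
        coupling = {(c, "C4", "P8"): 0.3 for c in conditions}
        extra: dict[str, Any] = {}
    elif name == "c4p8-contrast":
        coupling = {(a, "C4", "P8"): 0.1, (b, "C4", "P8"): 0.7}
        extra = {}
    elif name == "engagement":
        coupling = {(a, "C4", "P8"): 0.15, (b, "C4", "P8"): 0.55}
        extra = {
            "engagement_sd": 1.0,
            "engagement_kappa_slope": 0.25,
            "engagement_attention_slope": 0.12,
            "behavior_targets": {a: {"attention": 0.78}, b: {"attention": 0.85}},
        }
    else:
        raise ConfigError(f"unknown scenario {name!r}")
    params: dict[str, Any] = dict(
        n_dyads=n_dyads,
        conditions=conditions,
        coupling_table=coupling,
        seed=seed,
        **extra,
    )
    params.update(overrides)
    return synth.SimulationConfig(**params)


# ---------------------------------------------------------------- stages

def _load_recording(path: str) -> Recording:
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return io.read_recording_edf(p)
    return io.read_recording_tsv(p)


def _acquire(config: RunConfig) -> dict[tuple[str, str], tuple[Recording, Recording]]:
    """(dyad_id, condition) -> (infant, adult) raw recordings."""
    out: dict[tuple[str, str], tuple[Recording, Recording]] = {}
    if config.scenario is not None:
        sim = scenario_config(
            config.scenario,
            n_dyads=config.n_dyads,
            seed=config.seed,
            conditions=config.conditions,
            **config.sim_overrides,
        )
        for d in range(sim.n_dyads):
            for cond in config.conditions:
                infant, adult = synth.simulate_dyad(sim, d, cond)
                if sim.jump_rate > 0 or sim.ocular_rate > 0:
                    infant = synth.inject_artifacts(infant, sim, sim.seed)
                    adult = synth.inject_artifacts(adult, sim, sim.seed)
                out[(infant.dyad_id, cond)] = (infant, adult)
    else:
        for entry in config.manifest:
            key = (entry["dyad_id"], entry["condition"])
            infant = _load_recording(entry["infant"])
            adult = _load_recording(entry["adult"])
            out[key] = (infant, adult)
    return out


def preprocess_dyads(config: RunConfig) -> dict[str, dict[str, MatchedDyadEpochs]]:
    """Run filtering, cleanup, epoching, rejection and matching.

    Returns dyad_id -> condition -> MatchedDyadEpochs for the dyads that
    survive the minimum-duration rule in both conditions.
    """
    raw = _acquire(config)
    dyads = sorted({d for d, _ in raw})
    ca, cb = config.conditions

    matched: dict[str, dict[str, MatchedDyadEpochs]] = {}
    for dyad in dyads:
        if (dyad, ca) not in raw or (dyad, cb) not in raw:
            raise ConfigError(f"dyad {dyad!r} missing one of the contrast conditions")
        recs = {cond: raw[(dyad, cond)] for cond in config.conditions}
        # filter (and optionally clean) each member in each condition
        filtered: dict[str, list[Recording]] = {}
        for cond, (infant, adult) in recs.items():
            members = []
            for rec in (infant, adult):
                # keep the band inside Nyquist for low-rate (test) recordings
                high = min(config.high, 0.45 * rec.sampling_rate)
                rec = preprocess.bandpass(rec, config.low, high)
                if config.ica_template == "ocular":
                    template = synth.ocular_pattern(rec.channels)
                    rec, _ = preprocess.remove_template_components(
                        rec, template, seed=config.seed
                    )
                members.append(rec)
            filtered[cond] = members
        # match durations across the two conditions, per member role
        for role_idx in (0, 1):
            ra, rb = preprocess.match_durations(
                filtered[ca][role_idx], filtered[cb][role_idx]
            )
            filtered[ca][role_idx], filtered[cb][role_idx] = ra, rb

        per_cond: dict[str, MatchedDyadEpochs] = {}
        for cond, (infant, adult) in filtered.items():
            eps = []
            for rec in (infant, adult):
                es = preprocess.epoch(rec)
                if config.reject:
                    es = preprocess.reject_epochs(es)
                eps.append(es)
            m = preprocess.match_epochs(eps[0], eps[1])
            m = preprocess.enforce_minimum(m, config.min_seconds, config.cap_seconds)
            per_cond[cond] = m
        if any(m.excluded for m in per_cond.values()):
            continue  # dyad excluded by the minimum-duration rule
        matched[dyad] = per_cond
    return matched


def connectivity_maps(
    config: RunConfig, matched: dict[str, dict[str, MatchedDyadEpochs]]
) -> list[interbrain.ConnectivityMap]:
    maps = []
    for dyad in sorted(matched):
        for cond, m in matched[dyad].items():
            cross = interbrain.epoch_cross_spectra(
                m, config.grid, config.band, min_epochs=config.min_epochs
            )
            maps.append(interbrain.wpli(cross, min_epochs=config.min_epochs))
    return maps


def run_contrast(config: RunConfig) -> dict[str, Any]:
    """Execute the full contrast pipeline and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        matched = preprocess_dyads(config)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[preprocess] {exc}") from exc
    if len(matched) < 3:
        raise RuntimeError(
            f"[preprocess] only {len(matched)} dyads survived preprocessing; need >= 3"
        )
    try:
        maps = connectivity_maps(config, matched)
        group = interbrain.group_connectivity(maps)
    except Exception as exc:
        raise RuntimeError(f"[interbrain] {exc}") from exc
    try:
        result = permstats.max_f_permutation(
            group,
            conditions=config.conditions,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.alpha,
        )
    except Exception as exc:
        raise RuntimeError(f"[permstats] {exc}") from exc

    conn_path = io.write_connectivity_tsv(maps, out_dir / "connectivity.tsv")
    stats_path = io.write_stats_json(result, out_dir / "stats.json")
    log = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": _jsonify(dataclasses.asdict(config)),
        "n_dyads_analyzed": len(matched),
        "per_dyad_epochs": {
            d: {c: m.n_matched for c, m in conds.items()} for d, conds in matched.items()
        },
        "significant_pairs": sorted(
            [list(p) for p in result.significant_pairs]
        ),
        "outputs": {"connectivity": str(conn_path), "stats": str(stats_path)},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"group": group, "result": result, "maps": maps, "log": log, "matched": matched}


def _behavior_for(
    config: RunConfig, dyad: str, dyad_index: int, cond: str
) -> tuple[behavior.EventLog, behavior.EventLog]:
    if config.scenario is not None:
        sim = scenario_config(
            config.scenario,
            n_dyads=config.n_dyads,
            seed=config.seed,
            conditions=config.conditions,
            **config.sim_overrides,
        )
        return synth.simulate_behavior(sim, cond, seed=config.seed, dyad_index=dyad_index)
    for entry in config.manifest:
        if entry["dyad_id"] == dyad and entry["condition"] == cond:
            if "gaze" not in entry or "affect" not in entry:
                raise ConfigError(f"manifest entry for {dyad!r}/{cond!r} lacks behavior logs")
            gaze = behavior.read_event_log(entry["gaze"], "gaze")
            affect = behavior.read_event_log(
                entry["affect"], "affect", session_duration=gaze.session_duration
            )
            return gaze, affect
    raise ConfigError(f"no manifest entry for {dyad!r}/{cond!r}")


def run_brain_behavior(config: RunConfig) -> dict[str, Any]:
    """Correlate neural and visual-attention change scores across dyads."""
    bundle = run_contrast(config)
    group = bundle["group"]
    ca, cb = config.conditions
    pair_idx = group.pairs.index(config.target_pair)
    ia, ib = group.condition_index(ca), group.condition_index(cb)

    neural = []
    attention = []
    dyad_ids = []
    for di, dyad in enumerate(group.dyads):
        wa = group.values[di, ia, pair_idx]
        wb = group.values[di, ib, pair_idx]
        # synthetic dyad ids encode the simulation index ("dyad007")
        dyad_index = int(dyad[4:]) if dyad.startswith("dyad") and dyad[4:].isdigit() else di
        logs_a = _behavior_for(config, dyad, dyad_index, ca)
        logs_b = _behavior_for(config, dyad, dyad_index, cb)
        va = behavior.visual_attention(*logs_a)
        vb = behavior.visual_attention(*logs_b)
        neural.append(permstats.change_score(wb, wa))
        attention.append(permstats.change_score(vb, va))
        dyad_ids.append(dyad)
    neural = np.asarray(neural)
    attention = np.asarray(attention)

    excluded = permstats.exclude_3sd(neural) | permstats.exclude_3sd(attention)
    keep = ~excluded
    if keep.sum() < 3:
        raise RuntimeError("[brain-behavior] fewer than 3 dyads after 3-SD exclusion")
    r, p = permstats.pearson(neural[keep], attention[keep])

    report = {
        "target_pair": list(config.target_pair),
        "contrast": [cb, ca],
        "n_before_exclusion": int(neural.size),
        "n_after_exclusion": int(keep.sum()),
        "excluded_dyads": [d for d, e in zip(dyad_ids, excluded) if e],
        "pearson_r": r,
        "p_value": p,
        "neural_change_scores": neural.tolist(),
        "attention_change_scores": attention.tolist(),
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "brain_behavior.json").write_text(json.dumps(report, indent=2))
    return report
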