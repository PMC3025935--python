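"""Run configuration schema, seed management and the pipeline driver.

A :class:`RunConfig` validates the whole simulate → extract → analyze
pipeline configuration; unknown keys are rejected and every output file
carries a short hash of the configuration that produced it.  A single
top-level seed drives all stochastic stages through documented
sub-seeding (``numpy.random.SeedSequence.spawn``, one child per subject).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from . import extract as ex
from . import io as pio
from . import model as md
from . import stats as st
from . import synth as sy
from .errors import ConfigError

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "config_hash",
    "default_run_config",
    "run_pipeline",
]

log = logging.getLogger("pulsedecomp")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentConfig(_Strict):
    name: Literal["arm_x1", "thoracic_x2", "abdominal_x3"]
    length_m: float
    youngs_modulus_pa: float
    wall_thickness_m: float
    diameter_m: float
    fluid_density: float = 1050.0
    compliance_exponent: float = 0.008
    response_kind: Literal["exponential", "linear"] = "exponential"
    linearization_pressure: float = 90.0

    def to_segment(self) -> md.ArterialSegment:
        return md.ArterialSegment(
            name=self.name,
            length=self.length_m,
            youngs_modulus=self.youngs_modulus_pa,
            wall_thickness=self.wall_thickness_m,
            diameter=self.diameter_m,
            fluid_density=self.fluid_density,
            compliance_exponent=self.compliance_exponent,
            response_kind=self.response_kind,
            linearization_pressure=self.linearization_pressure,
        )


class CoefficientsConfig(_Strict):
    r1: float = 0.10
    r2_at_ref: float = 0.17
    r2_slope: float = 0.002
    r2_ref_systole: float = 120.0
    r3: float = 0.40

    def to_coefficients(self) -> md.ReflectionCoefficients:
        return md.ReflectionCoefficients(
            r1=self.r1,
            r2_at_ref=self.r2_at_ref,
            r2_slope=self.r2_slope,
            r2_ref_systole=self.r2_ref_systole,
            r3=self.r3,
        )


class PressureStateConfig(_Strict):
    psyst: float = 120.0
    pdiast: float = 75.0

    def to_state(self) -> md.PressureState:
        return md.PressureState(psyst=self.psyst, pdiast=self.pdiast)


class ModelBlock(_Strict):
    segments: dict[str, SegmentConfig]
    coefficients: CoefficientsConfig = CoefficientsConfig()
    pressure_state: PressureStateConfig = PressureStateConfig()

    def to_tree(self) -> md.ArterialTree:
        try:
            return md.ArterialTree(
                arm=self.segments["arm"].to_segment(),
                thoracic=self.segments["thoracic"].to_segment(),
                abdominal=self.segments["abdominal"].to_segment(),
            )
        except KeyError as exc:
            raise ConfigError(f"model.segments missing key {exc}") from exc


class ComponentConfig(_Strict):
    delay_ms: float
    amplitude: float
    width_ms: float = 50.0
    skew: float = 0.3

    def to_component(self) -> sy.ComponentSpec:
        return sy.ComponentSpec(
            delay=self.delay_ms, amplitude=self.amplitude, width=self.width_ms, skew=self.skew
        )


class StageConfig(_Strict):
    lbnp_mmhg: Literal[0, -15, -30, -45, -60]
    duration_s: float
    diastole_shift_mmhg: float = 0.0
    hr_shift_bpm: float = 0.0

    def to_stage(self) -> sy.StageSpec:
        return sy.StageSpec(
            lbnp_mmhg=self.lbnp_mmhg,
            duration_s=self.duration_s,
            diastole_shift_mmhg=self.diastole_shift_mmhg,
            hr_shift_bpm=self.hr_shift_bpm,
        )


class SynthBlock(_Strict):
    stages: list[StageConfig]
    sample_rate: float = 512.0
    noise_sd: float = 0.02
    base_hr_bpm: float = 60.0
    components: list[ComponentConfig]
    model_linked: bool = True

    def to_session_spec(self, base_state: md.PressureState, seed: int) -> sy.SessionSpec:
        return sy.SessionSpec(
            stages=tuple(s.to_stage() for s in self.stages),
            sample_rate=self.sample_rate,
            noise_sd=self.noise_sd,
            seed=seed,
            base_state=base_state,
            base_hr_bpm=self.base_hr_bpm,
            components=tuple(c.to_component() for c in self.components),
        )


class ExtractBlock(_Strict):
    p2_window_ms: Tuple[float, float] = (70.0, 140.0)
    p3_window_ms: Tuple[float, float] = (180.0, 400.0)
    integrator_order: int = 4
    integrator_hz: float = 20.0
    baseline_hp_hz: float = 0.3
    primary_lp_hz: float = 8.0
    beat_lp_hz: float = 18.0
    refractory_ms: float = 300.0
    snr_threshold_db: float = 10.0
    snr_band_hz: Tuple[float, float] = (0.5, 15.0)

    def to_settings(self) -> ex.ExtractSettings:
        return ex.ExtractSettings(
            p2_window_ms=self.p2_window_ms,
            p3_window_ms=self.p3_window_ms,
            integrator_order=self.integrator_order,
            integrator_hz=self.integrator_hz,
            baseline_hp_hz=self.baseline_hp_hz,
            primary_lp_hz=self.primary_lp_hz,
            beat_lp_hz=self.beat_lp_hz,
            refractory_ms=self.refractory_ms,
            snr_threshold_db=self.snr_threshold_db,
            snr_band_hz=self.snr_band_hz,
        )


class StatsBlock(_Strict):
    alpha: float = 0.01
    anova_mode: Literal["joint", "pooled"] = "joint"
    greenhouse_geisser: bool = False
    stages_tested: Tuple[int, int] = (-15, -30)


class RunConfig(_Strict):
    model: ModelBlock
    synth: SynthBlock
    extract: ExtractBlock = ExtractBlock()
    stats: StatsBlock = StatsBlock()
    n_subjects: int = 1
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


def default_run_config(seed: int = 0, stage_duration_s: float = 60.0, n_subjects: int = 1) -> RunConfig:
    """The documented default configuration."""
    tree = md.default_tree()
    seg_cfg = {
        key: SegmentConfig(
            name=seg.name,
            length_m=seg.length,
            youngs_modulus_pa=seg.youngs_modulus,
            wall_thickness_m=seg.wall_thickness,
            diameter_m=seg.diameter,
            fluid_density=seg.fluid_density,
            compliance_exponent=seg.compliance_exponent,
            response_kind=seg.response_kind,
            linearization_pressure=seg.linearization_pressure,
        )
        for key, seg in (("arm", tree.arm), ("thoracic", tree.thoracic), ("abdominal", tree.abdominal))
    }
    session = sy.default_session_spec(seed=seed, stage_duration_s=stage_duration_s)
    stages = [
        StageConfig(
            lbnp_mmhg=s.lbnp_mmhg,
            duration_s=s.duration_s,
            diastole_shift_mmhg=s.diastole_shift_mmhg,
            hr_shift_bpm=s.hr_shift_bpm,
        )
        for s in session.stages
    ]
    comps = [
        ComponentConfig(delay_ms=c.delay, amplitude=c.amplitude, width_ms=c.width, skew=c.skew)
        for c in session.components
    ]
    return RunConfig(
        model=ModelBlock(segments=seg_cfg),
        synth=SynthBlock(stages=stages, components=comps),
        n_subjects=n_subjects,
        seed=seed,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration; raises
    :class:`ConfigError` naming the offending key on schema violations."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid configuration key(s): {keys}") from exc


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.model_dump_json(indent=2))
        fh.write("\n")


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonicalized configuration."""
    canonical = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _subject_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(cfg: RunConfig, outdir: str | Path, resume: bool = False) -> Path:
    """Run simulate → extract → analyze, writing artifacts under ``outdir``.

    Deterministic for a fixed configuration and seed.  With ``resume``,
    per-subject stages whose outputs already exist are skipped.
    Returns the artifact directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    dump_config(cfg, outdir / "config.json")

    tree = cfg.model.to_tree()
    coeffs = cfg.model.coefficients.to_coefficients()
    base_state = cfg.model.pressure_state.to_state()
    settings = cfg.extract.to_settings()
    model_link = (tree, coeffs) if cfg.synth.model_linked else None
    schedule = [s.to_stage() for s in cfg.synth.stages]

    per_subject = {}
    seeds = _subject_seeds(cfg.seed, cfg.n_subjects)
    for i, sub_seed in enumerate(seeds):
        sid = f"s{i:02d}"
        stream_path = outdir / f"stream_{sid}.csv"
        truth_path = outdir / f"truth_{sid}.csv"
        beats_path = outdir / f"beats_{sid}.csv"
        qc_path = outdir / f"qc_{sid}.json"

        if resume and stream_path.exists() and truth_path.exists():
            log.info("resume: reusing %s", stream_path)
            samples, _ = pio.read_stream(stream_path)
            truth = pio.read_table(truth_path)
        else:
            spec = cfg.synth.to_session_spec(base_state, sub_seed)
            samples, truth = sy.synthesize_session(spec, model_link=model_link)
            meta = {"seed": sub_seed, "stages": [s.model_dump() for s in cfg.synth.stages]}
            pio.write_stream(stream_path, samples, cfg.synth.sample_rate, meta, chash)
            pio.write_table(truth_path, truth, chash)

        if resume and beats_path.exists():
            log.info("resume: reusing %s", beats_path)
            beats = pio.read_table(beats_path)
        else:
            stream = ex.DerivativeStream(samples, cfg.synth.sample_rate)
            beats, report = ex.extract_session(stream, settings, truth=truth)
            pio.write_table(beats_path, beats, chash)
            pio.write_json(qc_path, report.as_dict(), chash)

        per_subject[sid] = st.stage_aggregate(
            beats, schedule, cfg.synth.sample_rate, subject_id=sid
        )

    table = st.build_stage_table(per_subject)
    pio.write_table(outdir / "stage_table.csv", table, chash)

    complete = table.loc[~table["missing"]]
    fits: dict = {}
    if complete["mean_t13"].notna().sum() >= 3 and complete["lbnp_mmhg"].nunique() > 1:
        fits["t13_vs_stage"] = st.fit_linear(
            complete["lbnp_mmhg"].to_numpy(), complete["mean_t13"].to_numpy()
        ).as_dict()
    pio.write_json(outdir / "fits.json", fits, chash)

    analysis: dict = {}
    if cfg.n_subjects >= 2:
        try:
            res = st.rm_anova(
                table,
                stages=list(cfg.stats.stages_tested),
                mode=cfg.stats.anova_mode,
                gg=cfg.stats.greenhouse_geisser,
            )
            analysis["anova_t13"] = res.as_dict()
        except Exception as exc:  # incomplete designs at tiny scale
            analysis["anova_t13"] = {"error": str(exc)}
        try:
            roc = st.roc_stage(table, cfg.stats.stages_tested[0], cfg.stats.stages_tested[1])
            analysis["roc_t13"] = roc.as_dict()
        except Exception as exc:
            analysis["roc_t13"] = {"error": str(exc)}
    pio.write_json(outdir / "analysis.json", analysis, chash)
    return outdir
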