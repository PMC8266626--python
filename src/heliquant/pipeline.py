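"""End-to-end orchestration: configuration, stage execution, fixtures.

A run is described by a single JSON document: a seed, an output directory and
an ordered list of stages (simulate -> detect -> link -> analysis stages).
Each stage reads from and writes to a shared context, so e.g. the foci found
by ``detect`` feed ``link``, whose trajectories feed ``stoich`` or ``events``.
Every output carries provenance (tool version, config hash, seed) and the run
report summarises per-stage record counts and fit results as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import detection, kinetics, photobleach, simulate, stoichiometry
from .photobleach import IntensityTrajectory, LabelingCalibration

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "generate_fixtures",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """Invalid run configuration (unknown stage, bad ordering, missing input)."""


class StageError(RuntimeError):
    """A stage failed during execution."""


# stage -> context keys it needs; "movie" can be satisfied by a simulate stage
_REQUIRES = {
    "simulate": set(),
    "detect": {"movie"},
    "link": {"foci_by_frame"},
    "coloc": {"foci_by_frame"},
    "kymo": {"movie"},
    "steps": {"trajectories"},
    "dol": {"step_fits"},
    "calibrate": set(),
    "stoich": {"trajectories", "calibration"},
    "stoich_mixture": {"copies"},
    "lifetime": {"trajectories"},
    "frap": {"trajectories"},
    "events": {"trajectories", "calibration"},
    "summarize": {"event_series"},
}
# what each stage adds to the context
_PROVIDES = {
    "simulate": {"movie", "trajectories", "truths"},
    "detect": {"foci_by_frame"},
    "link": {"trajectories"},
    "coloc": set(),
    "kymo": set(),
    "steps": {"step_fits"},
    "dol": set(),
    "calibrate": {"calibration"},
    "stoich": {"copies"},
    "stoich_mixture": set(),
    "lifetime": set(),
    "frap": set(),
    "events": {"event_series"},
    "summarize": set(),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[dict]
    seed: int = 0
    out_dir: str = "heliquant_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigError("at least one stage required")
        available: set[str] = set()
        for spec in self.stages:
            if "stage" not in spec:
                raise ConfigError(f"stage entry missing 'stage' key: {spec}")
            name = spec["stage"]
            if name not in _REQUIRES:
                raise ConfigError(f"unknown stage {name!r}")
            missing = _REQUIRES[name] - available
            # stages may declare inline inputs (e.g. calibration block) instead
            inline = {k for k in ("calibration", "trajectories_csv", "values_csv",
                                  "movie_prefix") if k in spec}
            if missing and not inline:
                raise ConfigError(
                    f"stage {name!r} requires {sorted(missing)} but no earlier "
                    f"stage provides them (valid order: detection before linking "
                    f"before kinetics)")
            available |= _PROVIDES[name]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(f"config is not valid JSON: {e}") from e
        return cls(**doc)

    def hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Stage implementations
# --------------------------------------------------------------------------

def _calibration_from(block: dict) -> LabelingCalibration:
    return LabelingCalibration(
        single_fluor_intensity_mean=block["mean"],
        single_fluor_intensity_sd=block.get("sd", 0.0),
        dol_lambda=block.get("dol_lambda", float("nan")),
        n_molecules=block.get("n", 0),
    )


def _load_trajectories_csv(path: str | Path) -> list[IntensityTrajectory]:
    """Long-format CSV: focus_id,time_s,intensity."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    out = []
    for fid, g in df.groupby("focus_id"):
        out.append(IntensityTrajectory(
            times=g["time_s"].to_numpy(),
            intensities=g["intensity"].to_numpy(),
            source_focus_id=int(fid),
        ))
    return out


def _write_trajectories_csv(trajs: list[IntensityTrajectory], path: Path,
                            header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("focus_id,time_s,intensity\n")
        for tr in trajs:
            fid = tr.source_focus_id if tr.source_focus_id is not None else -1
            for t, i in zip(tr.times, tr.intensities):
                fh.write(f"{fid},{t},{i}\n")


def _stage_simulate(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    cfg_dict = dict(params.get("config", {}))
    cfg_dict.setdefault("seed", seed)
    if "field_shape" in cfg_dict:
        cfg_dict["field_shape"] = tuple(cfg_dict["field_shape"])
    config = simulate.SimConfig(**cfg_dict)
    rng = np.random.default_rng(config.seed)
    truths = []
    telegraphs = {}
    for i, em in enumerate(params.get("emitters", [])):
        truth = simulate.draw_emitter(
            rng, config, emitter_id=i, x=em["x"], y=em["y"],
            n_hexamers=em.get("n_hexamers", 1),
            kinetics_class=em.get("kinetics_class", "stable"),
            bind_time=em.get("bind_time", 0.0),
            off_lifetime=em.get("off_lifetime", math.inf))
        truths.append(truth)
        if em.get("telegraph"):
            telegraphs[i] = simulate.TelegraphParams(**em["telegraph"])
    mode = params.get("mode", "movie")
    report: dict = {"n_emitters": len(truths), "mode": mode}
    if mode == "movie":
        movie, truths = simulate.simulate_movie(config, truths,
                                                telegraphs=telegraphs, rng=rng)
        ctx["movie"] = movie
        paths = simulate.write_movie(movie, out_dir / "movie")
        report["movie"] = str(paths["tiff"])
    else:
        trajs = []
        for truth in truths:
            tel = telegraphs.get(truth.emitter_id)
            tr, truth_out = simulate.simulate_trajectory(config, truth, telegraph=tel)
            trajs.append(tr)
            truths[truth.emitter_id] = truth_out
        ctx["trajectories"] = trajs
        _write_trajectories_csv(trajs, out_dir / "trajectories.csv", header)
        report["n_trajectories"] = len(trajs)
    ctx["truths"] = truths
    ctx["sim_config"] = config
    simulate.write_truths(truths, out_dir / "truth.json")
    return report


def _stage_detect(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    movie = ctx.get("movie")
    if movie is None and "movie_prefix" in params:
        movie = simulate.read_movie(params["movie_prefix"])
        if params.get("offset"):
            profile = np.ones(movie.shape)
            movie = detection.correct_movie(movie, params["offset"], profile)
    if movie is None:
        raise StageError("detect: no movie in context or config")
    fb = detection.detect_foci_movie(movie,
                                     min_snr=params.get("min_snr", 5.0),
                                     window=params.get("window", 7))
    ctx["foci_by_frame"] = fb
    all_foci = [f for lst in fb.values() for f in lst]
    table = detection.foci_to_table(all_foci)
    out = out_dir / "foci.csv"
    with open(out, "w") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)
    return {"n_foci": len(all_foci), "n_frames": len(fb), "table": str(out)}


def _stage_link(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    movie = ctx.get("movie")
    trajs = detection.link_trajectories(
        ctx["foci_by_frame"],
        max_step=params.get("max_step", 3.0),
        max_gap=params.get("max_gap", 1),
        times=movie.times if movie is not None else None)
    min_len = params.get("min_length", 1)
    trajs = [t for t in trajs if len(t) >= min_len]
    ctx["trajectories"] = trajs
    _write_trajectories_csv(trajs, out_dir / "trajectories.csv", header)
    return {"n_trajectories": len(trajs)}


def _stage_coloc(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    frame = params.get("frame", 0)
    foci_a = ctx["foci_by_frame"].get(frame, [])
    import pandas as pd

    dfb = pd.read_csv(params["b_csv"], comment="#")
    foci_b = [detection.Focus(frame_index=int(r.frame), x=r.x_px, y=r.y_px,
                              integrated_intensity=r.intensity)
              for r in dfb.itertuples()]
    movie = ctx.get("movie")
    fov = float(np.prod(movie.shape)) if movie is not None else params.get("fov_area")
    result = detection.colocalize(foci_a, foci_b,
                                  radius=params.get("radius", 2.0),
                                  fov_area=fov)
    rep = {
        "n_a": len(foci_a), "n_b": len(foci_b),
        "n_pairs": len(result.pairs),
        "fraction_colocalised": result.fraction_colocalised,
        "chance_C": result.chance.C if result.chance else None,
    }
    (out_dir / "colocalisation.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_kymo(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    line = (tuple(params["line"][0]), tuple(params["line"][1]))
    kymo = detection.make_kymograph(ctx["movie"], line,
                                    width=params.get("width", 3))
    import tifffile

    tifffile.imwrite(out_dir / "kymograph.tif",
                     np.clip(np.round(kymo.image), 0, 65535).astype(np.uint16),
                     photometric="minisblack")
    return {"rows": kymo.image.shape[0], "cols": kymo.image.shape[1]}


def _stage_steps(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    trajs = ctx.get("trajectories")
    if trajs is None and "trajectories_csv" in params:
        trajs = _load_trajectories_csv(params["trajectories_csv"])
        ctx["trajectories"] = trajs
    fits = []
    for tr in trajs:
        try:
            fits.append(photobleach.detect_steps(
                tr, min_segment=params.get("min_segment", 3)))
        except ValueError:
            continue
    ctx["step_fits"] = fits
    hist = photobleach.count_steps_per_molecule(fits)
    (out_dir / "steps.json").write_text(json.dumps(
        {"histogram": hist, "n_molecules": len(fits)}, indent=2))
    return {"n_molecules": len(fits), "histogram": hist}


def _stage_dol(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    hist = photobleach.count_steps_per_molecule(ctx["step_fits"])
    rep: dict = {"histogram": hist}
    rep["lambda_plain"] = photobleach.fit_poisson_dol(hist, zero_truncated=False)
    try:
        rep["lambda_zero_truncated"] = photobleach.fit_poisson_dol(
            hist, zero_truncated=True)
    except ValueError as e:
        rep["lambda_zero_truncated"] = None
        rep["zero_truncated_error"] = str(e)
    (out_dir / "dol.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_calibrate(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    if "calibration" in params:
        calib = _calibration_from(params["calibration"])
    else:
        if "values_csv" in params:
            values = np.loadtxt(params["values_csv"], skiprows=1, delimiter=",",
                                ndmin=1)
        else:
            values = photobleach.last_step_sizes(ctx["step_fits"])
        calib = photobleach.calibrate_single_fluorophore(
            values, dol_lambda=params.get("dol_lambda", float("nan")))
    ctx["calibration"] = calib
    rep = dataclasses.asdict(calib)
    (out_dir / "calibration.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_stoich(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    if "calibration" in params:
        ctx["calibration"] = _calibration_from(params["calibration"])
    if "trajectories_csv" in params:
        ctx["trajectories"] = _load_trajectories_csv(params["trajectories_csv"])
    estimates = [stoichiometry.estimate_stoichiometry(
        tr, ctx["calibration"],
        n_initial_frames=params.get("n_initial_frames", 3))
        for tr in ctx["trajectories"]]
    copies = np.array([e.copies for e in estimates])
    ctx["copies"] = copies
    out = out_dir / "copies.csv"
    with open(out, "w") as fh:
        fh.write(header)
        fh.write("focus_id,initial_intensity,copies\n")
        for e in estimates:
            fh.write(f"{e.focus_id},{e.initial_intensity},{e.copies}\n")
    return {"n_foci": len(estimates),
            "mean_copies": float(copies.mean()) if copies.size else None}


def _stage_stoich_mixture(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    fit = stoichiometry.fit_stoichiometry_mixture(
        ctx["copies"], k=params.get("k", 3), seed=seed,
        constrained=params.get("constrained", False),
        sd_mode=params.get("sd_mode", "free"))
    rep = {"k": fit.k, "means": fit.means.tolist(), "sds": fit.sds.tolist(),
           "weights": fit.weights.tolist(),
           "log_likelihood": fit.log_likelihood,
           "constrained": fit.constrained}
    (out_dir / "mixture.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_lifetime(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    if "trajectories_csv" in params:
        ctx["trajectories"] = _load_trajectories_csv(params["trajectories_csv"])
    fit = kinetics.ensemble_lifetime(ctx["trajectories"],
                                     fit_offset=params.get("fit_offset", False),
                                     n_boot=params.get("n_boot", 0), seed=seed)
    rep = {"amplitude": fit.amplitude, "lifetime_s": fit.lifetime,
           "lifetime_se_s": fit.lifetime_se,
           "n_trajectories": len(ctx["trajectories"])}
    if params.get("tau_bleach_s"):
        try:
            rep["bleach_corrected_lifetime_s"] = kinetics.bleach_corrected_lifetime(
                fit.lifetime, params["tau_bleach_s"])
        except ValueError as e:
            rep["bleach_corrected_lifetime_s"] = None
            rep["bleach_correction_error"] = str(e)
    (out_dir / "lifetime.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_frap(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    if "trajectories_csv" in params:
        ctx["trajectories"] = _load_trajectories_csv(params["trajectories_csv"])
    t, mean = kinetics.ensemble_mean_trajectory(ctx["trajectories"])
    fit = kinetics.fit_frap_recovery(t, mean,
                                     bleach_time=params.get("bleach_time", 0.0))
    rep = {"a": fit.a, "tau_b_s": fit.tau_b, "I0": fit.I0,
           "tau_exchange_s": fit.tau}
    (out_dir / "frap.json").write_text(json.dumps(rep, indent=2))
    return rep


def _stage_events(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    if "calibration" in params:
        ctx["calibration"] = _calibration_from(params["calibration"])
    if "trajectories_csv" in params:
        ctx["trajectories"] = _load_trajectories_csv(params["trajectories_csv"])
    series = [kinetics.detect_binding_events(
        tr, ctx["calibration"],
        threshold_molecules=params.get("threshold_molecules", 0.5),
        min_duration=params.get("min_duration", 1))
        for tr in ctx["trajectories"]]
    ctx["event_series"] = series
    out = out_dir / "events.csv"
    with open(out, "w") as fh:
        fh.write(header)
        fh.write("trajectory,t_start_s,t_end_s\n")
        for i, s in enumerate(series):
            for a, b in s.events:
                fh.write(f"{i},{a},{b}\n")
    return {"n_trajectories": len(series),
            "n_events": sum(len(s.events) for s in series)}


def _stage_summarize(ctx, params, out_dir: Path, seed: int, header: str) -> dict:
    summary = kinetics.summarize_binding(ctx["event_series"],
                                         group=params.get("group"))
    rep = dataclasses.asdict(summary)
    (out_dir / "binding_summary.json").write_text(json.dumps(rep, indent=2))
    return rep


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "link": _stage_link,
    "coloc": _stage_coloc,
    "kymo": _stage_kymo,
    "steps": _stage_steps,
    "dol": _stage_dol,
    "calibrate": _stage_calibrate,
    "stoich": _stage_stoich,
    "stoich_mixture": _stage_stoich_mixture,
    "lifetime": _stage_lifetime,
    "frap": _stage_frap,
    "events": _stage_events,
    "summarize": _stage_summarize,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run report.

    Any stage failure raises :class:`StageError` naming the failing stage.
    The report is also written to ``<out_dir>/run_report.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (f"# heliquant {__version__} config={config.hash()} "
              f"seed={config.seed}\n")
    ctx: dict = {}
    report = {
        "tool": "heliquant",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    for spec in config.stages:
        name = spec["stage"]
        params = {k: v for k, v in spec.items() if k != "stage"}
        logger.info("stage %s", name)
        try:
            stage_report = _STAGE_FNS[name](ctx, params, out_dir, config.seed, header)
        except (ConfigError, StageError):
            raise
        except Exception as e:
            raise StageError(f"stage {name!r} failed: {e}") from e
        report["stages"].append({"stage": name, **stage_report})
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report


# --------------------------------------------------------------------------
# Named fixture scenarios
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("loading", "chase", "frap", "association")


def _loading_fixture(seed: int, out_dir: Path, n_foci: int = 606) -> dict:
    """Helicase-loading stoichiometry scenario: 1/2/3-hexamer populations with
    decreasing occupancy, SNR ~10 trajectories.

    Foci whose hexamers carry zero dyes in total are invisible in a real
    experiment and are excluded, so the written sample is detection-
    conditioned.  The calibration lambda recorded in the manifest is the mean
    dye count per hexamer actually realised by the (site-capped) labelling
    statistics — what a photobleaching-step DOL measurement calibrates.
    """
    config = simulate.SimConfig(
        seed=seed, frame_interval=8.0, exposure=0.4, n_frames=40,
        read_noise_sd=70.0, photons_per_dye_per_frame=200.0,
        dol_lambda=3.5, bleach_tau=1e9)
    rng = np.random.default_rng(seed)
    weights = (0.55, 0.30, 0.15)
    trajs, truths = [], []
    i = 0
    while len(trajs) < n_foci:
        nh = int(rng.choice([1, 2, 3], p=weights))
        truth = simulate.draw_emitter(rng, config, emitter_id=i, x=10.0, y=10.0,
                                      n_hexamers=nh)
        i += 1
        if truth.total_dyes == 0:
            continue   # undetectable focus
        tr, truth = simulate.simulate_trajectory(
            config, truth, rng=np.random.default_rng([seed, i]))
        trajs.append(tr)
        truths.append(truth)
    _write_trajectories_csv(trajs, out_dir / "trajectories.csv",
                            f"# heliquant loading fixture seed={seed}\n")
    simulate.write_truths(truths, out_dir / "truth.json")
    manifest = {
        "scenario": "loading",
        "seed": seed,
        "n_foci": n_foci,
        "populations": [1, 2, 3],
        "weights": list(weights),
        "dol_lambda": config.dol_lambda,
        "calibration_lambda": simulate.truncated_poisson_mean(
            config.dol_lambda, config.max_dyes),
        "single_fluor_intensity": config.photons_per_dye_per_frame,
        "expected": "3-component mixture of copies with means near 1, 2, 3 "
                    "and decreasing weights (constrained sd_mode='scaled' fit)",
    }
    return manifest


def _chase_fixture(seed: int, out_dir: Path, n_traj: int = 60) -> dict:
    """Chase scenario: stable anchored helicase whose signal loss is
    bleach-limited (4.8 min) versus an exchanging variant, plus the
    bleach-only control."""
    # 400 ms / 800 ms duty -> wall-clock bleach tau = 2 * exposure-clock tau
    base = dict(frame_interval=0.8, exposure=0.4, n_frames=1500,
                read_noise_sd=60.0, photons_per_dye_per_frame=200.0,
                dol_lambda=3.5, bleach_tau=4.8 * 60 * 0.5)
    groups = {
        "bleach_control": (math.inf, 0),
        "chase_stable": (math.inf, 1),
        "chase_exchange": (1.0 / 0.25 * 60.0, 2),  # 0.25 events/min off-rate
    }
    manifest: dict = {"scenario": "chase", "seed": seed, "groups": {},
                      "bleach_lifetime_min": 4.8}
    for name, (off_lifetime, salt) in groups.items():
        config = simulate.SimConfig(seed=seed + salt, **base)
        rng = np.random.default_rng([seed, salt])
        trajs, truths = [], []
        for i in range(n_traj):
            truth = simulate.draw_emitter(rng, config, emitter_id=i,
                                          x=10.0, y=10.0,
                                          off_lifetime=off_lifetime)
            tr, truth = simulate.simulate_trajectory(config, truth,
                                                     rng=np.random.default_rng([seed, salt, i]))
            trajs.append(tr)
            truths.append(truth)
        _write_trajectories_csv(trajs, out_dir / f"{name}.csv",
                                f"# heliquant chase fixture {name} seed={seed}\n")
        simulate.write_truths(truths, out_dir / f"{name}_truth.json")
        manifest["groups"][name] = {
            "n": n_traj,
            "off_lifetime_s": None if math.isinf(off_lifetime) else off_lifetime,
        }
    manifest["expected"] = ("chase_stable lifetime indistinguishable from "
                            "bleach_control; chase_exchange significantly shorter")
    return manifest


def _frap_fixture(seed: int, out_dir: Path, n_curves: int = 100) -> dict:
    """FRAP curves from the recovery-with-photobleaching model plus noise."""
    # sampled over ~2x the slowest time constant so tau_b is identifiable
    true = {"a": 2.0, "tau_b": 300.0, "I0": 1.0, "tau": 120.0}
    t = np.arange(0.0, 600.0, 2.0)
    rng = np.random.default_rng(seed)
    with open(out_dir / "frap_curves.csv", "w") as fh:
        fh.write(f"# heliquant frap fixture seed={seed}\n")
        fh.write("focus_id,time_s,intensity\n")
        for c in range(n_curves):
            y = kinetics.frap_model(t, **true) + rng.normal(0, 0.1 * true["I0"], t.size)
            for tt, yy in zip(t, y):
                fh.write(f"{c},{tt},{yy}\n")
    return {"scenario": "frap", "seed": seed, "n_curves": n_curves,
            "true_params": true, "noise_sd": 0.1 * true["I0"],
            "expected": "fitted parameters within 10% of true_params on average"}


def _association_fixture(seed: int, out_dir: Path,
                         n_fast: int = 123, n_slow: int = 74) -> dict:
    """Transient-association scenario: two telegraph binding-rate groups
    matching the replisome (0.84 / min) and helicase-only (0.13 / min)
    regimes."""
    config = simulate.SimConfig(
        seed=seed, frame_interval=1.0, exposure=0.5, n_frames=600,
        read_noise_sd=3.5 * 200.0 / 8.0,   # SNR 8 on a one-molecule signal
        photons_per_dye_per_frame=200.0, dol_lambda=3.5, bleach_tau=1e9)
    groups = {"replisome": (0.84, n_fast, 11), "helicase_only": (0.13, n_slow, 12)}
    manifest: dict = {"scenario": "association", "seed": seed,
                      "dol_lambda": config.dol_lambda,
                      "single_fluor_intensity": config.photons_per_dye_per_frame,
                      "mean_dwell_s": 8.0, "groups": {}}
    for name, (rate, n, salt) in groups.items():
        tel = simulate.TelegraphParams(on_rate=rate, mean_dwell=8.0)
        trajs, truths = [], []
        for i in range(n):
            truth = simulate.EmitterTruth(
                emitter_id=i, x=10.0, y=10.0, n_hexamers=1,
                dye_counts=[max(1, int(round(config.dol_lambda)))],
                kinetics_class="transient-telegraph")
            tr, truth = simulate.simulate_trajectory(
                config, truth, telegraph=tel,
                rng=np.random.default_rng([seed, salt, i]))
            trajs.append(tr)
            truths.append(truth)
        _write_trajectories_csv(trajs, out_dir / f"{name}.csv",
                                f"# heliquant association fixture {name} seed={seed}\n")
        simulate.write_truths(truths, out_dir / f"{name}_truth.json")
        true_rate = float(np.mean([
            sum(1 for _ in t.bound_intervals) for t in truths
        ]) / (config.duration / 60.0))
        manifest["groups"][name] = {"on_rate_per_min": rate, "n": n,
                                    "true_event_rate_per_min": true_rate}
    manifest["expected"] = ("detected binding frequencies within 15% of "
                            "true_event_rate_per_min; group 95% CIs disjoint")
    return manifest


_FIXTURE_FNS = {
    "loading": _loading_fixture,
    "chase": _chase_fixture,
    "frap": _frap_fixture,
    "association": _association_fixture,
}


def generate_fixtures(name: str, seed: int, out_dir: str | Path,
                      **kwargs) -> Path:
    """Write a self-contained scenario directory (trajectories + ground truth
    + expected-property manifest) for one of the named assay scenarios.

    Raises
    ------
    ConfigError
        For an unknown scenario name.
    """
    if name not in _FIXTURE_FNS:
        raise ConfigError(
            f"unknown scenario {name!r}; choose from {FIXTURE_NAMES}")
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    manifest = _FIXTURE_FNS[name](seed, out, **kwargs)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
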