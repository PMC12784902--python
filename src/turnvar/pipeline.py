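"""End-to-end pipeline: simulate/score -> summarize -> test -> report.

One entry point, ``run_pipeline``, drives the whole analysis from any of
three input modes:

* ``simulate``   — draw a synthetic cohort (Beta-Bernoulli hierarchy);
* ``events``     — read an already-scored turn-event CSV;
* ``trajectories`` — read centroid tracks and score them into events.

Whatever the source, the analysis stage sees only the events table plus
parameters, so scored and simulated inputs are interchangeable.  Every
table, seed and parameter is echoed into a JSON run manifest from which the
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .inference import anova_bias, kruskal_activity, pairwise_activity_tests
from .io import read_events, read_trajectories, write_events
from .scoring import CONVENTIONS, MazeGeometry, score_turns
from .stats import group_variability, pairwise_mad_tests, summarize_flies
from .synthetic import SyntheticConfig, config_from_file, study_default_config

log = logging.getLogger("turnvar")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "run_from_manifest"]

_TABLES = (
    "fly_summaries",
    "excluded_flies",
    "group_variability",
    "permutation_tests",
    "omnibus_tests",
    "pairwise_tests",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    mode: str = "simulate"  # simulate | events | trajectories
    events_path: str | None = None
    trajectories_path: str | None = None
    geometry: MazeGeometry = field(default_factory=MazeGeometry)
    synthetic: SyntheticConfig | str | None = None  # config object or YAML path
    observation_minutes: float = 120.0
    min_turns: int = 10
    n_iter: int = 10_000
    n_boot: int = 10_000
    alpha: float = 0.05
    alternative: str = "two_sided"
    convention: str = "cw-right"
    seed: int = 0
    out_dir: str | None = None
    figures: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "events", "trajectories"):
            raise ValueError(f"mode: must be simulate|events|trajectories, got {self.mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha: must lie in (0, 1), got {self.alpha}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention: must be one of {CONVENTIONS}")
        if self.n_iter < 1 or self.n_boot < 100:
            raise ValueError("n_iter must be >= 1 and n_boot >= 100")
        if self.n_iter < 1000:
            warnings.warn(
                f"n_iter={self.n_iter} is below 1000; permutation p-values will be coarse",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class ReportBundle:
    """All analysis outputs of one run."""

    fly_summaries: pd.DataFrame
    excluded_flies: pd.DataFrame
    group_variability: pd.DataFrame
    permutation_tests: pd.DataFrame
    omnibus_tests: pd.DataFrame
    pairwise_tests: pd.DataFrame
    events: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _get_events(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Resolve the input mode into (events, roster-or-None, provenance)."""
    prov: dict = {"mode": config.mode}
    if config.mode == "simulate":
        syn = config.synthetic
        if isinstance(syn, (str, Path)):
            prov["synthetic_config_path"] = str(syn)
            syn = config_from_file(syn)
        elif syn is None:
            syn = study_default_config(seed=config.seed)
        prov["synthetic_config"] = {
            "groups": [asdict(g) for g in syn.groups],
            "session_minutes": syn.session_minutes,
            "seed": syn.seed,
        }
        from .synthetic import simulate_cohort

        events, roster = simulate_cohort(syn)
        return events, roster, prov
    if config.mode == "events":
        if not config.events_path:
            raise ValueError("events mode requires events_path")
        prov["events_path"] = str(config.events_path)
        prov["events_sha256"] = _sha256(Path(config.events_path))
        return read_events(config.events_path), None, prov
    # trajectories mode
    if not config.trajectories_path:
        raise ValueError("trajectories mode requires trajectories_path")
    prov["trajectories_path"] = str(config.trajectories_path)
    prov["trajectories_sha256"] = _sha256(Path(config.trajectories_path))
    tracks = read_trajectories(config.trajectories_path)
    frames = []
    qc_rows = []
    for fly, track in tracks.groupby("fly_id", sort=True):
        ev, qc = score_turns(
            track.sort_values("time_s"), config.geometry, convention=config.convention
        )
        qc_rows.append({"fly_id": fly, **qc})
        if len(ev):
            ev = ev.copy()
            ev.insert(0, "fly_id", fly)
            # treatment is encoded as the fly_id prefix "<label>_<number>"
            ev.insert(1, "treatment", str(fly).rsplit("_", 1)[0])
            frames.append(ev[["fly_id", "treatment", "time_s", "direction", "arm_from", "arm_to"]])
    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["fly_id", "treatment", "time_s", "direction", "arm_from", "arm_to"])
    )
    prov["scoring_qc"] = qc_rows
    return events, None, prov


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full simulate/score -> analyze -> report chain."""
    events, roster, prov = _get_events(config)

    summaries, excluded = summarize_flies(
        events,
        observation_minutes=config.observation_minutes,
        min_turns=config.min_turns,
        roster=roster,
    )
    if len(summaries) == 0:
        raise ValueError("no flies passed the inclusion threshold; nothing to analyze")

    gv = group_variability(summaries, n_boot=config.n_boot, seed=config.seed)
    perms = pairwise_mad_tests(
        summaries, n_iter=config.n_iter, alternative=config.alternative, seed=config.seed
    )

    n_groups = summaries["treatment"].nunique()
    omni_rows = []
    if n_groups >= 2:
        an = anova_bias(summaries)
        omni_rows.append(
            {"test": an.test, "statistic": an.statistic, "df1": an.df1, "df2": an.df2,
             "p_value": an.p_value, **an.diagnostics}
        )
        kw = kruskal_activity(
            {k: g["turns_per_min"].to_numpy() for k, g in summaries.groupby("treatment")}
        )
        omni_rows.append(
            {"test": kw.test, "statistic": kw.statistic, "df1": kw.df1, "df2": kw.df2,
             "p_value": kw.p_value}
        )
        pairwise = pairwise_activity_tests(summaries)
    else:
        pairwise = pd.DataFrame()
    omnibus = pd.DataFrame(omni_rows)

    manifest = {
        "version": __version__,
        "provenance": prov,
        "params": {
            "observation_minutes": config.observation_minutes,
            "min_turns": config.min_turns,
            "n_iter": config.n_iter,
            "n_boot": config.n_boot,
            "alpha": config.alpha,
            "alternative": config.alternative,
            "convention": config.convention,
            "seed": config.seed,
            "geometry": asdict(config.geometry),
        },
        "n_flies_analyzed": int(len(summaries)),
        "n_flies_excluded": int(len(excluded)),
    }

    bundle = ReportBundle(
        fly_summaries=summaries,
        excluded_flies=excluded,
        group_variability=gv,
        permutation_tests=perms,
        omnibus_tests=omnibus,
        pairwise_tests=pairwise,
        events=events,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_report(bundle, config.out_dir, figures=config.figures, alpha=config.alpha)
    return bundle


def write_report(bundle: ReportBundle, out_dir, figures: bool = True, alpha: float = 0.05) -> None:
    """Write all tables, the manifest, and (optionally) the figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(bundle, name).to_csv(out / f"{name}.csv", index=False)
    write_events(bundle.events, out / "events.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)

    if figures:
        from .plots import mad_barplot, strip_plot

        mad_barplot(bundle.group_variability, out / "fig_mad.png", alpha=alpha)
        mad_pairs = bundle.permutation_tests.rename(columns={"p_adjusted": "p_adjusted"})
        strip_plot(
            bundle.fly_summaries, "prop_right", out / "fig_prop_right.png",
            pairwise=mad_pairs if len(mad_pairs) else None, alpha=alpha,
            ylabel="proportion of right turns",
        )
        strip_plot(
            bundle.fly_summaries, "turns_per_min", out / "fig_turns_per_min.png",
            pairwise=bundle.pairwise_tests if len(bundle.pairwise_tests) else None,
            alpha=alpha, ylabel="turns per minute",
        )


def run_from_manifest(manifest_path, out_dir=None) -> ReportBundle:
    """Re-run a pipeline from its JSON manifest alone.

    The manifest's provenance and parameter blocks fully determine the run;
    for simulate mode the synthetic config (including seed) is embedded, for
    file modes the recorded paths are re-read and their hashes re-checked.
    """
    with open(manifest_path) as fh:
        man = json.load(fh)
    prov = man["provenance"]
    params = man["params"]
    geometry = MazeGeometry(
        center_xy=tuple(params["geometry"]["center_xy"]),
        arm_angles_deg=tuple(params["geometry"]["arm_angles_deg"]),
        arm_length_mm=params["geometry"]["arm_length_mm"],
        center_radius_mm=params["geometry"]["center_radius_mm"],
        commit_radius_mm=params["geometry"]["commit_radius_mm"],
        extent_tol_mm=params["geometry"]["extent_tol_mm"],
    )
    synthetic = None
    if prov["mode"] == "simulate":
        from .synthetic import GroupSpec

        sc = prov["synthetic_config"]
        synthetic = SyntheticConfig(
            groups=tuple(GroupSpec(**g) for g in sc["groups"]),
            session_minutes=sc["session_minutes"],
            seed=sc["seed"],
        )
    config = RunConfig(
        mode=prov["mode"],
        events_path=prov.get("events_path"),
        trajectories_path=prov.get("trajectories_path"),
        geometry=geometry,
        synthetic=synthetic,
        observation_minutes=params["observation_minutes"],
        min_turns=params["min_turns"],
        n_iter=params["n_iter"],
        n_boot=params["n_boot"],
        alpha=params["alpha"],
        alternative=params["alternative"],
        convention=params["convention"],
        seed=params["seed"],
        out_dir=str(out_dir) if out_dir is not None else None,
        figures=False,
    )
    for key in ("events_path", "trajectories_path"):
        if prov.get(key):
            recorded = prov.get(key.replace("_path", "_sha256"))
            if recorded and _sha256(Path(prov[key])) != recorded:
                raise ValueError(f"{prov[key]}: content hash differs from the manifest")
    return run_pipeline(config)
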