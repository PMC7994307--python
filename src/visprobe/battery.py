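"""Configuration, orchestration, and reporting for the 12-experiment battery.

:func:`run_battery` generates the stimulus set of every requested
experiment (seeded), extracts activations with the configured extractor,
computes the experiment's per-layer result, and collects everything into a
tidy results table plus one presence verdict per experiment.  The verdict
follows the last-fully-connected-layer rule: a property counts as *present*
when the experiment's signed presence quantity at the last fc layer is
positive and its magnitude exceeds its s.e.m. (where an s.e.m. exists);
*undefined* when that layer is flagged.  Experiments whose primary result
is not a contrast index use a documented signed quantity instead (see
``_PRESENCE_RULES``).

Outputs are deterministic under a fixed config; a hash of the canonical
config JSON is recorded in every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import indices, stimuli
from .features import (ActivationTable, extract, pixel_extractor,
                       reference_convnet, surrogate_extractor)
from .metrics import IndexProfile

__all__ = [
    "EXPERIMENTS",
    "BatteryConfig",
    "BatteryReport",
    "run_battery",
    "presence_verdict",
    "render_report",
    "load_reference_constants",
    "cli",
]

log = logging.getLogger("visprobe")

EXPERIMENTS = (
    "thatcher", "mirror", "scenes", "normalization", "sparseness", "weber",
    "relative_size", "surface_invariance", "depth3d", "occlusion", "parts",
    "global_local",
)


@dataclass
class BatteryConfig:
    """Everything needed to reproduce a battery run."""

    extractor: str = "refnet"        # pixel | refnet | surrogate:<kind>
    experiments: tuple = EXPERIMENTS
    metric: str = "euclidean"
    image_size: int = 64
    seed: int = 0
    refnet_width: float = 1.0
    refnet_input_size: int = 64
    top_fraction_size: float = 0.07
    top_fraction_surface: float = 0.09
    n_faces: int = 20
    n_mirror_objects: int = 100
    n_scene_objects: int = 40
    n_multi_objects: int = 49
    n_pairs: int = 200
    n_triplets: int = 200
    n_size_tetrads: int = 24
    n_patterns: int = 6
    n_surfaces: int = 4
    output_dir: str = "battery_out"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.experiments) - set(EXPERIMENTS)
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")
        if not (0 < self.top_fraction_size <= 1
                and 0 < self.top_fraction_surface <= 1):
            raise ValueError("top fractions must be in (0, 1]")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BatteryReport:
    """Tidy per-layer results, presence verdicts, and provenance."""

    results: pd.DataFrame
    verdicts: dict
    provenance: dict

    def to_summary(self) -> dict:
        return {
            "provenance": self.provenance,
            "verdicts": self.verdicts,
            "results": self.results.to_dict(orient="records"),
        }

    @classmethod
    def from_summary(cls, summary: dict) -> "BatteryReport":
        return cls(pd.DataFrame(summary["results"]), summary["verdicts"],
                   summary["provenance"])


# ---------------------------------------------------------------------------
# extractor / stimulus construction


def _build_extractor(config: BatteryConfig):
    spec = config.extractor
    if spec == "pixel":
        return pixel_extractor()
    if spec == "refnet":
        return reference_convnet(config.seed, config.refnet_width,
                                 config.refnet_input_size)
    if spec.startswith("surrogate:"):
        return surrogate_extractor(spec.split(":", 1)[1],
                                   {"seed": config.seed, **config.extras})
    if ":" in spec:  # adapter: "module:callable"
        import importlib

        mod, attr = spec.split(":", 1)
        factory = getattr(importlib.import_module(mod), attr)
        return factory()
    raise ValueError(f"unknown extractor spec {spec!r}")


def _exp_seed(config: BatteryConfig, exp: str) -> int:
    return int(np.random.SeedSequence(
        [config.seed, EXPERIMENTS.index(exp)]).generate_state(1)[0] % (2 ** 31))


def build_stimuli(exp: str, config: BatteryConfig) -> stimuli.StimulusSet:
    s, size = _exp_seed(config, exp), config.image_size
    if exp == "thatcher":
        return stimuli.make_thatcher_set(config.n_faces, s, size)
    if exp == "mirror":
        return stimuli.make_mirror_set(config.n_mirror_objects, s, size)
    if exp == "scenes":
        return stimuli.make_scenes(config.n_scene_objects, s, size)
    if exp == "normalization":
        return stimuli.make_multiobject_displays(
            config.n_multi_objects, config.n_pairs, config.n_triplets, s, size)
    if exp == "sparseness":
        return stimuli.make_shape_sets(s, size)
    if exp == "weber":
        return stimuli.make_length_bars(None, s, size)
    if exp == "relative_size":
        return stimuli.make_size_tetrads(config.n_size_tetrads, s, size)
    if exp == "surface_invariance":
        return stimuli.make_surface_tetrads(config.n_patterns,
                                            config.n_surfaces, s, size)
    if exp == "depth3d":
        return stimuli.make_3d_pairs(s, size)
    if exp == "occlusion":
        return stimuli.make_occlusion_displays(s, size)
    if exp == "parts":
        return stimuli.make_part_objects(s, size)
    if exp == "global_local":
        return stimuli.make_hierarchical_stimuli(s, size)
    raise ValueError(exp)


# ---------------------------------------------------------------------------
# presence verdicts


def presence_verdict(profile: IndexProfile) -> str:
    """present | absent | undefined at the last fully connected layer."""
    fc = [k for k, s in enumerate(profile.layers) if s.kind == "fc"]
    if not fc:
        raise ValueError("profile has no fc layer")
    k = fc[-1]
    if not profile.defined(k):
        return "undefined"
    mean, sem = float(profile.mean[k]), float(profile.sem[k])
    return "present" if (mean > 0 and abs(mean) > sem) else "absent"


def _last_fc(layers) -> int:
    """Last fc layer; extractors without one (e.g. pixel) use the final
    layer as their read-out stage."""
    fc = [k for k, s in enumerate(layers) if s.kind == "fc"]
    return fc[-1] if fc else len(layers) - 1


def _profile_verdict(profile: IndexProfile) -> str:
    k = _last_fc(profile.layers)
    if not profile.defined(k):
        return "undefined"
    mean, sem = float(profile.mean[k]), float(profile.sem[k])
    return "present" if (mean > 0 and abs(mean) > sem) else "absent"


def _verdict_from_quantity(value: float, sem: float = 0.0) -> str:
    if not np.isfinite(value):
        return "undefined"
    return "present" if (value > 0 and abs(value) > sem) else "absent"


#: Signed presence quantities for experiments whose result is not a plain
#: contrast index.  Positive = property present at the last fc layer.
_PRESENCE_RULES = {
    "normalization": "0.1 − max(|slope_pairs − 1/2|, |slope_triplets − 1/3|)",
    "sparseness": "reference-vs-morph sparseness correlation",
    "weber": "r_rel − r_abs",
    "depth3d": "min over the two control conditions of the 3D index",
    "occlusion": "min over the two effects of the occlusion index",
    "parts": "part-break index (advantage reported alongside)",
}


# ---------------------------------------------------------------------------
# per-experiment runners


def _rows_from_profile(profile: IndexProfile, exp: str, measure: str) -> list[dict]:
    rows = profile.to_records(exp)
    for r in rows:
        r["measure"] = measure
    return rows


def _run_experiment(exp: str, stims: stimuli.StimulusSet,
                    table: ActivationTable,
                    config: BatteryConfig) -> tuple[list[dict], str]:
    metric = config.metric
    if exp == "thatcher":
        p = indices.thatcher_index(stims, table, metric)
        return _rows_from_profile(p, exp, "thatcher_index"), _profile_verdict(p)
    if exp == "mirror":
        p = indices.mirror_confusion_index(stims, table, metric)
        return _rows_from_profile(p, exp, "mirror_confusion_index"), \
            _profile_verdict(p)
    if exp == "scenes":
        p = indices.scene_incongruence_distance(stims, table, metric)
        return _rows_from_profile(p, exp, "incongruence_index"), \
            _profile_verdict(p)
    if exp == "normalization":
        sp = indices.normalization_slopes(stims, table)
        rows = []
        for k, spec in enumerate(sp.layers):
            for measure, val, npts in (
                    ("slope_pairs", sp.slope_pairs[k], sp.n_points_pairs[k]),
                    ("slope_triplets", sp.slope_triplets[k],
                     sp.n_points_triplets[k])):
                rows.append({"experiment": exp, "layer_index": spec.index,
                             "layer_name": spec.name, "layer_kind": spec.kind,
                             "measure": measure, "mean": float(val),
                             "sem": 0.0, "n": int(npts), "excluded": 0})
        k = _last_fc(sp.layers)
        if not sp.defined(k):
            return rows, "undefined"
        q = 0.1 - max(abs(sp.slope_pairs[k] - 0.5),
                      abs(sp.slope_triplets[k] - 1.0 / 3.0))
        return rows, _verdict_from_quantity(q)
    if exp == "sparseness":
        sp = indices.correlated_sparseness(stims, table)
        rows = []
        for k, spec in enumerate(sp.layers):
            for measure, val, n in (
                    ("r_reference_morph", sp.r_reference_morph[k],
                     sp.n_units_reference_morph[k]),
                    ("r_texture_shape", sp.r_texture_shape[k],
                     sp.n_units_texture_shape[k])):
                rows.append({"experiment": exp, "layer_index": spec.index,
                             "layer_name": spec.name, "layer_kind": spec.kind,
                             "measure": measure, "mean": float(val),
                             "sem": 0.0, "n": int(n), "excluded": 0})
        k = _last_fc(sp.layers)
        return rows, _verdict_from_quantity(sp.r_reference_morph[k])
    if exp == "weber":
        w = indices.weber_index(stims, table, metric)
        rows = []
        for k, spec in enumerate(w.layers):
            for measure, val in (("r_abs", w.r_abs[k]), ("r_rel", w.r_rel[k]),
                                 ("weber_difference", w.difference[k])):
                rows.append({"experiment": exp, "layer_index": spec.index,
                             "layer_name": spec.name, "layer_kind": spec.kind,
                             "measure": measure, "mean": float(val),
                             "sem": 0.0, "n": len(stims), "excluded": 0})
        return rows, _verdict_from_quantity(w.difference[_last_fc(w.layers)])
    if exp == "relative_size":
        p = indices.relative_size_index(stims, table, config.top_fraction_size)
        return _rows_from_profile(p, exp, "relative_size_index"), \
            _profile_verdict(p)
    if exp == "surface_invariance":
        p = indices.surface_invariance_index(stims, table,
                                             config.top_fraction_surface)
        return _rows_from_profile(p, exp, "surface_invariance_index"), \
            _profile_verdict(p)
    if exp == "depth3d":
        profiles = indices.depth3d_index(stims, table, metric)
        rows = []
        for cond, p in profiles.items():
            rows += _rows_from_profile(p, exp, f"depth3d_index_{cond}")
        k = _last_fc(table.layers)
        vals = [p.mean[k] for p in profiles.values()]
        sems = [p.sem[k] for p in profiles.values()]
        if any(not np.isfinite(v) for v in vals):
            return rows, "undefined"
        j = int(np.argmin(vals))
        return rows, _verdict_from_quantity(vals[j], sems[j])
    if exp == "occlusion":
        profiles = indices.occlusion_index(stims, table, metric)
        rows = []
        for eff, p in profiles.items():
            rows += _rows_from_profile(p, exp, f"occlusion_index_{eff}")
        k = _last_fc(table.layers)
        vals = [p.mean[k] for p in profiles.values()]
        if any(not np.isfinite(v) for v in vals):
            return rows, "undefined"
        return rows, _verdict_from_quantity(min(vals))
    if exp == "parts":
        p = indices.part_break_index(stims, table, metric)
        rows = _rows_from_profile(p, exp, "part_break_index")
        adv = indices.natural_part_advantage(stims, table, metric)
        for k, spec in enumerate(adv.layers):
            for measure, val in (("r_natural", adv.r_natural[k]),
                                 ("r_unnatural", adv.r_unnatural[k]),
                                 ("natural_part_advantage", adv.advantage[k])):
                rows.append({"experiment": exp, "layer_index": spec.index,
                             "layer_name": spec.name, "layer_kind": spec.kind,
                             "measure": measure, "mean": float(val),
                             "sem": 0.0, "n": 21, "excluded": 0})
        return rows, _profile_verdict(p)
    if exp == "global_local":
        p = indices.global_advantage_index(stims, table, metric,
                                           seed=config.seed)
        return _rows_from_profile(p, exp, "global_advantage_index"), \
            _profile_verdict(p)
    raise ValueError(exp)


# ---------------------------------------------------------------------------
# orchestration


def run_battery(config: BatteryConfig) -> BatteryReport:
    """Run the requested experiments end to end for the configured extractor."""
    extractor = _build_extractor(config)
    all_rows, verdicts = [], {}
    for exp in config.experiments:
        log.info("experiment %s: generating stimuli", exp)
        stims = build_stimuli(exp, config)
        log.info("experiment %s: extracting %d stimuli", exp, len(stims))
        table = extract(extractor, stims)
        try:
            rows, verdict = _run_experiment(exp, stims, table, config)
        except Exception as err:
            raise RuntimeError(f"experiment {exp!r} failed: {err}") from err
        all_rows += rows
        verdicts[exp] = verdict
        log.info("experiment %s: verdict %s", exp, verdict)
    results = pd.DataFrame(all_rows)
    provenance = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": _version(),
        "presence_rules": _PRESENCE_RULES,
    }
    return BatteryReport(results, verdicts, provenance)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("visprobe")
    except Exception:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# reporting


def load_reference_constants() -> list[dict]:
    """Published human/monkey reference values carried as plot annotations."""
    with resources.files("visprobe").joinpath(
            "data/reference_constants.json").open() as fh:
        return json.load(fh)


def render_report(report: BatteryReport, output_dir: str | Path,
                  plots: bool = False) -> dict[str, Path]:
    """Write results.csv and summary.json (optionally per-experiment plots)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    csv_path = out / "results.csv"
    df = report.results.copy()
    df["config_hash"] = report.provenance["config_hash"]
    df.to_csv(csv_path, index=False)
    files["csv"] = csv_path
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(report.to_summary(), indent=1,
                                    sort_keys=True, default=str))
    files["json"] = json_path
    if plots:
        files.update(_render_plots(report, out))
    return files


_KIND_MARKERS = {"input": ("^", "none"), "conv": ("o", "none"),
                 "relu": ("o", "full"), "pool": ("D", "none"),
                 "fc": ("s", "none"), "softmax": ("*", "full")}


def _render_plots(report: BatteryReport, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    constants = {c["experiment"]: c for c in load_reference_constants()}
    files = {}
    for exp, grp in report.results.groupby("experiment"):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for measure, sub in grp.groupby("measure"):
            sub = sub.sort_values("layer_index")
            ax.errorbar(sub["layer_index"], sub["mean"], yerr=sub["sem"],
                        label=measure, lw=1)
            for _, row in sub.iterrows():
                marker, fill = _KIND_MARKERS.get(row["layer_kind"], ("x", "full"))
                ax.plot(row["layer_index"], row["mean"], marker=marker,
                        mfc=("k" if fill == "full" else "none"), mec="k", ms=5)
        ref = constants.get(exp)
        if ref and ref.get("value") is not None:
            ax.axhline(ref["value"], ls="--", color="gray",
                       label=f"{ref['observer']} reference")
        ax.axhline(0.0, color="lightgray", lw=0.5)
        ax.set_xlabel("layer")
        ax.set_title(exp)
        ax.legend(fontsize=7)
        path = out / f"profile_{exp}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        files[f"plot_{exp}"] = path
    return files


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log progress to stderr")
def cli(verbose: bool) -> None:
    """Distance-based perceptual property battery for visual features."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--experiment", "-e", type=click.Choice(EXPERIMENTS),
              required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--size", type=int, default=stimuli.DEFAULT_SIZE,
              show_default=True)
@click.option("--out", type=click.Path(), default="stimuli_out",
              show_default=True)
def generate(experiment: str, seed: int, size: int, out: str) -> None:
    """Generate and export one experiment's stimulus set (PNG + JSON)."""
    config = BatteryConfig(seed=seed, image_size=size)
    stims = build_stimuli(experiment, config)
    path = stimuli.export_set(stims, out)
    click.echo(str(path))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML or JSON BatteryConfig")
@click.option("--extractor", default=None)
@click.option("--experiments", default=None,
              help="comma-separated subset of experiments")
@click.option("--seed", type=int, default=None)
@click.option("--size", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
@click.option("--plots", is_flag=True)
def run(config_path, extractor, experiments, seed, size, out, plots) -> None:
    """Run the battery and write results.csv / summary.json."""
    kwargs = {}
    if config_path:
        text = Path(config_path).read_text()
        kwargs = yaml.safe_load(text) or {}
    if extractor is not None:
        kwargs["extractor"] = extractor
    if experiments is not None:
        kwargs["experiments"] = tuple(x.strip() for x in experiments.split(","))
    if seed is not None:
        kwargs["seed"] = seed
    if size is not None:
        kwargs["image_size"] = size
    if out is not None:
        kwargs["output_dir"] = out
    if "experiments" in kwargs:
        kwargs["experiments"] = tuple(kwargs["experiments"])
    config = BatteryConfig(**kwargs)
    report = run_battery(config)
    files = render_report(report, config.output_dir, plots=plots)
    for verdictexp, verdict in report.verdicts.items():
        click.echo(f"{verdictexp}: {verdict}")
    click.echo(str(files["json"]))


@cli.command()
@click.argument("summary", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default="battery_out")
def report(summary: str, out: str) -> None:
    """Re-render plots and CSV from a saved summary.json."""
    rep = BatteryReport.from_summary(json.loads(Path(summary).read_text()))
    files = render_report(rep, out, plots=True)
    click.echo(str(files["csv"]))
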