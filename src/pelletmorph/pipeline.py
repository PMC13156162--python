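"""End-to-end pipeline: simulation → 2D/3D analysis → classification → stats.

The runner ties the stages into one reproducible report.  A typical demo
configuration compares a high-shear arm (breakage-dominated event schedule)
with a low-shear arm (fusion-dominated) applied to the same seed population,
then checks the macroscopic consequences: pellet number concentration,
median diameter, size-distribution overlap, class shares and the
surface-to-volume ratio.

Reports are deterministic: identical config + seed gives byte-identical
metric tables, and every report embeds the config, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify as classify_mod
from . import image2d, io, kinetics, phantom, popstats, tomo3d

__all__ = ["ArmConfig", "RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class ArmConfig:
    """One simulated cultivation arm (a shear regime)."""

    name: str = "arm"
    n_pellets: int = 200
    diameter_median: float = 609.0
    diameter_gcv: float = 0.33
    class_mix: dict = field(default_factory=lambda: {"I": 0.3, "II": 0.7})
    breakage_rate: float = 0.0
    fusion_rate: float = 0.0
    n_steps: int = 1
    sampled_volume: float = 1.0
    mu: float = 0.15
    y_xs: float = 0.65


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; every default is echoed into the report."""

    stages: tuple[str, ...] = ("simulate", "analyze2d", "analyze3d", "classify", "popstats", "kinetics")
    arms: tuple[ArmConfig, ...] = (
        ArmConfig(name="high_shear", breakage_rate=0.4),
        ArmConfig(name="low_shear", fusion_rate=0.2),
    )
    seed: int = 0
    # 2D stage
    pixel_size: float = 5.0
    field_um: tuple[float, float] = (14000.0, 14000.0)
    noise_sd: float = 0.01
    dispersed_cutoff: float = 50.0
    # 3D stage
    n_3d_pellets: int = 2
    voxel_size: float = 1.0
    # compact class-I-like pellet: dense centre, ~0.95 porosity regime
    pellet_spec: dict = field(
        default_factory=lambda: {
            "spores_per_agglomerate": 60,
            "germ_tubes_per_spore": 3,
            "spore_spread": 15.0,
            "growth_duration": 1.5,
            "direction_persistence": 0.95,
            "self_avoidance": False,
        }
    )
    prune_length: float = 6.0
    dbscan_eps: float = 10.0
    dbscan_min_pts: int = 3
    figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "arms" in d:
            d["arms"] = tuple(ArmConfig(**a) for a in d["arms"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "field_um" in d:
            d["field_um"] = tuple(d["field_um"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _child_seed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes ``report.json`` plus CSV tables (and optional figures) under
    ``outdir``; returns the report dict.  Raises :class:`PipelineError` on
    any stage failure; no stage silently drops records.
    """
    if not cfg.stages:
        raise PipelineError("configuration enables no stages")
    unknown = set(cfg.stages) - {"simulate", "analyze2d", "analyze3d", "classify", "popstats", "kinetics"}
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    populations: dict[str, tuple[phantom.SyntheticPopulation, phantom.SyntheticPopulation]] = {}
    if "simulate" in cfg.stages:
        try:
            sim_out = {}
            for arm in cfg.arms:
                seed = _child_seed(cfg.seed, f"simulate:{arm.name}")
                before = phantom.simulate_population(
                    arm.n_pellets,
                    diameter_median=arm.diameter_median,
                    diameter_gcv=arm.diameter_gcv,
                    class_mix=arm.class_mix,
                    sampled_volume=arm.sampled_volume,
                    seed=seed,
                )
                after = phantom.simulate_population(
                    arm.n_pellets,
                    diameter_median=arm.diameter_median,
                    diameter_gcv=arm.diameter_gcv,
                    class_mix=arm.class_mix,
                    breakage_rate=arm.breakage_rate,
                    fusion_rate=arm.fusion_rate,
                    n_steps=arm.n_steps,
                    sampled_volume=arm.sampled_volume,
                    seed=seed,
                )
                populations[arm.name] = (before, after)
                dist = image2d.size_distribution(after.diameters)
                sim_out[arm.name] = {
                    "n_before": len(before.pellets),
                    "n_after": len(after.pellets),
                    "concentration_before_per_ml": before.concentration,
                    "concentration_after_per_ml": after.concentration,
                    "median_before_um": float(np.median(before.diameters)),
                    "median_after_um": dist.median,
                    "iqr_after_um": dist.iqr,
                    "mean_clusters_before": before.mean_clusters(),
                    "mean_clusters_after": after.mean_clusters(),
                    "n_events": len(after.event_log),
                }
                pd.DataFrame(
                    {
                        "diameter_um": after.diameters,
                        "pellet_class": [p.pellet_class for p in after.pellets],
                        "n_clusters": [p.n_clusters for p in after.pellets],
                    }
                ).to_csv(outdir / f"population_{arm.name}.csv", index=False, float_format="%.6f")
            report["stages"]["simulate"] = sim_out
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"simulate stage failed: {e}") from e

    if "analyze2d" in cfg.stages:
        if not populations:
            raise PipelineError("analyze2d requires the simulate stage")
        try:
            out2d = {}
            seg_cfg = image2d.Segmentation2DConfig(dispersed_cutoff=cfg.dispersed_cutoff)
            for name, (_, pop) in populations.items():
                img, _truth = phantom.render_projection(
                    pop,
                    field=cfg.field_um,
                    pixel_size=cfg.pixel_size,
                    noise_sd=cfg.noise_sd,
                    seed=_child_seed(cfg.seed, f"render:{name}"),
                )
                regions = image2d.segment_pellets(img, seg_cfg)
                pellets = [r for r in regions if not r.is_dispersed and not r.touches_border]
                diam = [r.area_equivalent_diameter for r in pellets]
                dist = image2d.size_distribution(diam) if diam else None
                out2d[name] = {
                    "n_regions": len(regions),
                    "n_pellets": len(pellets),
                    "n_excluded_border": sum(r.touches_border for r in regions),
                    "n_dispersed": sum(r.is_dispersed for r in regions),
                    "concentration_per_ml": image2d.number_concentration(
                        len(pellets), img.sampled_volume
                    ),
                    "dispersed_area_fraction": image2d.dispersed_fraction(regions),
                    "median_um": dist.median if dist else None,
                    "iqr_um": dist.iqr if dist else None,
                }
                io.regions_to_dataframe(regions).to_csv(
                    outdir / f"regions2d_{name}.csv", index=False, float_format="%.6f"
                )
                if cfg.figures and dist is not None:
                    _plot_q0(dist, outdir / f"q0_{name}.png")
            report["stages"]["analyze2d"] = out2d
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"analyze2d stage failed: {e}") from e

    metrics3d: list[tomo3d.PelletMetrics3D] = []
    if "analyze3d" in cfg.stages:
        try:
            profiles = {}
            for i in range(cfg.n_3d_pellets):
                spec = phantom.PelletSpec(
                    rng_seed=_child_seed(cfg.seed, f"pellet3d:{i}"), **cfg.pellet_spec
                )
                pellet = phantom.grow_pellet(spec)
                vol = phantom.voxelize(pellet, cfg.voxel_size)
                m = tomo3d.compute_metrics(
                    vol,
                    spore_points=pellet.spore_points,
                    prune_length=cfg.prune_length,
                    dbscan_eps=cfg.dbscan_eps,
                    dbscan_min_pts=cfg.dbscan_min_pts,
                    pellet_id=i,
                )
                metrics3d.append(m)
                profiles[str(i)] = tomo3d.radial_solid_fraction(vol)
            io.write_metrics_csv(outdir / "metrics3d.csv", metrics3d)
            io.radial_profiles_to_dataframe(profiles).to_csv(
                outdir / "radial_profiles.csv", index=False, float_format="%.6f"
            )
            report["stages"]["analyze3d"] = {
                "n_pellets": len(metrics3d),
                "mean_abl_um": float(
                    np.mean([m.avg_branch_length for m in metrics3d if m.avg_branch_length])
                ),
                "mean_porosity": float(np.mean([m.porosity for m in metrics3d])),
            }
            if cfg.figures:
                _plot_radial(profiles, outdir / "radial_profiles.png")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"analyze3d stage failed: {e}") from e

    if "classify" in cfg.stages:
        try:
            out_cls = {}
            if metrics3d:
                rule = classify_mod.ClassRule()
                calls = [classify_mod.classify_pellet(m, rule=rule) for m in metrics3d]
                shares, main = classify_mod.class_shares(calls)
                out_cls["metrics3d"] = {"shares": shares, "main_class": main}
            for name, (_, pop) in populations.items():
                shares, main = classify_mod.class_shares(
                    [p.pellet_class for p in pop.pellets]
                )
                out_cls[name] = {"shares": shares, "main_class": main}
            if not out_cls:
                raise ValueError("nothing to classify: enable simulate and/or analyze3d")
            report["stages"]["classify"] = out_cls
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"classify stage failed: {e}") from e

    if "popstats" in cfg.stages:
        if len(populations) < 2:
            raise PipelineError("popstats requires at least two simulated arms")
        try:
            names = list(populations)
            stats_out = {}
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a = populations[names[i]][1].diameters
                    b = populations[names[j]][1].diameters
                    u, p = popstats.mann_whitney_u(a, b)
                    stats_out[f"{names[i]}_vs_{names[j]}"] = {
                        "U": u,
                        "p_two_sided": p,
                        "stars": popstats.significance_stars(p),
                        "overlap_coefficient": popstats.overlap_coefficient(a, b),
                    }
            sv = {}
            for name, (_, pop) in populations.items():
                res = popstats.surface_to_volume(pop.diameters, pop.concentration)
                sv[name] = res.sv_ratio
            stats_out["sv_ratio_per_um"] = sv
            report["stages"]["popstats"] = stats_out
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"popstats stage failed: {e}") from e

    if "kinetics" in cfg.stages:
        try:
            kin_out = {}
            for arm in cfg.arms:
                series = phantom.simulate_growth_series(
                    mu=arm.mu, y_xs=arm.y_xs, seed=_child_seed(cfg.seed, f"kin:{arm.name}")
                )
                res = kinetics.GrowthKineticsModel(series).fit()
                kin_out[arm.name] = res.to_dict()
            report["stages"]["kinetics"] = kin_out
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"kinetics stage failed: {e}") from e

    io.write_json(outdir / "report.json", report)
    return report


def _plot_q0(dist, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
    ax.bar(centers, dist.q0, width=np.diff(dist.bin_edges), alpha=0.6, label="q0")
    ax2 = ax.twinx()
    ax2.plot(centers, dist.Q0, "k-", label="Q0")
    ax.set_xlabel("equivalent diameter [um]")
    ax.set_ylabel("q0")
    ax2.set_ylabel("Q0")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_radial(profiles, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pid, prof in profiles.items():
        ax.plot(prof.shell_inner_radii, prof.solid_fraction_per_shell, label=f"pellet {pid}")
    ax.set_xlabel("radial coordinate [um]")
    ax.set_ylabel("solid fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
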