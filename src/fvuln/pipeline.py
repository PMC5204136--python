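"""End-to-end orchestration: inputs -> entities -> space -> diversity -> maps.

A run is configured by a :class:`RunConfig` (usually loaded from YAML),
takes either the three standard input CSVs or a synthetic-community
configuration, and writes every stage's tabular output plus a manifest
with SHA-256 checksums. Runs are deterministic under a fixed seed:
repeating a run produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__, beta, entities, io, mapping, redundancy, space, synthetic
from . import vulnerability as vuln
from .errors import FvulnError, PipelineError, ValidationError

log = logging.getLogger("fvuln")

STAGES = ("simulate", "entities", "space", "beta", "redundancy", "vulnerability", "maps")

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``synth`` (generator settings) or ``inputs`` (paths to
    traits/abundance/sensitivity CSVs) must be provided.
    """

    outdir: str | Path = "fvuln_out"
    seed: int = 0
    synth: synthetic.SynthConfig | None = None
    inputs: dict | None = None  # {"traits": ..., "abundances": [...], "sensitivity": ...}
    n_axes: int = 4
    negative_policy: str = "auto"
    target_area_m2: float | None = None  # aggregate transects up to this area
    beta_samples: int = 100_000
    topsis_cost: tuple[str, ...] = vuln.DEFAULT_COST
    topsis_benefit: tuple[str, ...] = vuln.DEFAULT_BENEFIT
    topsis_weights: dict | None = None
    kde_grid: int = 100
    kde_axis_pairs: tuple = (("PC1", "PC2"), ("PC3", "PC4"))
    render_maps: bool = True

    def __post_init__(self):
        if (self.synth is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'synth' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        synth_cfg = None
        if "synth" in raw and raw["synth"] is not None:
            synth_raw = dict(raw.pop("synth"))
            if "sensitivity_range" in synth_raw:
                synth_raw["sensitivity_range"] = tuple(synth_raw["sensitivity_range"])
            synth_raw.setdefault("seed", raw.get("seed", 0))
            synth_cfg = synthetic.SynthConfig(**synth_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "kde_axis_pairs" in raw:
            raw["kde_axis_pairs"] = tuple(tuple(p) for p in raw["kde_axis_pairs"])
        for key in ("topsis_cost", "topsis_benefit"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth_cfg, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)
    return path


class _Run:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.artifacts: dict[str, Path] = {}
        self.traits: pd.DataFrame | None = None
        self.communities: list[redundancy.CommunityMatrix] = []
        self.sensitivity: pd.Series | None = None
        self.fe_map: pd.Series | None = None
        self.members: dict[str, list[str]] | None = None
        self.sp_space: space.FunctionalSpace | None = None
        self.fe_space: space.FunctionalSpace | None = None
        self.profiles: pd.DataFrame | None = None
        self.vuln: pd.DataFrame | None = None

    def add(self, name: str, path: Path):
        self.artifacts[name] = path


def _stage_inputs(run: _Run):
    cfg = run.cfg
    if cfg.synth is not None:
        data = synthetic.generate_dataset(cfg.synth)
        paths = synthetic.write_dataset(data, run.outdir / "inputs")
        for name, p in paths.items():
            run.add(f"input_{name}", p)
        run.traits = entities.validate_traits(data.traits)
        run.communities = list(data.communities)
        run.sensitivity = data.sensitivity
    else:
        inp = cfg.inputs
        for key in ("traits", "abundances", "sensitivity"):
            if key not in inp:
                raise ValidationError(f"inputs config lacks '{key}'")
        run.traits = entities.validate_traits(io.read_traits(inp["traits"]))
        run.communities = [io.read_abundance(p) for p in inp["abundances"]]
        run.sensitivity = io.read_sensitivity(inp["sensitivity"])
    if cfg.target_area_m2 is not None:
        run.communities = [
            redundancy.aggregate_transects(cm, cfg.target_area_m2, seed=cfg.seed + i)
            for i, cm in enumerate(run.communities)
        ]
    log.info("inputs: %d species, %d regions", len(run.traits), len(run.communities))


def _stage_entities(run: _Run):
    run.fe_map = entities.assign_entities(run.traits)
    run.members = entities.entity_members(run.fe_map)
    ent_df = run.fe_map.rename_axis("species_id").reset_index()
    run.add("entities", _write_csv(ent_df, run.outdir / "entities.csv", index=False))
    hist = entities.species_per_entity(run.fe_map)
    run.add("fe_histogram", _write_csv(hist, run.outdir / "fe_histogram.csv"))
    log.info("entities: %d species -> %d FEs (%.1f%% singletons)",
             len(run.fe_map), len(run.members),
             100 * entities.singleton_fraction(run.fe_map))


def _stage_space(run: _Run):
    cfg = run.cfg
    dist = space.gower_distance(run.traits)
    run.sp_space = space.pcoa(dist, n_axes=cfg.n_axes, negative_policy=cfg.negative_policy)
    coords = run.sp_space.coordinates
    run.add("coordinates", _write_csv(coords, run.outdir / "coordinates.csv"))
    eig = pd.DataFrame(
        {"axis": coords.columns, "eigenvalue": run.sp_space.eigenvalues}
    )
    run.add("eigenvalues", _write_csv(eig, run.outdir / "eigenvalues.csv", index=False))
    # species of one FE share all trait categories, hence Gower distance 0
    # and identical ordination coordinates: the FE point is that shared point
    fe_coords = coords.groupby(run.fe_map).first()
    fe_coords.index.name = "fe_id"
    run.fe_space = space.FunctionalSpace(
        coordinates=fe_coords,
        eigenvalues=run.sp_space.eigenvalues,
        corrected=run.sp_space.corrected,
    )
    run.add("fe_coordinates", _write_csv(fe_coords, run.outdir / "fe_coordinates.csv"))

    rows = []
    global_sp = list(run.traits.index)
    for cm in run.communities:
        present = cm.counts.columns[(cm.counts.sum(axis=0) > 0)].tolist()
        res = space.fric(run.sp_space, present, global_sp, region_id=cm.region_id)
        rows.append(
            {"region_id": res.region_id, "hull_volume": res.hull_volume,
             "global_volume": res.global_volume, "fric_ratio": res.ratio}
        )
    run.add("fric", _write_csv(pd.DataFrame(rows), run.outdir / "fric.csv", index=False))
    log.info("space: %d axes, corrected=%s", run.sp_space.n_axes, run.sp_space.corrected)


def _region_species(cm: redundancy.CommunityMatrix) -> set[str]:
    return set(cm.counts.columns[cm.counts.sum(axis=0) > 0])


def _stage_beta(run: _Run):
    cfg = run.cfg
    sp_sets = {cm.region_id: _region_species(cm) for cm in run.communities}
    results = beta.taxonomic_beta(sp_sets)
    fe_sets = {
        rid: set(run.fe_map[run.fe_map.index.isin(sps)].unique())
        for rid, sps in sp_sets.items()
    }
    results += beta.functional_beta(
        run.fe_space, fe_sets, n_samples=cfg.beta_samples, seed=cfg.seed
    )
    run.add("beta", _write_csv(beta.beta_frame(results), run.outdir / "beta.csv", index=False))
    log.info("beta: %d pairs", len(results))


def _stage_redundancy(run: _Run):
    frames = [redundancy.redundancy_profile(cm, run.members) for cm in run.communities]
    run.profiles = pd.concat(frames)
    run.add("redundancy", _write_csv(run.profiles, run.outdir / "redundancy.csv"))


def _stage_vulnerability(run: _Run):
    cfg = run.cfg
    sens = vuln.fe_sensitivity(run.members, run.sensitivity)
    out = []
    for cm in run.communities:
        prof = run.profiles[run.profiles["region_id"] == cm.region_id]
        prof = prof[prof["present"]].copy()
        prof["sensitivity"] = sens.reindex(prof.index)
        res = vuln.topsis_vulnerability(
            prof, cost=cfg.topsis_cost, benefit=cfg.topsis_benefit,
            weights=cfg.topsis_weights,
        )
        out.append(vuln.rank_entities(res.reset_index()))
    run.vuln = pd.concat(out, ignore_index=True)
    cols = ["region_id", "fe_id", "FR_S", "FR_ab", "FR_Shannon", "sensitivity",
            "d_plus", "d_minus", "V", "rank"]
    run.add(
        "vulnerability",
        _write_csv(run.vuln[cols], run.outdir / "vulnerability.csv", index=False),
    )
    log.info("vulnerability: %d FE x region rankings", len(run.vuln))


_MAP_INDICES = ("FR_Shannon", "sensitivity", "V")


def _stage_maps(run: _Run):
    cfg = run.cfg
    corr_rows = []
    for cm in run.communities:
        rv = run.vuln[run.vuln["region_id"] == cm.region_id].set_index("fe_id")
        for pair in cfg.kde_axis_pairs:
            pts = run.fe_space.coordinates.loc[rv.index, list(pair)].to_numpy()
            h = mapping.adhoc_bandwidth(pts)
            surfaces = {}
            for field in _MAP_INDICES:
                surf = mapping.kde_surface(
                    pts, weights=rv[field].to_numpy(), h=h,
                    grid_size=cfg.kde_grid, axis_pair=tuple(pair), weight_field=field,
                )
                surfaces[field] = surf
                name = f"surface_{cm.region_id}_{field}_{pair[0]}-{pair[1]}"
                run.add(
                    name,
                    _write_csv(mapping.surface_frame(surf),
                               run.outdir / f"{name}.csv", index=False),
                )
                if cfg.render_maps:
                    png = run.outdir / f"{name}.png"
                    _render_surface(surf, pts, f"{cm.region_id}: {field}", png)
                    run.add(f"{name}_png", png)
            for fa, fb in (("V", "sensitivity"), ("sensitivity", "FR_Shannon"),
                           ("V", "FR_Shannon")):
                r_fe, p_fe = mapping.index_correlation(rv[fa], rv[fb])
                r_gr, p_gr = mapping.surface_correlation(surfaces[fa], surfaces[fb])
                corr_rows.append(
                    {"region_id": cm.region_id, "axes": f"{pair[0]}-{pair[1]}",
                     "index_a": fa, "index_b": fb,
                     "r_fe": r_fe, "p_fe": p_fe, "r_grid": r_gr, "p_grid": p_gr}
                )
    run.add(
        "correlations",
        _write_csv(pd.DataFrame(corr_rows), run.outdir / "correlations.csv", index=False),
    )


def _render_surface(surf: mapping.DensitySurface, pts: np.ndarray, title: str, path: Path):
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(surf.x, surf.y, surf.values, cmap="viridis", shading="auto")
    ax.plot(pts[:, 0], pts[:, 1], ".", color="white", ms=2, alpha=0.6)
    ax.set_xlabel(surf.axis_pair[0])
    ax.set_ylabel(surf.axis_pair[1])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=surf.weight_field)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": f"fvuln {__version__}"})
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_inputs,
    "entities": _stage_entities,
    "space": _stage_space,
    "beta": _stage_beta,
    "redundancy": _stage_redundancy,
    "vulnerability": _stage_vulnerability,
    "maps": _stage_maps,
}


def run_pipeline(cfg: RunConfig, upto: str = "maps") -> dict:
    """Execute pipeline stages in order and write a manifest.

    ``upto`` names the last stage to run (stages are cumulative, each
    depending on its predecessors). Returns the manifest dict; on stage
    failure, partial outputs written by this run are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    if upto not in STAGES:
        raise ValidationError(f"unknown stage '{upto}' (choose from {STAGES})")
    run = _Run(cfg)
    run.outdir.mkdir(parents=True, exist_ok=True)
    last = STAGES.index(upto)
    try:
        for stage in STAGES[: last + 1]:
            try:
                _STAGE_FUNCS[stage](run)
            except FvulnError:
                raise
            except Exception as exc:  # attach the failing stage
                raise PipelineError(stage, str(exc)) from exc
    except Exception:
        for p in run.artifacts.values():
            p.unlink(missing_ok=True)
        raise
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "upto": upto,
        "artifacts": {
            name: {"path": str(p.relative_to(run.outdir)), "sha256": _sha256(p)}
            for name, p in sorted(run.artifacts.items())
        },
    }
    mpath = run.outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
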