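"""End-to-end orchestration on synthetic data.

``run_pipeline`` chains simulate -> delimit -> sdm -> krige -> richness ->
gap -> prioritize from a single config, writing text outputs (ESRI ASCII
grids, CSV, newick) plus a YAML manifest with every seed and setting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from evoreserve import gap, gmyc, kriging, prioritize, richness, sdm, synth
from evoreserve.raster import write_ascii_grid
from evoreserve.sdm import BinaryRange

log = logging.getLogger(__name__)

_STATUSES = ("LC", "LC", "NT", "DD", "CR")  # cycled over species


@dataclass
class RunConfig:
    out_dir: str = "evoreserve_run"
    seed: int = 0
    nrows: int = 64
    ncols: int = 64
    n_vars: int = 8
    autocorr_range: float = 6.0
    n_species: int = 5
    max_lineages: int = 3
    n_records: int = 60
    tips_per_lineage: int = 8
    max_abs_corr: float = 0.75
    select_k: int = 8
    restricted_cutoff: float = 0.30
    krige_threshold: float = 0.5
    target_scale: str = "loglog"
    blp: float = 0.4
    warp: int = 1
    zoning_fractions: tuple = (0.35, 0.25, 0.3, 0.1)
    stages: tuple = ("simulate", "delimit", "sdm", "krige", "richness", "gap", "prioritize")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("zoning_fractions", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunState:
    """In-memory artefacts produced by the stages."""

    stack: synth.LandscapeStack = None
    truths: dict = field(default_factory=dict)
    occurrences: dict = field(default_factory=dict)
    trees: dict = field(default_factory=dict)
    genetic: dict = field(default_factory=dict)  # species -> (samples df, distance df)
    zoning: gap.ZoningPlan = None
    cost: np.ndarray = None
    assignments: dict = field(default_factory=dict)
    species_ranges: dict = field(default_factory=dict)
    lineage_ranges: dict = field(default_factory=dict)
    evaluations: dict = field(default_factory=dict)
    layers: dict = field(default_factory=dict)
    variograms: dict = field(default_factory=dict)
    gap_table: pd.DataFrame = None
    richness_gap: dict = field(default_factory=dict)
    solutions: dict = field(default_factory=dict)


def _species_seed(cfg: RunConfig, i: int, salt: int) -> int:
    return cfg.seed * 100_003 + i * 1009 + salt


def stage_simulate(cfg: RunConfig, st: RunState) -> None:
    st.stack = synth.gen_landscape(cfg.seed, cfg.nrows, cfg.ncols, cfg.n_vars, cfg.autocorr_range)
    rng = np.random.default_rng(cfg.seed)
    for i in range(cfg.n_species):
        sp = f"sp{i:02d}"
        var = st.stack.var_names[i % st.stack.n_vars]
        response = synth.logistic_response(var, center=float(rng.normal(0, 0.3)), slope=2.5)
        n_lin = 1 + i % cfg.max_lineages
        truth = synth.gen_virtual_species(st.stack, response, n_lin, seed=_species_seed(cfg, i, 1))
        occ = synth.sample_occurrences(truth, cfg.n_records, seed=_species_seed(cfg, i, 2), feature_id=sp)
        tree, _ = synth.gen_tree(
            n_lin, cfg.tips_per_lineage, yule_rate=0.2, coal_scale=0.002, seed=_species_seed(cfg, i, 3)
        )
        samples = _genetic_samples(truth, tree, cfg, i)
        dist = synth.gen_genetic_distances(
            samples, within_rate=0.002, between_offset=1.0, noise_sd=0.01,
            seed=_species_seed(cfg, i, 4),
        )
        st.truths[sp], st.occurrences[sp], st.trees[sp] = truth, occ, tree
        st.genetic[sp] = (samples, dist)
    zp_arr, cost = synth.gen_zoning(st.stack, cfg.zoning_fractions, seed=cfg.seed + 17)
    st.zoning = gap.ZoningPlan(zp_arr)
    st.cost = cost


def _genetic_samples(truth: synth.TruthSet, tree, cfg: RunConfig, i: int) -> pd.DataFrame:
    """One georeferenced sample per tree tip, placed in its true lineage domain."""
    rng = np.random.default_rng(_species_seed(cfg, i, 5))
    rows = []
    for c in range(truth.n_lineages):
        rr, cc = np.nonzero(truth.domains == c)
        tips = [t for t in tree.tip_labels if t.startswith(f"c{c}_")]
        take = rng.choice(len(rr), size=len(tips), replace=len(rr) < len(tips))
        for t, k in zip(tips, take):
            lon, lat = truth.stack.grid.cell_center(rr[k], cc[k])
            rows.append({"tip": t, "lon": float(lon), "lat": float(lat), "lineage": c})
    return pd.DataFrame(rows).set_index("tip")


def stage_delimit(cfg: RunConfig, st: RunState) -> None:
    for sp, tree in st.trees.items():
        assignment, _model = gmyc.delimit(tree)
        st.assignments[sp] = assignment
        log.info("%s: %d lineages delimited", sp, assignment.nunique())


def stage_sdm(cfg: RunConfig, st: RunState) -> None:
    selected = sdm.select_variables(st.stack, cfg.max_abs_corr, cfg.select_k)
    status_of = {sp: _STATUSES[i % len(_STATUSES)] for i, sp in enumerate(st.occurrences)}
    for i, (sp, occ) in enumerate(st.occurrences.items()):
        if len(occ) <= 5:
            st.species_ranges[sp] = sdm.records_to_range(occ, st.stack, sp)
        else:
            ev = sdm.replicate_evaluate(
                occ, st.stack, selected, seed=_species_seed(cfg, i, 6)
            )
            binary, theta = sdm.binarize_mtp(ev, occ, st.stack)
            binary.status = status_of[sp]
            st.species_ranges[sp] = binary
            st.evaluations[sp] = {
                "replicates": ev.replicates,
                "theta": theta,
                "tss": sdm.tss(binary, occ, st.stack, seed=_species_seed(cfg, i, 7)),
            }
        st.species_ranges[sp].status = status_of[sp]


def stage_krige(cfg: RunConfig, st: RunState) -> None:
    st.variograms = {}
    for sp, (samples, dist) in st.genetic.items():
        assignment = st.assignments.get(sp)
        labels = (
            assignment.reindex(samples.index)
            if assignment is not None
            else samples["lineage"]
        )
        k = labels.nunique()
        species_range = st.species_ranges[sp]
        if k <= 1:  # single-lineage bypass: lineage range is the species range
            st.lineage_ranges[f"{sp}_0"] = BinaryRange(
                f"{sp}_0", "lineage", species_range.raster, species_range.status
            )
            continue
        emp = kriging.empirical_variogram(dist, samples)
        vgm = kriging.fit_variogram(emp, family="spherical")
        st.variograms[sp] = vgm
        work = samples.copy()
        work["lineage"] = labels.to_numpy()
        probs = kriging.krige_indicator(work, vgm, st.stack.grid, st.stack.mask)
        for lin, prob in probs.items():
            fid = f"{sp}_{lin}"
            st.lineage_ranges[fid] = kriging.lineage_binary(
                prob, species_range, fid, cfg.krige_threshold
            )


def stage_richness(cfg: RunConfig, st: RunState) -> None:
    n_island = int(st.stack.mask.sum())
    st.layers = richness.six_layers(
        list(st.species_ranges.values()), list(st.lineage_ranges.values()), n_island
    )


def stage_gap(cfg: RunConfig, st: RunState) -> None:
    feats = list(st.species_ranges.values()) + list(st.lineage_ranges.values())
    feats = [f for f in feats if f.raster.any()]
    st.gap_table = gap.gap_table(feats, st.zoning, target_scale=cfg.target_scale)
    # richness-hotspot representation and inside/outside-PA comparison for
    # the total and restricted-range layers (wide-range layers carry lower
    # conservation value and are excluded)
    st.richness_gap = {}
    for name, layer in st.layers.items():
        if name.endswith("_wide") or layer.count.max() == 0:
            continue
        hotspot = richness.top_quartile_binary(layer, st.stack.mask)
        entry = {"hotspot_pa_percent": gap.richness_gap(hotspot, st.zoning)}
        try:
            glm = gap.compare_in_out(layer, st.zoning)
            entry.update(
                mean_inside=glm["inside"]["mean"],
                mean_outside=glm["outside"]["mean"],
                p_value=glm["p_value"],
            )
        except ValueError:
            pass  # degenerate layer (one PA group or zero variance)
        st.richness_gap[name] = entry


def stage_prioritize(cfg: RunConfig, st: RunState) -> None:
    cost = prioritize.build_cost(st.zoning)
    for name, ranges in (("species", st.species_ranges), ("lineages", st.lineage_ranges)):
        feats = [f for f in ranges.values() if f.raster.any()]
        targets = {
            f.feature_id: float(st.gap_table.loc[f.feature_id, "target_percent"]) for f in feats
        }
        problem = prioritize.PrioritizationProblem(
            feats, targets, cost, st.stack.mask, blp=cfg.blp, warp=cfg.warp
        )
        st.solutions[name] = prioritize.rank_cells(problem, record_trace=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "delimit": stage_delimit,
    "sdm": stage_sdm,
    "krige": stage_krige,
    "richness": stage_richness,
    "gap": stage_gap,
    "prioritize": stage_prioritize,
}


def run_pipeline(cfg: RunConfig) -> RunState:
    st = RunState()
    for stage in cfg.stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _STAGE_FUNCS[stage](cfg, st)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    write_outputs(cfg, st)
    return st


def write_outputs(cfg: RunConfig, st: RunState) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "config_hash": cfg.config_hash(), "stages_run": list(cfg.stages)}
    if st.stack is not None:
        grid = st.stack.grid
        for name, layer in st.stack.layers.items():
            write_ascii_grid(out / f"lv_{name}.asc", layer, grid, st.stack.mask)
    if st.zoning is not None:
        write_ascii_grid(out / "zoning.asc", st.zoning.categories, st.stack.grid)
        write_ascii_grid(out / "cost.asc", np.nan_to_num(st.cost, nan=-9999), st.stack.grid)
    for sp, occ in st.occurrences.items():
        occ.to_csv(out / f"occurrences_{sp}.csv", index=False)
    for sp, tree in st.trees.items():
        tree.write_newick(out / f"tree_{sp}.nwk")
    for sp, (samples, dist) in st.genetic.items():
        samples.to_csv(out / f"genetic_samples_{sp}.csv")
        dist.to_csv(out / f"genetic_dist_{sp}.csv")
    for sp, assignment in st.assignments.items():
        assignment.rename("lineage_id").to_csv(out / f"lineages_{sp}.csv")
    for fid, br in {**st.species_ranges, **st.lineage_ranges}.items():
        write_ascii_grid(out / f"range_{fid}.asc", br.raster.astype(int), st.stack.grid)
    for name, layer in st.layers.items():
        write_ascii_grid(out / f"richness_{name}.asc", layer.relative, st.stack.grid, st.stack.mask)
    if st.gap_table is not None:
        st.gap_table.round(6).to_csv(out / "gap_table.csv")
        manifest["n_features"] = int(len(st.gap_table))
    if st.richness_gap:
        pd.DataFrame(st.richness_gap).T.round(6).to_csv(out / "richness_gap.csv")
    if st.variograms:
        pd.DataFrame(
            {
                sp: {"family": v.family, "nugget": v.nugget, "sill": v.sill,
                     "range": v.range_, "rss": v.rss}
                for sp, v in st.variograms.items()
            }
        ).T.to_csv(out / "variograms.csv")
    for name, sol in st.solutions.items():
        write_ascii_grid(out / f"rank_{name}.asc", sol.rank, st.stack.grid)
        write_ascii_grid(out / f"minimal_{name}.asc", sol.minimal.astype(int), st.stack.grid)
    if st.evaluations:
        rows = []
        for sp, ev in st.evaluations.items():
            r = ev["replicates"].mean(numeric_only=True)
            rows.append(
                {"feature": sp, "auc_train": r["auc_train"], "auc_test": r["auc_test"],
                 "theta": ev["theta"], "tss": ev["tss"]}
            )
        pd.DataFrame(rows).set_index("feature").round(6).to_csv(out / "sdm_evaluation.csv")
    manifest["n_species"] = len(st.occurrences)
    manifest["n_lineage_features"] = len(st.lineage_ranges)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
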