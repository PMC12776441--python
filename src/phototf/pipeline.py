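"""Declarative end-to-end pipeline over the analysis stages.

A run config (YAML) names the input files, curation parameters and seeds;
``run`` executes any subset of the stages {simulate, background, formation,
repair, mutations, structure, report}, each writing TSV outputs plus a JSON
provenance record (inputs, parameters, seed, package version) into the
output directory. Stages read their upstream inputs from disk, so a single
stage can be rerun against cached artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import ContextRateTable, estimate_context_rates
from .damage import filter_blacklist, read_damage_bed, read_mutations_tsv
from .genome import read_fasta
from .intervals import IntervalSet, read_bed, write_bed
from .mutations import (actual_mutation_profile, concordance, project_mutations,
                        trinucleotide_shuffle_test)
from .profiles import (CurationConfig, analyze_formation, build_accessible_regions,
                       curate_active_sites, naked_dna_filter, shuffle_null_test)
from .repair import bootstrap_unrepaired_test, repair_efficiency_by_context
from .simulate import PlantedEffect, write_fixture_bundle
from .sites import read_sites_bed

log = logging.getLogger(__name__)

STAGES = ("simulate", "background", "formation", "repair", "mutations",
          "structure", "report")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    outdir: Path
    seed: int = 0
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def load(cls, source: str | Path | dict) -> "RunConfig":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = dict(source)
        if "outdir" not in raw:
            raise ConfigError("config needs an 'outdir'")
        cfg = cls(Path(raw["outdir"]), int(raw.get("seed", 0)),
                  dict(raw.get("paths", {})), dict(raw.get("params", {})),
                  dict(raw.get("simulate", {})))
        for key in ("threshold_cpd", "threshold_64pp"):
            t = cfg.params.get(key)
            if t is not None and not 0 < t < 1:
                raise ConfigError(f"{key}={t} outside (0,1)")
        return cfg

    def curation(self, lesion: str = "CPD") -> CurationConfig:
        p = self.params
        return CurationConfig(
            window_halfwidth=int(p.get("window_halfwidth", 40)),
            flank_margin=int(p.get("flank_margin", 5)),
            top_fraction=float(p.get("top_fraction", 0.5)),
            site_cap=p.get("site_cap"),
            min_aggregate=int(p.get("min_aggregate", 30)),
            threshold=float(p.get("threshold_cpd", 0.05)) if lesion == "CPD"
            else float(p.get("threshold_64pp", 0.01)),
            k_flank=int(p.get("k_flank", 2)),
        )

    def path(self, key: str, stage: str) -> Path:
        if key not in self.paths:
            raise ConfigError(f"stage '{stage}' needs paths.{key}")
        p = Path(self.paths[key])
        if not p.exists():
            raise FileNotFoundError(
                f"stage '{stage}': missing input {p}; run the stage that produces "
                "it first (e.g. 'simulate' for fixture inputs)")
        return p


def _provenance(cfg: RunConfig, stage: str, inputs: dict, params: dict) -> None:
    rec = {"stage": stage, "inputs": {k: str(v) for k, v in inputs.items()},
           "parameters": params, "seed": cfg.seed, "version": __version__}
    with open(cfg.outdir / f"{stage}.provenance.json", "w") as fh:
        json.dump(rec, fh, indent=2, sort_keys=True)


def _load_common(cfg: RunConfig, stage: str):
    genome = read_fasta(cfg.path("genome", stage))
    accessible = read_bed(cfg.path("accessible", stage))
    if "genic" in cfg.paths and Path(cfg.paths["genic"]).exists():
        accessible = accessible.subtract(read_bed(Path(cfg.paths["genic"])))
    return genome, accessible


def _load_damage(cfg: RunConfig, stage: str, key: str, lesion: str, timepoint: str,
                 genome) -> "pd.DataFrame":
    dmap = read_damage_bed(cfg.path(key, stage), lesion, genome, timepoint)
    if "blacklist" in cfg.paths and Path(cfg.paths["blacklist"]).exists():
        dmap = filter_blacklist(dmap, read_bed(Path(cfg.paths["blacklist"])))
    return dmap


def _curated_sites(cfg: RunConfig, stage: str, accessible, lesion: str = "CPD"):
    sites = read_sites_bed(cfg.path("sites", stage))
    return curate_active_sites(sites, accessible, cfg.curation(lesion))


def run(config: RunConfig | str | Path | dict, stages: list[str]) -> Path:
    """Execute the requested stages in canonical order; returns the outdir."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.load(config)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; choose from {STAGES}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for stage in [s for s in STAGES if s in stages]:
        t0 = time.time()
        log.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](cfg)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return cfg.outdir


def _stage_simulate(cfg: RunConfig) -> None:
    fixture = cfg.outdir / "fixture"
    sim = cfg.simulate
    effects = [PlantedEffect(*e) if not isinstance(e, PlantedEffect) else e
               for e in sim.get("effects", [])]
    write_fixture_bundle(fixture, seed=cfg.seed,
                         n_sites=int(sim.get("n_sites", 500)),
                         consensus=str(sim.get("consensus", "GGAATT")),
                         spacing=int(sim.get("spacing", 300)),
                         effects=effects,
                         hotspots=[tuple(h) for h in sim.get("hotspots", [])],
                         n_samples=int(sim.get("n_samples", 50)))
    defaults = {"genome": "genome.fa", "sites": "sites.bed",
                "accessible": "accessible.bed", "genic": "genic.bed",
                "cpd_0h": "cpd_0h.bed", "cpd_t": "cpd_6h.bed",
                "pp64": "pp64_0h.bed", "mutations": "mutations.tsv"}
    for key, name in defaults.items():
        cfg.paths.setdefault(key, str(fixture / name))
    _provenance(cfg, "simulate", {"outdir": fixture}, sim)


def _stage_background(cfg: RunConfig) -> None:
    genome, accessible = _load_common(cfg, "background")
    if "peaks" in cfg.paths:
        genic = read_bed(Path(cfg.paths["genic"])) if "genic" in cfg.paths else None
        accessible = build_accessible_regions(
            cfg.path("peaks", "background"), genic,
            float(cfg.params.get("top_fraction", 0.5)))
        write_bed(accessible, cfg.outdir / "accessible_regions.bed")
    kf = int(cfg.params.get("k_flank", 2))
    for key, lesion, out in (("cpd_0h", "CPD", "rates_cpd.tsv"),
                             ("pp64", "64PP", "rates_64pp.tsv")):
        if key not in cfg.paths:
            continue
        dmap = _load_damage(cfg, "background", key, lesion, "0h", genome)
        table = estimate_context_rates(dmap, genome, accessible, kf,
                                       region_id="accessible_intergenic")
        table.to_tsv(cfg.outdir / out)
    if "cpd_t" in cfg.paths:
        m0 = _load_damage(cfg, "background", "cpd_0h", "CPD", "0h", genome)
        mt = _load_damage(cfg, "background", "cpd_t", "CPD", "t", genome)
        eff = repair_efficiency_by_context(
            m0, mt, genome, accessible,
            norm_factor=float(cfg.params.get("norm_factor", 1.0)))
        eff.to_tsv(cfg.outdir / "repair_efficiency.tsv")
    _provenance(cfg, "background", {k: cfg.paths[k] for k in
                                    ("genome", "accessible") if k in cfg.paths},
                {"k_flank": kf})


def _stage_formation(cfg: RunConfig) -> None:
    genome, accessible = _load_common(cfg, "formation")
    for key, lesion, rates_name, out in (
            ("cpd_0h", "CPD", "rates_cpd.tsv", "formation_cpd.tsv"),
            ("pp64", "64PP", "rates_64pp.tsv", "formation_64pp.tsv")):
        if key not in cfg.paths:
            continue
        rates_path = cfg.outdir / rates_name
        if not rates_path.exists():
            raise FileNotFoundError(
                f"stage 'formation': {rates_path} missing; run 'background' first")
        rate_table = ContextRateTable.from_tsv(rates_path)
        dmap = _load_damage(cfg, "formation", key, lesion, "0h", genome)
        curation = cfg.curation(lesion)
        siteset = _curated_sites(cfg, "formation", accessible, lesion)
        prof = analyze_formation(siteset, dmap, genome, rate_table, curation)
        if bool(cfg.params.get("run_shuffle", False)):
            sh = shuffle_null_test(dmap, accessible, genome, siteset,
                                   n_iter=int(cfg.params.get("n_iter", 2000)),
                                   seed=cfg.seed, window=curation.window_halfwidth,
                                   threshold=curation.threshold)
            sh.to_tsv(cfg.outdir / out.replace(".tsv", "_shuffle.tsv"))
        if f"{key}_naked" in cfg.paths:
            naked = _load_damage(cfg, "formation", f"{key}_naked", lesion, "0h", genome)
            nprof = analyze_formation(siteset, naked, genome, rate_table, curation)
            prof = naked_dna_filter(prof, nprof)
        prof.to_tsv(cfg.outdir / out)
    _provenance(cfg, "formation", {"sites": cfg.paths.get("sites", "")},
                {"window": cfg.params.get("window_halfwidth", 40)})


def _stage_repair(cfg: RunConfig) -> None:
    genome, accessible = _load_common(cfg, "repair")
    m0 = _load_damage(cfg, "repair", "cpd_0h", "CPD", "0h", genome)
    mt = _load_damage(cfg, "repair", "cpd_t", "CPD", "t", genome)
    siteset = _curated_sites(cfg, "repair", accessible)
    res = bootstrap_unrepaired_test(
        siteset, m0, mt, genome, accessible,
        n_boot=int(cfg.params.get("n_boot", 10_000)), seed=cfg.seed,
        window=int(cfg.params.get("repair_halfwidth", 30)),
        threshold=float(cfg.params.get("threshold_cpd", 0.05)),
        kernel=str(cfg.params.get("bootstrap_kernel", "binomial")))
    res.to_tsv(cfg.outdir / "repair_test.tsv")
    _provenance(cfg, "repair", {"cpd_0h": cfg.paths["cpd_0h"],
                                "cpd_t": cfg.paths["cpd_t"]},
                {"n_boot": cfg.params.get("n_boot", 10_000)})


def _stage_mutations(cfg: RunConfig) -> None:
    genome, accessible = _load_common(cfg, "mutations")
    muts = read_mutations_tsv(cfg.path("mutations", "mutations"), genome)
    m0 = _load_damage(cfg, "mutations", "cpd_0h", "CPD", "0h", genome)
    siteset = _curated_sites(cfg, "mutations", accessible)
    w = int(cfg.params.get("window_halfwidth", 40))
    actual = actual_mutation_profile(muts, genome, siteset, w)
    projected = project_mutations(m0, genome, siteset, w)
    null = trinucleotide_shuffle_test(muts, accessible, genome, siteset,
                                      n_iter=int(cfg.params.get("n_iter", 1000)),
                                      seed=cfg.seed, window=w)
    conc = concordance(projected, actual, seed=cfg.seed)
    out = null.set_index("position")
    out["actual"] = actual
    out["projected"] = projected
    out["residual_z"] = conc.residual_z
    out.reset_index().to_csv(cfg.outdir / "mutations_profile.tsv", sep="\t",
                             index=False, float_format="%.6g")
    with open(cfg.outdir / "mutations_concordance.json", "w") as fh:
        json.dump({"pearson_r": conc.r, "slope": conc.slope,
                   "intercept": conc.intercept,
                   "discordant_positions": conc.discordant}, fh, indent=2)
    _provenance(cfg, "mutations", {"mutations": cfg.paths["mutations"]},
                {"window": w})


def _stage_structure(cfg: RunConfig) -> None:
    from .geometry import (compare_states, confidence_filter, dipyrimidine_geometry,
                           load_structure)
    rows = []
    geoms = {"bound": [], "unbound": []}
    for state in ("bound", "unbound"):
        key = f"structures_{state}"
        for path in cfg.paths.get(key, []):
            model = load_structure(path)
            ok, retained = confidence_filter(
                model, float(cfg.params.get("min_plddt", 70.0)),
                int(cfg.params.get("trim_bp", 3)))
            if not ok:
                log.warning("structure %s fails the confidence filter; skipped", path)
                continue
            by_chain: dict[str, list] = {}
            for r in retained:
                by_chain.setdefault(r.chain, []).append(r)
            for chain_res in by_chain.values():
                for r5, r3 in zip(chain_res, chain_res[1:]):
                    if r5.is_pyrimidine and r3.is_pyrimidine:
                        g = dipyrimidine_geometry(r5, r3, structure_id=model.structure_id,
                                                  state=state)
                        geoms[state].append(g)
                        rows.append(g.as_dict())
    pd.DataFrame(rows).to_csv(cfg.outdir / "structure_geometry.tsv", sep="\t",
                              index=False, float_format="%.6g")
    if len(geoms["bound"]) >= 3 and len(geoms["unbound"]) >= 3:
        thresholds = cfg.params.get("reactivity_thresholds") or None
        if thresholds:
            thresholds = {k: tuple(v) for k, v in thresholds.items()}
        cmp_df = compare_states(geoms["bound"], geoms["unbound"], thresholds)
        cmp_df.to_csv(cfg.outdir / "structure_comparison.tsv", sep="\t",
                      index=False, float_format="%.6g")
    _provenance(cfg, "structure", {}, {"min_plddt": cfg.params.get("min_plddt", 70)})


def _stage_report(cfg: RunConfig) -> None:
    """clusters x positions matrices of signed max-|z| per position."""
    for name in ("formation_cpd", "formation_64pp", "repair_test"):
        path = cfg.outdir / f"{name}.tsv"
        if not path.exists():
            continue
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        def pick(grp):
            z = grp["z"].to_numpy(dtype=float)
            return np.nan if np.all(np.isnan(z)) else z[np.nanargmax(np.abs(z))]
        series = df.groupby("position").apply(pick, include_groups=False)
        mat = pd.DataFrame([series.to_numpy()], columns=series.index,
                           index=[meta.get("cluster", "cluster")])
        mat.to_csv(cfg.outdir / f"{name}_zmatrix.tsv", sep="\t",
                   float_format="%.4g")
    _provenance(cfg, "report", {}, {})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "background": _stage_background,
    "formation": _stage_formation,
    "repair": _stage_repair,
    "mutations": _stage_mutations,
    "structure": _stage_structure,
    "report": _stage_report,
}
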