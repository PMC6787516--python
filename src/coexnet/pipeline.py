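"""End-to-end orchestration of the two-arm coexpression analysis.

Stages: (optional) simulate -> preprocess -> rank-product DE filter ->
WGCNA arm -> DiffCoEx arm -> enrichment -> report.  Every stage reads and
writes the plain TSV interfaces of the library modules, so stages are
composable on disk; a manifest records parameters, seeds and row counts.
All stage parameters default to the study's published settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffcoex as dc
from . import enrichment as enr
from . import io as cio
from . import rankprod as rp
from . import simulate as sim
from . import wgcna as wg
from .datatypes import GREY, ExpressionMatrix, ModuleAssignment, TraitTable

log = logging.getLogger("coexnet")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    # inputs (ignored when simulate=True)
    expression: str | None = None
    traits: str | None = None
    probe_map: str | None = None
    gene_sets: str | None = None          # GMT path for enrichment

    # synthetic-data stage
    simulate: bool = False

    # global
    seed: int = 0

    # DE filter
    de_alpha: float = 0.05
    de_n_perm: int = 1000
    de_comparison_cap: int = 50
    filter_to_degs: bool = True

    # WGCNA arm
    powers: tuple = wg.DEFAULT_POWERS
    target_fit: float = 0.85
    scan_subsample: int = 5000
    wgcna_min_size: int = 50
    wgcna_merge_height: float = 0.25
    wgcna_cut_height: float | None = None
    wgcna_min_kme: float = 0.5
    hub_top_n: int = 10

    # DiffCoEx arm
    diffcoex_beta: float = dc.DEFAULT_BETA
    diffcoex_cut_height: float = dc.DEFAULT_CUT_HEIGHT
    diffcoex_min_size: int = dc.DEFAULT_MIN_SIZE
    diffcoex_merge_height: float = dc.DEFAULT_MERGE_HEIGHT
    delta_r_threshold: float = dc.DEFAULT_DELTA_R
    dispersion_n_perm: int = 200

    # enrichment
    ora_top_k: int = 20
    ora_alpha: float = 0.05

    # stage toggles
    run_de: bool = True
    run_wgcna: bool = True
    run_diffcoex: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if getattr(cfg, f.name) != getattr(defaults, f.name):
                log.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(d["powers"])
        return d


def _write_modules(modules: ModuleAssignment, path) -> None:
    modules.labels.to_csv(path, sep="\t", index_label="gene")


def read_modules(path) -> ModuleAssignment:
    s = pd.read_csv(path, sep="\t", index_col=0)["module"]
    return ModuleAssignment(s)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> sim.SyntheticDataset:
    spec = sim.benchmark_a(seed=cfg.seed)
    ds = sim.generate(spec)
    cio.write_expression(ds.expr, outdir / "expression.tsv")
    cio.write_trait_table(ds.traits, outdir / "traits.tsv")
    ds.truth.module_labels.to_csv(outdir / "truth.tsv", sep="\t",
                                  index_label="gene")
    return ds


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> tuple[ExpressionMatrix, TraitTable]:
    expr = cio.read_expression(cfg.expression,
                               dialect="csv" if str(cfg.expression).endswith(".csv") else "tsv")
    if cfg.probe_map:
        pm = cio.read_probe_map(cfg.probe_map)
        expr = cio.collapse_probes(expr, pm)
    traits = cio.read_trait_table(cfg.traits)
    expr, traits = cio.align(expr, traits)
    return expr, traits


def stage_de(cfg: PipelineConfig, expr: ExpressionMatrix, traits: TraitTable,
             outdir: Path) -> list[str]:
    result = rp.rank_product(expr, traits, n_comparisons_cap=cfg.de_comparison_cap,
                             n_perm=cfg.de_n_perm, seed=cfg.seed)
    result.write(outdir / "rankprod.tsv", alpha=cfg.de_alpha)
    degs = rp.filter_degs(result, alpha=cfg.de_alpha)
    (outdir / "degs.txt").write_text("\n".join(degs) + ("\n" if degs else ""))
    return degs


def stage_wgcna(cfg: PipelineConfig, expr: ExpressionMatrix, traits: TraitTable,
                outdir: Path) -> ModuleAssignment:
    scan = wg.soft_connectivity_scan(expr, powers=cfg.powers,
                                     subsample=cfg.scan_subsample,
                                     target_fit=cfg.target_fit, seed=cfg.seed)
    scan.as_frame().to_csv(outdir / "scan.tsv", sep="\t", index=False,
                           float_format="%.10g")
    power = scan.chosen_power
    if power is None:
        fits = [f for f in scan.fit_index if f is not None]
        if not fits:
            raise StageError("wgcna: scale-free fit undefined for every power")
        power = scan.powers[int(np.nanargmax(
            [np.nan if f is None else f for f in scan.fit_index]))]
        log.warning("wgcna: no power reached fit %.2f; using best power %s",
                    cfg.target_fit, power)
    adj = wg.adjacency(expr, power)
    t = wg.tom(adj)
    diss = t.dissimilarity()
    z = wg.cluster_genes(diss)
    modules = wg.cut_modules(z, diss, expr.gene_ids,
                             min_size=cfg.wgcna_min_size,
                             cut_height=cfg.wgcna_cut_height)
    if modules.modules():
        modules = wg.merge_similar_modules(expr, modules,
                                           merge_height=cfg.wgcna_merge_height,
                                           min_size=cfg.wgcna_min_size)
        modules = wg.prune_low_kme(expr, modules, min_kme=cfg.wgcna_min_kme,
                                   min_size=cfg.wgcna_min_size)
    _write_modules(modules, outdir / "modules_wgcna.tsv")

    if modules.modules():
        egs = wg.module_eigengene(expr, modules)
        egs.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t",
                              float_format="%.10g")
        mt = wg.module_trait_correlation(egs, traits)
        mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False,
                  float_format="%.10g")
        kme = wg.module_membership(expr, egs)
        kme.to_csv(outdir / "kme.tsv", sep="\t", float_format="%.10g")
        hubs = wg.hub_genes(adj, modules, top_n=cfg.hub_top_n)
        hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False,
                    float_format="%.10g")
    gs = wg.gene_significance(expr, traits)
    gs["gs"].to_csv(outdir / "gene_significance.tsv", sep="\t",
                    float_format="%.10g")
    return modules


def stage_diffcoex(cfg: PipelineConfig, expr: ExpressionMatrix, traits: TraitTable,
                   outdir: Path) -> dc.DiffCoExResult:
    cc = dc.condition_correlations(expr, traits)
    modules = dc.diffcoex_modules(expr, cc, beta=cfg.diffcoex_beta,
                                  cut_height=cfg.diffcoex_cut_height,
                                  min_size=cfg.diffcoex_min_size,
                                  merge_height=cfg.diffcoex_merge_height)
    _write_modules(modules, outdir / "modules_diffcoex.tsv")
    disp = dc.dispersion_test(expr, traits, modules,
                              n_perm=cfg.dispersion_n_perm, seed=cfg.seed)
    disp.to_csv(outdir / "dispersion.tsv", sep="\t", index=False,
                float_format="%.10g")
    assigned = [g for g in modules.gene_ids
                if modules.labels[g] != GREY] or None
    edges = dc.differential_edges(cc, threshold=cfg.delta_r_threshold,
                                  restrict_to=assigned)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False,
                 float_format="%.10g")
    return dc.DiffCoExResult(modules=modules, dispersion=disp,
                             params={"beta": cfg.diffcoex_beta,
                                     "cut_height": cfg.diffcoex_cut_height,
                                     "min_size": cfg.diffcoex_min_size,
                                     "merge_height": cfg.diffcoex_merge_height,
                                     "n_perm": cfg.dispersion_n_perm,
                                     "seed": cfg.seed})


def stage_enrichment(cfg: PipelineConfig, background: list[str],
                     assignments: dict[str, ModuleAssignment],
                     outdir: Path) -> None:
    sets = enr.read_gmt(cfg.gene_sets)
    for arm, modules in assignments.items():
        frames = []
        for m in modules.modules():
            query = [g for g in modules.genes_in(m) if g in set(background)]
            if not query:
                continue
            res = enr.ora(query, background, sets)
            top = enr.top_terms(res, k=cfg.ora_top_k, alpha=cfg.ora_alpha)
            top.insert(0, "module", m)
            frames.append(top)
        out = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["module", "set_id", "name", "overlap",
                                          "set_size", "query_size",
                                          "background_size", "p", "q", "genes"]))
        out.to_csv(outdir / f"enrichment_{arm}.tsv", sep="\t", index=False,
                   float_format="%.10g")


def write_report(outdir: Path) -> str:
    """Summarize module counts and sizes from the run artifacts only."""
    lines = []
    for arm in ("wgcna", "diffcoex"):
        path = outdir / f"modules_{arm}.tsv"
        if not path.exists():
            continue
        modules = read_modules(path)
        sizes = modules.sizes()
        lines.append(f"{arm}: {len(sizes)} modules, "
                     f"{modules.n_assigned()}/{len(modules.gene_ids)} genes assigned")
        for m, s in sizes.items():
            lines.append(f"  {m}: {s} genes")
    disp_path = outdir / "dispersion.tsv"
    if disp_path.exists():
        disp = pd.read_csv(disp_path, sep="\t")
        for _, row in disp.iterrows():
            lines.append(f"dispersion {row['module']}: T={row['T']:.4f} p={row['p']:.4g}")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def run(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    try:
        if cfg.simulate:
            ds = stage_simulate(cfg, outdir)
            expr, traits = ds.expr, ds.traits
        else:
            expr, traits = stage_preprocess(cfg, outdir)
    except StageError:
        raise
    except Exception as exc:
        fail("preprocess", exc)
    manifest["stages"]["preprocess"] = {
        "status": "ok", "n_genes": expr.n_genes, "n_samples": expr.n_samples,
    }

    network_expr = expr
    if cfg.run_de:
        try:
            degs = stage_de(cfg, expr, traits, outdir)
        except Exception as exc:
            fail("de", exc)
        manifest["stages"]["de"] = {"status": "ok", "n_degs": len(degs)}
        if cfg.filter_to_degs:
            if len(degs) < 10:
                fail("de", ValueError(
                    f"only {len(degs)} genes pass the DE filter at "
                    f"alpha={cfg.de_alpha}; downstream network stages need "
                    f"more genes — relax de_alpha or set filter_to_degs: false"))
            network_expr = expr.subset_genes(degs)

    assignments: dict[str, ModuleAssignment] = {}
    if cfg.run_wgcna:
        try:
            assignments["wgcna"] = stage_wgcna(cfg, network_expr, traits, outdir)
        except StageError:
            raise
        except Exception as exc:
            fail("wgcna", exc)
        manifest["stages"]["wgcna"] = {
            "status": "ok",
            "n_modules": len(assignments["wgcna"].modules()),
            "sizes": assignments["wgcna"].sizes(),
        }

    if cfg.run_diffcoex:
        try:
            result = stage_diffcoex(cfg, network_expr, traits, outdir)
        except StageError:
            raise
        except Exception as exc:
            fail("diffcoex", exc)
        assignments["diffcoex"] = result.modules
        manifest["stages"]["diffcoex"] = {
            "status": "ok",
            "n_modules": len(result.modules.modules()),
            "sizes": result.modules.sizes(),
        }

    if cfg.run_enrichment and cfg.gene_sets and assignments:
        try:
            stage_enrichment(cfg, network_expr.gene_ids, assignments, outdir)
        except Exception as exc:
            fail("enrichment", exc)
        manifest["stages"]["enrichment"] = {"status": "ok"}

    write_report(outdir)
    manifest["seed"] = cfg.seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
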