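"""End-to-end orchestration: simulate -> normalize -> DE -> cluster ->
predict -> integrate -> enrich, from one config with one top-level seed.

The top-level seed deterministically derives one sub-seed per stochastic
stage (simulation, ANOVA permutations, SAM permutations, template-match
permutations, UTR generation), so any stage can be rerun in isolation and
identical config+seed gives byte-identical outputs.  In fixtures-only mode
the packaged shared-target table replaces simulation+prediction and the
pipeline reproduces the published intersection count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import hcluster, to_newick
from .diffexpr import classify_de, fold_change, permutation_anova, sam_two_class
from .enrichment import enrich
from .integration import TemplateMatch, build_template, integrate, template_match_test
from .io_formats import GeneSetCollection, load_fixture, write_expression_matrix
from .matrix import ExpressionMatrix
from .normalization import between_array_center
from .synthetic_data import (DEFAULT_MATURE_SEQS, SimulationConfig,
                             simulate_expression, simulate_utrs)
from .target_prediction import MatureMiRNA, predict_targets

__all__ = ["PipelineConfig", "run_pipeline", "derive_seeds"]

_STAGES = ("simulate", "anova", "sam", "template", "utrs")


def derive_seeds(seed: int) -> dict[str, int]:
    """Per-stage sub-seeds derived from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(len(_STAGES))
    return {name: int(s % (2**31 - 1)) for name, s in zip(_STAGES, children)}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    ``mode`` is ``synthetic`` (simulate everything) or ``fixtures`` (use the
    packaged shared-target table; no simulation).  Thresholds follow the
    module defaults: ANOVA alpha 0.05 with fold-change dead band 0.8/1.2,
    SAM q cutoff, template-match r <= r_max with permutation alpha, and the
    per-gene ddG cutoff for calling predicted targets.
    """

    mode: str = "synthetic"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    rng_seed: int = 0
    out_dir: str = "atromir_run"
    n_perm: int = 1000
    alpha: float = 0.05
    fc_down: float = 0.8
    fc_up: float = 1.2
    sam_n_perm: int = 100
    sam_q: float = 0.10
    ddg_cutoff: float = 0.0
    r_max: float = -0.8
    template_alpha: float = 0.05
    template_n_perm: int = 1000
    top_terms: int = 10
    utr_length: int = 300
    between_method: str = "median"
    down_contrast: tuple[str, str] = ("Den3", "late")  # Den3 vs Den7+Den14

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
        if "planted_mirnas" in sim_raw:
            sim_raw["planted_mirnas"] = {
                k: dict(v) for k, v in sim_raw["planted_mirnas"].items()
            }
        cfg = cls(**raw)
        cfg.simulate = SimulationConfig(**sim_raw) if sim_raw else cfg.simulate
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _log(stage: str, t0: float, **params) -> None:
    rec = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3), **params}
    print(json.dumps(rec), file=sys.stderr)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(c) for c in r) + "\n")


def _down_regulated_genes(cfg: PipelineConfig, mrna: ExpressionMatrix,
                          seeds: dict[str, int]) -> set[str]:
    """SAM-called down-regulated genes between early and late denervation."""
    labels = mrna.conditions()
    if cfg.down_contrast[1] == "late":
        group2 = {"Den7", "Den14"}
    else:
        group2 = {cfg.down_contrast[1]}
    two = ["g1" if c == cfg.down_contrast[0] else ("g2" if c in group2 else "other")
           for c in labels]
    keep = [s for s, g in zip(mrna.sample_ids, two) if g != "other"]
    sub = mrna.subset_samples(keep)
    sub_groups = [g for g in two if g != "other"]
    res = sam_two_class(sub, sub_groups, "g1", "g2", n_perm=cfg.sam_n_perm,
                        rng_seed=seeds["sam"])
    # down in late vs early: mean(g2) < mean(g1) <=> d > 0 under d = m1 - m2
    return {r.feature_id for r in res
            if r.tested and r.d_stat > 0 and r.q_value <= cfg.sam_q}


def _synthetic_gene_sets(truth, rng_seed: int) -> GeneSetCollection:
    """Gene-set collection for synthetic runs: planted programs + decoys."""
    rng = np.random.default_rng(rng_seed)
    genes = list(truth.mrna_effects.index)
    sets: dict[str, set[str]] = {
        "PLANTED_SHARED": set(truth.shared_targets),
    }
    for mirna, tg in truth.targets.items():
        sets[f"PLANTED_TARGETS_{mirna}"] = set(tg)
    for k in range(10):
        size = int(rng.integers(10, 60))
        sets[f"DECOY_{k:02d}"] = set(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection.from_dict(sets)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline and write its report bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    emitted artifacts, seeds and the config hash.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg.rng_seed)
    artifacts: list[str] = []
    results: dict = {}

    if cfg.mode == "fixtures":
        return _run_fixtures_mode(cfg, out, artifacts)
    if cfg.mode != "synthetic":
        raise ValueError(f"unknown pipeline mode {cfg.mode!r}")

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    sim = dataclasses.replace(cfg.simulate, rng_seed=seeds["simulate"])
    mirna_m, mrna_m, truth = simulate_expression(sim)
    utrs = simulate_utrs(truth, utr_length=cfg.utr_length, rng_seed=seeds["utrs"])
    _log("simulate", t0, n_mirna=sim.n_mirna, n_mrna=sim.n_mrna)

    # --- normalize ------------------------------------------------------
    t0 = time.perf_counter()
    mirna_n = between_array_center(mirna_m, method=cfg.between_method)
    mrna_n = between_array_center(mrna_m, method=cfg.between_method)
    write_expression_matrix(mirna_n, out / "mirna_normalized.tsv",
                            meta_path=out / "mirna_samples.tsv")
    write_expression_matrix(mrna_n, out / "mrna_normalized.tsv")
    artifacts += ["mirna_normalized.tsv", "mrna_normalized.tsv"]
    _log("normalize", t0, method=cfg.between_method)

    # --- miRNA DE (permutation ANOVA + fold-change classes) -------------
    t0 = time.perf_counter()
    de = permutation_anova(mirna_n, n_perm=cfg.n_perm, rng_seed=seeds["anova"])
    conditions = [c for c in dict.fromkeys(mirna_n.conditions()) if c != "control"]
    fcs = {c: fold_change(mirna_n, c) for c in conditions}
    rows = []
    for r in de:
        row = [r.feature_id, f"{r.F_stat:.4f}" if r.tested else "NA",
               f"{r.p_perm:.4g}" if r.tested else "NA"]
        for c in conditions:
            fc = fcs[c][r.feature_id]
            if r.tested and np.isfinite(fc):
                row += [f"{fc:.4f}", classify_de(fc, r.p_perm, cfg.alpha,
                                                 cfg.fc_down, cfg.fc_up)]
            else:
                row += ["NA", "untested"]
        rows.append(row)
    hdr = ["mirna", "F", "p_perm"]
    for c in conditions:
        hdr += [f"fc_{c}", f"class_{c}"]
    _write_tsv(out / "mirna_de.tsv", hdr, rows)
    artifacts.append("mirna_de.tsv")
    _log("de", t0, n_perm=cfg.n_perm, tested=sum(r.tested for r in de))

    # --- clustering -----------------------------------------------------
    t0 = time.perf_counter()
    tree = hcluster(mirna_n, axis="samples")
    (out / "samples_dendrogram.nwk").write_text(to_newick(tree) + "\n")
    artifacts.append("samples_dendrogram.nwk")
    results["dendrogram"] = tree
    _log("cluster", t0, n_samples=len(tree.labels))

    # --- target prediction ----------------------------------------------
    t0 = time.perf_counter()
    mirnas = [MatureMiRNA(name, DEFAULT_MATURE_SEQS[name])
              for name in sim.planted_mirnas]
    preds, unevaluated = predict_targets(utrs, mirnas, cutoff=cfg.ddg_cutoff)
    _write_tsv(out / "predicted_targets.tsv",
               ["gene", "mirna", "sites", "ddG_total"],
               [[p.gene_id, p.mirna, p.n_sites, f"{p.ddG_total:.4f}"] for p in preds])
    artifacts.append("predicted_targets.tsv")
    _log("predict", t0, n_predictions=len(preds), unevaluated=len(unevaluated))

    # --- integration ----------------------------------------------------
    t0 = time.perf_counter()
    down = _down_regulated_genes(cfg, mrna_n, seeds)
    pred_sets = {m.name: {p.gene_id for p in preds if p.mirna == m.name}
                 for m in mirnas}
    mirna_cond = mirna_n.condition_means()
    mrna_cond = mrna_n.condition_means()
    matches: dict[str, dict[str, TemplateMatch]] = {}
    rng = np.random.default_rng(seeds["template"])
    for m in mirnas:
        template = build_template(mirna_cond.loc[m.name].to_numpy())
        mm: dict[str, TemplateMatch] = {}
        for gene in sorted(pred_sets[m.name]):
            mm[gene] = template_match_test(
                mrna_cond.loc[gene].to_numpy(), template,
                n_perm=cfg.template_n_perm,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                r_max=cfg.r_max, alpha=cfg.template_alpha, gene_id=gene,
            )
        matches[m.name] = mm
    result = integrate(pred_sets, down, matches)
    (out / "venn_counts.json").write_text(json.dumps(result.venn, indent=2) + "\n")
    _write_tsv(out / "shared_targets.tsv", ["gene"],
               [[g] for g in sorted(result.shared)])
    artifacts += ["venn_counts.json", "shared_targets.tsv"]
    results["integration"] = result
    results["truth"] = truth
    _log("integrate", t0, **result.venn)

    # --- enrichment -----------------------------------------------------
    t0 = time.perf_counter()
    collection = _synthetic_gene_sets(truth, seeds["template"])
    universe = set(mrna_n.feature_ids)
    top_rows, all_rows = enrich(result.shared or set(), universe, collection,
                                top=cfg.top_terms) if result.shared else ([], [])
    _write_tsv(out / "enrichment.tsv",
               ["term", "K", "n", "k", "p_hyper", "p_bh", "genes"],
               [[r.term, r.K, r.n, r.k, f"{r.p_hyper:.4g}", f"{r.p_bh:.4g}",
                 ",".join(r.overlap)] for r in top_rows])
    artifacts.append("enrichment.tsv")
    results["enrichment"] = all_rows
    _log("enrich", t0, n_terms=len(all_rows))

    manifest = {
        "version": __version__,
        "mode": cfg.mode,
        "rng_seed": cfg.rng_seed,
        "stage_seeds": seeds,
        "config_hash": cfg.config_hash(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def _run_fixtures_mode(cfg: PipelineConfig, out: Path, artifacts: list[str]) -> dict:
    """Reproduce the published shared-target intersection from the packaged
    table instead of simulating: every fixture gene with >= 1 site for a miRNA
    is that miRNA's anticorrelated target (the table lists exactly the genes
    that passed the published filter for both)."""
    records = load_fixture("table5_shared_targets")
    per = {
        "miR-206": {r.gene_symbol for r in records if r.sites_206 > 0},
        "miR-21": {r.gene_symbol for r in records if r.sites_21 > 0},
    }
    matches = {m: {g: TemplateMatch(g, -1.0, 0.0, True) for g in s}
               for m, s in per.items()}
    down = per["miR-206"] | per["miR-21"]
    result = integrate(per, down, matches)
    (out / "venn_counts.json").write_text(json.dumps(result.venn, indent=2) + "\n")
    _write_tsv(out / "shared_targets.tsv",
               ["gene", "sites_206", "score_206", "sites_21", "score_21"],
               [[r.gene_symbol, r.sites_206, r.score_206, r.sites_21, r.score_21]
                for r in records])
    artifacts += ["venn_counts.json", "shared_targets.tsv"]
    cats = load_fixture("table6_categories")
    universe = {r.gene_symbol.upper() for r in records}
    collection = GeneSetCollection.from_dict(
        {row["term_name"]: set(row["genes"]) for _, row in cats.iterrows()}
    )
    top_rows, all_rows = enrich({r.gene_symbol for r in records}, universe,
                                collection, top=cfg.top_terms)
    _write_tsv(out / "enrichment.tsv",
               ["term", "K", "n", "k", "p_hyper", "p_bh", "genes"],
               [[r.term, r.K, r.n, r.k, f"{r.p_hyper:.4g}", f"{r.p_bh:.4g}",
                 ",".join(r.overlap)] for r in top_rows])
    artifacts.append("enrichment.tsv")
    manifest = {
        "version": __version__, "mode": "fixtures", "rng_seed": cfg.rng_seed,
        "config_hash": cfg.config_hash(), "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {"integration": result, "enrichment": all_rows, "manifest": manifest}
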