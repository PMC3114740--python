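"""Run the full analysis from one structured config file.

Stages execute in dependency order — load/simulate inputs, weight characters,
search, consensus, branch support, stratigraphic fit, topology tests,
character maps — and a provenance manifest records config and input digests,
seeds, and per-stage scores so a rerun with the same config reproduces the
same numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .matrix_io import (
    AgeTable,
    CharacterMatrix,
    MatrixError,
    read_age_table,
    read_newick,
    read_nexus,
    write_newick,
    write_nexus,
)
from .parsimony import WeightScheme, scaling_weights, tree_length
from .stratigraphy import stratfit
from .support import bremer_support, double_decay_support, format_bs, format_ddbs
from .synthetic_data import SimConfig, simulate_dataset
from .topology_tests import per_character_diffs, templeton_test, winning_sites_test
from .tree import PhyloTree
from .tree_search import BackboneConstraint, heuristic_search, strict_consensus
from .char_evolution import classify_pair_homology, deltran, state_changes
from .matrix_io import read_newick_list

log = logging.getLogger("paleopars")

__all__ = ["RunManifest", "run_pipeline", "validate_inputs"]

KNOWN_KEYS = {
    "seed",
    "inputs",
    "weighting",
    "k",
    "stages",
    "output_dir",
}
KNOWN_STAGES = {"score", "search", "consensus", "support", "stratfit", "toptest", "charmap"}


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    input_digests: dict
    stages: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def validate_inputs(
    matrix: Optional[CharacterMatrix],
    trees: Optional[list[PhyloTree]],
    ages: Optional[AgeTable],
    constraint: Optional[BackboneConstraint],
) -> list[str]:
    """Cross-check taxon names between the bundle's pieces; returns a report
    of every mismatch (empty = consistent).  Never raises."""
    report: list[str] = []
    mat_taxa = set(matrix.taxa) if matrix is not None else None
    for i, tree in enumerate(trees or []):
        if mat_taxa is not None:
            for tip in set(tree.tip_labels()) - mat_taxa:
                report.append(f"tree {i}: tip {tip!r} absent from matrix")
        if ages is not None:
            for tip in tree.tip_labels():
                if tip not in ages:
                    report.append(f"tree {i}: tip {tip!r} absent from age table")
    if constraint is not None and mat_taxa is not None:
        for tip in set(constraint.backbone.tip_labels()) - mat_taxa:
            report.append(f"constraint backbone tip {tip!r} absent from matrix")
        for tip in constraint.floating - mat_taxa:
            report.append(f"floating taxon {tip!r} absent from matrix")
    if ages is not None and mat_taxa is not None:
        for taxon in mat_taxa - set(ages.taxa()):
            report.append(f"matrix taxon {taxon!r} absent from age table")
        # an extant taxon whose molecular data are all missing is suspicious:
        # it matches the coding pattern of a fossil
        for taxon in sorted(mat_taxa & set(ages.taxa())):
            if not ages.is_extant(taxon):
                continue
            row = matrix.cells[matrix.taxa.index(taxon)]
            full = [frozenset(s.state_space) for s in matrix.specs]
            if matrix.n_char and all(c == f for c, f in zip(row, full)):
                report.append(
                    f"taxon {taxon!r} is listed as extant but every cell is "
                    f"missing (fossil-style coding)"
                )
    return report


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise MatrixError(f"unknown config keys: {sorted(unknown)}")
    for key in set(cfg.get("stages", {})) - KNOWN_STAGES:
        raise MatrixError(f"unknown stage {key!r} in config")
    if "seed" not in cfg:
        raise MatrixError("config must set an explicit seed")
    return cfg


def run_pipeline(config, output_dir: Optional[str] = None) -> RunManifest:
    """Execute the enabled stages; outputs land in `output_dir` and the
    returned manifest records scores and digests.  A stage failure stops the
    stages that depend on it, with the cause logged and recorded."""
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(output_dir or cfg.get("output_dir", "paleopars_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=_digest(json.dumps(cfg, sort_keys=True, default=str)),
        seeds={"master": seed},
        input_digests={},
    )

    inputs = cfg.get("inputs", {})
    matrix = trees = ages = constraint = true_tree = None

    if "simulate" in inputs:
        sim = SimConfig(**{**inputs["simulate"], "seed": seed})
        true_tree, matrix, ages, fossils = simulate_dataset(sim)
        manifest.stages["simulate"] = {
            "n_taxa": matrix.n_taxa,
            "n_char": matrix.n_char,
            "fossils": sorted(fossils),
        }
        write_nexus(matrix, outdir / "matrix.nex")
        write_newick(true_tree, outdir / "true_tree.nwk")
    elif "matrix" in inputs:
        text = Path(inputs["matrix"]).read_text()
        manifest.input_digests["matrix"] = _digest(text)
        matrix = read_nexus(text)
    if "trees" in inputs:
        text = Path(inputs["trees"]).read_text()
        manifest.input_digests["trees"] = _digest(text)
        trees = read_newick_list(text)
    if "ages" in inputs and ages is None:
        text = Path(inputs["ages"]).read_text()
        manifest.input_digests["ages"] = _digest(text)
        ages = read_age_table(text)
    if "constraint" in inputs:
        c = inputs["constraint"]
        backbone = read_newick(c["backbone"])
        constraint = BackboneConstraint(backbone, frozenset(c.get("floating", [])))

    report = validate_inputs(matrix, trees, ages, constraint)
    if report:
        for line in report:
            log.warning("input check: %s", line)
        manifest.stages["validate"] = {"mismatches": report}

    if matrix is None:
        raise MatrixError("no matrix: supply inputs.matrix or inputs.simulate")

    mode = cfg.get("weighting", "equal")
    if mode == "scaled":
        weights = scaling_weights(matrix)
    elif mode == "implied":
        weights = WeightScheme(mode="implied", k=float(cfg.get("k", 3.0)))
    elif mode == "equal":
        weights = WeightScheme(mode="equal")
    else:
        raise MatrixError(f"unknown weighting mode {mode!r}")

    stages = cfg.get("stages", {})
    best_trees: Optional[list[PhyloTree]] = None
    best_score: Optional[float] = None
    failed = False

    def stage_enabled(name) -> bool:
        return bool(stages.get(name))

    def opts(name) -> dict:
        val = stages.get(name)
        return val if isinstance(val, dict) else {}

    if stage_enabled("score"):
        target = trees[0] if trees else true_tree
        if target is None:
            log.error("score stage needs an input tree")
            failed = True
        else:
            t0 = time.time()
            report_len = tree_length(target, matrix, weights)
            manifest.stages["score"] = {
                "total": report_len.total,
                "seconds": round(time.time() - t0, 3),
            }
            log.info("score: %.4f weighted steps", report_len.total)

    if stage_enabled("search") and not failed:
        t0 = time.time()
        res = heuristic_search(
            matrix,
            weights,
            constraint=constraint,
            n_replicates=int(opts("search").get("replicates", 10)),
            seed=seed,
        )
        best_trees, best_score = res.best_trees, res.best_score
        with open(outdir / "trees.nwk", "w") as fh:
            for t in best_trees:
                fh.write(t.to_newick() + "\n")
        manifest.stages["search"] = {
            "best_score": best_score,
            "n_trees": len(best_trees),
            "replicates_hitting_best": res.replicates_hitting_best,
            "seconds": round(time.time() - t0, 3),
        }
        log.info("search: best %.4f (%d trees)", best_score, len(best_trees))

    if stage_enabled("consensus"):
        source = best_trees or trees
        if not source:
            log.error("consensus stage needs search results or input trees")
        else:
            cons = strict_consensus(source)
            write_newick(cons, outdir / "consensus.nwk")
            manifest.stages["consensus"] = {"newick": cons.to_newick()}

    if stage_enabled("support"):
        if best_score is None:
            log.error("support stage needs the search stage")
        else:
            sup_cfg = opts("support")
            rows = []
            fossils = set(sup_cfg.get("fossils", []))
            extant = [t for t in matrix.taxa if t not in fossils]
            backbone = (best_trees[0].restrict(extant)
                        if fossils else best_trees[0])
            clades = sup_cfg.get("clades")
            if not clades:
                clades = [
                    sorted(c)
                    for c in best_trees[0].clades()
                    if 2 <= len(c) <= matrix.n_taxa - 2
                ]
            for clade in clades:
                bs = bremer_support(
                    matrix, weights, best_score, clade, seed=seed
                )
                row = {"clade": ",".join(sorted(clade)), "bs": format_bs(bs.bs)}
                if fossils:
                    extant_clade = frozenset(clade) - fossils
                    if len(extant_clade) >= 2:
                        dd = double_decay_support(
                            matrix, weights, backbone, extant_clade, fossils,
                            seed=seed, best_score=best_score,
                        )
                        row["ddbs"] = format_ddbs(dd.ddbs)
                rows.append(row)
            with open(outdir / "support.tsv", "w") as fh:
                fh.write("clade\tbs\tddbs\n")
                for r in rows:
                    fh.write(
                        f"{r['clade']}\t{r['bs']}\t{r.get('ddbs', '')}\n"
                    )
            manifest.stages["support"] = {"table": rows}

    if stage_enabled("stratfit"):
        target = (best_trees or trees or ([true_tree] if true_tree else []))
        if not target or ages is None:
            log.error("stratfit stage needs a tree and an age table")
        else:
            fit = stratfit(
                target[0],
                ages,
                n_perm=int(opts("stratfit").get("permutations", 999)),
                seed=seed,
            )
            manifest.stages["stratfit"] = {
                "mig": fit.mig,
                "g_min": fit.g_min,
                "g_max": fit.g_max,
                "msm_star": fit.msm_star,
                "ger": fit.ger,
                "p_value": fit.p_value,
            }
            with open(outdir / "ghosts.tsv", "w") as fh:
                fh.write("branch\tghost_ma\n")
                for branch, dur in fit.per_branch_ghost.items():
                    fh.write(f"{branch}\t{dur:g}\n")

    if stage_enabled("toptest"):
        t_cfg = opts("toptest")
        try:
            tree_a = read_newick(t_cfg["tree_a"])
            tree_b = read_newick(t_cfg["tree_b"])
        except KeyError as exc:
            raise MatrixError(f"toptest stage needs key {exc}") from exc
        diffs = per_character_diffs(matrix, weights, tree_a, tree_b)
        stat, p_t = templeton_test(diffs)
        p_w = winning_sites_test(diffs)
        manifest.stages["toptest"] = {
            "n_nonzero": diffs.n_nonzero,
            "templeton_statistic": stat,
            "templeton_p": p_t,
            "winning_sites_p": p_w,
        }

    if stage_enabled("charmap"):
        c_cfg = opts("charmap")
        target = (best_trees or trees or ([true_tree] if true_tree else []))
        if not target:
            log.error("charmap stage needs a tree")
        else:
            tree = target[0]
            chars = c_cfg.get("chars", [])
            out_rows = []
            for j in chars:
                column = matrix.column(int(j))
                spec = matrix.specs[int(j)]
                rec = deltran(tree, column, spec)
                for node, a, b in state_changes(tree, rec):
                    where = node.label or ",".join(sorted(tree.tipset(node)))
                    out_rows.append({"char": j, "branch": where, "from": a, "to": b})
            calls = []
            for pair in c_cfg.get("pairs", []):
                x, y = pair
                for j in chars:
                    try:
                        call = classify_pair_homology(
                            tree, matrix.column(int(j)), matrix.specs[int(j)], x, y
                        )
                        calls.append(
                            {"pair": f"{x}/{y}", "char": j, "call": call.call}
                        )
                    except MatrixError:
                        calls.append({"pair": f"{x}/{y}", "char": j, "call": "-"})
            manifest.stages["charmap"] = {"changes": out_rows, "homology": calls}

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
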