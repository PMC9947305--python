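"""End-to-end orchestration: simulate/load → patrilines → heritability →
haplotypes → association, with a consolidated, reproducible report.

A single top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`` so no stage's
random stream depends on another stage having run.  Given the same config
and seed the report regenerates byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc_tree, haplotypes, herit_stats, io_formats, patrilines, simulate

log = logging.getLogger("beetol")

__all__ = ["run_pipeline", "validate_config", "stage_seed"]

_STAGES = {"simulate": 0, "errors": 1, "monte_carlo": 2, "cds": 3, "tree": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the top-level seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(cfg: dict) -> dict:
    """Check config shape before any stage runs; fill defaults."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if not has_sim and not has_inputs:
        raise ValueError("config needs a 'simulate' block or an 'inputs' block")
    if has_inputs:
        inputs = cfg["inputs"]
        for key in ("genotypes", "phenotypes"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r} path")
    out = dict(cfg)
    out.setdefault("seed", 0)
    out.setdefault("patrilines", {})
    out.setdefault("herit", {})
    out.setdefault("tree", {})
    return out


def _tree_to_dict(node: assoc_tree.TreeNode) -> dict:
    d: dict[str, Any] = {
        "n": node.n,
        "n_survived": node.n_survived,
        "p_survive": round(node.p_survive, 6),
        "prediction": node.prediction,
    }
    if not node.is_leaf:
        d["split"] = {
            "gene": node.split.gene,
            "left": sorted(node.split.left_labels),
            "right": sorted(node.split.right_labels),
        }
        d["left"] = _tree_to_dict(node.left)
        d["right"] = _tree_to_dict(node.right)
    return d


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run every stage, write artifacts under ``out_dir``, return the report.

    Raises on stage failure (partial artifacts are retained on disk).
    """
    if not isinstance(config, dict):
        config = io_formats.load_yaml(config)
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"seed": seed, "config": cfg, "stages": {}, "qc": {}}

    # ------------------------------------------------------------------ input
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs["seed"] = stage_seed(seed, "simulate")
        sim_cfg = simulate.SimConfig(**sim_kwargs)
        sims = simulate.simulate_colonies(sim_cfg)
        workers = [w for _, _, ws in sims for w in ws]
        if sim_cfg.genotyping_error_rate > 0:
            err_rng = np.random.default_rng(stage_seed(seed, "errors"))
            observed = simulate.apply_genotyping_errors(
                workers, sim_cfg.genotyping_error_rate, err_rng
            )
        else:
            observed = workers
        gt = simulate.genotype_table(observed)
        pheno = simulate.phenotype_frame(workers)
        truth = simulate.truth_frame(workers)
        io_formats.write_genotypes(gt, out_dir / "genotypes.csv")
        io_formats.write_phenotypes(pheno, out_dir / "phenotypes.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
        with open(out_dir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        report["stages"]["simulate"] = {
            "n_workers": len(workers),
            "colonies": sorted({w.colony for w in workers}),
            "files": ["genotypes.csv", "phenotypes.csv", "truth.csv"],
        }
    else:
        gt = io_formats.read_genotypes(cfg["inputs"]["genotypes"])
        pheno = io_formats.read_phenotypes(cfg["inputs"]["phenotypes"])
        truth = None
        report["stages"]["input"] = {
            "n_workers": len(gt.workers),
            "colonies": sorted(gt.data["colony"].unique()),
        }

    # --------------------------------------------------------------------- QC
    n_before = len(pheno)
    pheno_kept = io_formats.filter_phenotypes(
        pheno, cfg.get("herit", {}).get("min_consumed", 0.90)
    )
    report["qc"]["excluded_low_consumption"] = n_before - len(pheno_kept)
    if (pheno_kept["dose_group"] == "control").any():
        check = io_formats.check_control_mortality(pheno_kept)
        report["qc"]["control_mortality"] = round(check.mortality, 4)
        report["qc"]["control_mortality_pass"] = bool(check.passed)
    lethal = pheno_kept[
        (pheno_kept["dose_group"] == "lethal") & pheno_kept["survived"].notna()
    ].copy()
    report["qc"]["n_lethal_analyzed"] = len(lethal)

    # -------------------------------------------------------------- patrilines
    pat_cfg = cfg["patrilines"]
    colonies = sorted(gt.data["colony"].unique())
    assign_frames = []
    pat_stage: dict[str, Any] = {}
    for colony in colonies:
        queen, grouping, haps = patrilines.assign_patrilines(
            gt,
            colony,
            max_mismatch_fraction=pat_cfg.get("max_mismatch_fraction", 0.05),
            min_resolved_loci=pat_cfg.get("min_resolved_loci", 6),
        )
        frame = grouping.to_frame()
        frame["patriline"] = frame["patriline"].map(
            lambda p: f"{colony}:{p}" if p else ""
        )
        assign_frames.append(frame)
        pat_stage[colony] = {
            "n_patrilines": grouping.n_patrilines,
            "n_unassigned": len(grouping.unassigned),
            "queen": {l: list(p) if p else None for l, p in queen.pairs.items()},
        }
    assignment = pd.concat(assign_frames, ignore_index=True)
    assignment.to_csv(out_dir / "patrilines.csv", index=False)
    report["stages"]["patrilines"] = pat_stage
    report["qc"]["unassigned_workers"] = int((assignment["patriline"] == "").sum())

    # ------------------------------------------------------------ heritability
    herit_cfg = cfg["herit"]
    bees = lethal.merge(assignment, on="worker_id")
    bees = bees[bees["patriline"] != ""]
    mc_B = herit_cfg.get("monte_carlo_B", 5000)
    mc_rng = np.random.default_rng(stage_seed(seed, "monte_carlo"))
    herit_rep: dict[str, Any] = {}

    mortality = {
        c: {
            "dead": int((~bees[bees["colony"] == c]["survived"]).sum()),
            "n": int(len(bees[bees["colony"] == c])),
        }
        for c in colonies
    }
    herit_rep["colony_mortality"] = mortality
    if len(colonies) >= 2:
        tab = np.array(
            [[mortality[c]["dead"], mortality[c]["n"] - mortality[c]["dead"]] for c in colonies]
        )
        res = herit_stats.chisq_test(tab, yates=True, monte_carlo_B=mc_B, seed=mc_rng)
        herit_rep["colony_chisq"] = {
            "statistic": round(res.statistic, 4),
            "df": res.df,
            "p": round(res.pvalue, 6),
            "monte_carlo_p": round(res.monte_carlo_p, 6),
        }
    for colony in colonies:
        sub = bees[bees["colony"] == colony]
        tab = pd.crosstab(sub["patriline"], sub["survived"]).to_numpy()
        if tab.shape[0] >= 2 and tab.shape[1] == 2:
            res = herit_stats.chisq_test(tab, yates=False, monte_carlo_B=mc_B, seed=mc_rng)
            herit_rep.setdefault("patriline_chisq", {})[colony] = {
                "statistic": round(res.statistic, 4),
                "df": res.df,
                "p": round(res.pvalue, 6),
                "monte_carlo_p": round(res.monte_carlo_p, 6),
            }

    def _partition(frame: pd.DataFrame) -> dict:
        part = herit_stats.partition_deviance(
            frame["survived"].astype(float).to_numpy(),
            frame["colony"],
            frame["patriline"],
            adjusted=True,
        )
        return {
            "share_colony": round(part.share_colony, 4),
            "share_patriline": round(part.share_patriline, 4),
            "share_residual": round(part.share_residual, 4),
            "h2": round(part.h2, 4),
            "h2_raw": round(part.h2_raw, 4),
            "h2_adjusted": round(part.adjusted["h2"], 4),
            "n": part.n,
        }

    herit_rep["partition_all"] = _partition(bees)
    min_n = herit_cfg.get("min_workers", 5)
    bees_min = herit_stats.filter_min_workers(
        assignment, lethal, min_n=min_n
    )
    if not bees_min.empty:
        herit_rep[f"partition_min{min_n}"] = _partition(bees_min)
    report["stages"]["herit"] = herit_rep
    with open(out_dir / "herit.json", "w") as fh:
        json.dump(herit_rep, fh, indent=2, sort_keys=True)

    # --------------------------------------------------------------- haplotypes
    genes = list(simulate.GENES)
    if truth is not None:
        cds_seed = stage_seed(seed, "cds")
        refs = {
            g: simulate.reference_for_profiles(
                520, simulate.DEFAULT_GENE_PROFILES[g], seed=cds_seed + i
            )
            for i, g in enumerate(genes)
        }
        selected = bees_min if not bees_min.empty else bees
        sel_truth = truth[truth["worker_id"].isin(selected["worker_id"])]
        profiles_by_worker: dict[str, dict[str, haplotypes.ChangeProfile]] = {}
        label_map = {}
        for gene in genes:
            cds_set = simulate.simulate_cds_set(
                refs[gene], simulate.DEFAULT_GENE_PROFILES[gene]
            )
            io_formats.write_fasta(
                {f"{gene}|{lab}": s for lab, s in cds_set.items()},
                out_dir / f"{gene}.fasta",
            )
            called = {
                lab: haplotypes.call_changes(s, refs[gene], gene=gene)
                for lab, s in cds_set.items()
            }
            label_map[gene] = {prof.key: lab for lab, prof in called.items()}
            for _, row in sel_truth.iterrows():
                profiles_by_worker.setdefault(row["worker_id"], {})[gene] = called[
                    row[gene]
                ]
        catalog = haplotypes.build_catalog(
            profiles_by_worker, genes=genes, label_map=label_map
        )
        report["stages"]["haplotypes"] = {
            "n_sequences": len(profiles_by_worker),
            "n_combinations": catalog.n_combinations,
            "labels_per_gene": {
                g: sorted({v[g] for v in catalog.sample_labels.values()})
                for g in genes
            },
        }

        # ------------------------------------------------------------ association
        assoc = selected.merge(
            pd.DataFrame(
                [
                    {"worker_id": w, **labs}
                    for w, labs in catalog.sample_labels.items()
                ]
            ),
            on="worker_id",
        )
        assoc["survived"] = assoc["survived"].astype(float)
        agg = (
            assoc.groupby(["colony", "patriline"] + genes, as_index=False)
            .agg(survived_n=("survived", "sum"), tested_n=("survived", "count"))
        )
        glm_rows = assoc_tree.haplotype_glm(agg, genes)
        report["stages"]["assoc_glm"] = [
            {
                "term": r.term,
                "lr_chi2": round(r.lr_chi2, 4),
                "df": r.df,
                "p": round(r.pvalue, 6),
                "flagged": r.flagged,
            }
            for r in glm_rows
        ]

        tree_cfg = cfg["tree"]
        grown = assoc_tree.grow_tree(
            assoc,
            genes,
            min_split=tree_cfg.get("min_split", 20),
            min_bucket=tree_cfg.get("min_bucket", 7),
        )
        pruned = assoc_tree.prune_tree(
            grown,
            assoc,
            folds=tree_cfg.get("folds", 10),
            cp_floor=tree_cfg.get("cp", 0.01),
            seed=np.random.default_rng(stage_seed(seed, "tree")),
        )
        tree_dict = {
            "n_splits": pruned.n_splits,
            "chosen_cp": pruned.chosen_cp,
            "tree": _tree_to_dict(pruned.root),
            "cp_table": pruned.cp_table.round(6).to_dict("records"),
        }
        with open(out_dir / "tree.json", "w") as fh:
            json.dump(tree_dict, fh, indent=2, sort_keys=True)
        (out_dir / "tree.txt").write_text(assoc_tree.render_tree(pruned) + "\n")
        report["stages"]["tree"] = {
            "n_splits": pruned.n_splits,
            "chosen_cp": pruned.chosen_cp,
            "root_split": (
                {
                    "gene": pruned.root.split.gene,
                    "left": sorted(pruned.root.split.left_labels),
                }
                if pruned.root.split
                else None
            ),
        }
    else:
        report["stages"]["haplotypes"] = {"skipped": "no sequence inputs"}

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    _write_markdown(report, out_dir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# beetol run report", "", f"seed: {report['seed']}", ""]
    herit = report["stages"].get("herit", {})
    if "colony_chisq" in herit:
        c = herit["colony_chisq"]
        lines.append(
            f"- colony mortality difference: χ² = {c['statistic']}, df = {c['df']}, p = {c['p']}"
        )
    for key in sorted(herit):
        if key.startswith("partition"):
            p = herit[key]
            lines.append(
                f"- {key}: shares colony/patriline/residual = "
                f"{p['share_colony']}/{p['share_patriline']}/{p['share_residual']}, "
                f"H² = {p['h2']} (n = {p['n']})"
            )
    if "assoc_glm" in report["stages"]:
        for r in report["stages"]["assoc_glm"]:
            lines.append(
                f"- {r['term']}: LR χ² = {r['lr_chi2']}, df = {r['df']}, p = {r['p']}"
            )
    tree = report["stages"].get("tree")
    if tree and tree.get("root_split"):
        lines.append(
            f"- pruned tree: {tree['n_splits']} splits, root on {tree['root_split']['gene']} "
            f"(low-survival side: {tree['root_split']['left']})"
        )
    path.write_text("\n".join(lines) + "\n")
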