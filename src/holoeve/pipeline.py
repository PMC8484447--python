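"""End-to-end pipeline chaining the analysis stages on disk.

Stages run in a fixed order (simulate -> eve -> eve_r -> everest -> qmf ->
redundancy -> physio); only the requested subset executes.  Every output
TSV carries a provenance header (package version, seed, config hash) and
a ``manifest.json`` records per-stage status, so a failed run leaves its
partial outputs inspectable.  All randomness flows from the single config
seed.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import pandas as pd

from . import __version__, comparative, eve, metabolism, photophysiology, variants
from .eve import SampleLayout
from .io import RunConfig, read_expression, read_newick, read_table, write_table
from .phylogeny import Phylogeny
from .simulate import (
    SimulationConfig,
    SpeciesPhysioEffect,
    make_tree,
    simulate_annotation,
    simulate_expression,
    simulate_physiology,
)

__all__ = ["run_pipeline", "PipelineError"]

_STAGE_ORDER = ("simulate", "eve", "eve_r", "everest", "qmf", "redundancy",
                "physio")


class PipelineError(RuntimeError):
    """A stage failed; the manifest marks which."""


def _provenance(config: RunConfig) -> dict:
    return {"holoeve_version": __version__, "seed": config.seed,
            "config_hash": config.config_hash()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, returning the manifest dict.

    Raises :class:`PipelineError` after writing the manifest if any stage
    fails; earlier stages' outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    stages = [s for s in _STAGE_ORDER if s in config.stages]
    manifest: dict = {"stages": {}, **prov}

    state: dict = {}
    failed = None
    for stage in stages:
        try:
            _run_stage(stage, config, outdir, prov, state)
            manifest["stages"][stage] = "ok"
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            failed = (stage, exc, traceback.format_exc())
            break
    for stage in stages:
        manifest["stages"].setdefault(stage, "not_run")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if failed:
        raise PipelineError(
            f"stage {failed[0]!r} failed: {failed[1]}\n{failed[2]}"
        )
    return manifest


def _load_tree(config: RunConfig, outdir: Path, state: dict) -> Phylogeny:
    if "tree" in state:
        return state["tree"]
    if config.tree:
        tree = read_newick(config.tree)
    else:
        sim_tree = outdir / "tree.nwk"
        if sim_tree.exists():
            tree = read_newick(sim_tree)
        else:
            raise FileNotFoundError("no tree: set 'tree' or run simulate")
    state["tree"] = tree
    return tree


def _load_expression(config: RunConfig, outdir: Path, state: dict):
    if "expr" in state:
        return state["expr"], state["meta"]
    if config.expression and config.metadata:
        expr, meta = read_expression(config.expression, config.metadata)
    else:
        e, m = outdir / "expression.tsv", outdir / "metadata.tsv"
        if not e.exists():
            raise FileNotFoundError(
                "no expression inputs: set paths or run simulate"
            )
        expr, meta = read_expression(e, m)
    state["expr"], state["meta"] = expr, meta
    return expr, meta


def _load_tpm_annotation(config: RunConfig, outdir: Path, state: dict):
    if "tpm" in state:
        return state["tpm"], state["annotation"]
    if config.tpm and config.annotation:
        tpm = read_table(config.tpm, index_col=0)
        ann = read_table(config.annotation)
    else:
        t, a = outdir / "tpm.tsv", outdir / "annotation.tsv"
        if not t.exists():
            raise FileNotFoundError(
                "no TPM/annotation inputs: set paths or run simulate"
            )
        tpm = read_table(t, index_col=0)
        ann = read_table(a)
    ann = ann.fillna({"pathway": "", "ec": "", "ko": ""})
    state["tpm"], state["annotation"] = tpm, ann
    return tpm, ann


def _run_stage(
    stage: str, config: RunConfig, outdir: Path, prov: dict, state: dict
) -> None:
    if stage == "simulate":
        sim = SimulationConfig(
            n_genes=config.n_genes,
            n_replicates_per_condition=config.n_replicates_per_condition,
            gene_class_proportions=dict(config.gene_class_proportions),
            seed=config.seed,
        )
        tree = make_tree(sim.tree_spec)
        expr, meta, truth = simulate_expression(sim, tree)
        tree.write(outdir / "tree.nwk")
        write_table(expr, outdir / "expression.tsv", provenance=prov)
        write_table(meta, outdir / "metadata.tsv", index=False, provenance=prov)
        write_table(truth, outdir / "ground_truth.tsv", provenance=prov)
        ann, tpm = simulate_annotation(
            n_transcripts_per_member=40,
            pathway_catalog=[f"map{i:05d}" for i in range(1, 7)],
            ec_catalog=[f"1.1.1.{i}" for i in range(1, 13)],
            overlap_design={
                f"1.1.1.{i}": ("host", "symbiont", "bacteria")[: 1 + i % 3]
                for i in range(1, 13)
            },
            seed=config.seed + 1,
        )
        write_table(ann, outdir / "annotation.tsv", index=False, provenance=prov)
        write_table(tpm, outdir / "tpm.tsv", provenance=prov)
        physio = simulate_physiology(
            seed=config.seed + 2,
            effects={
                sp: SpeciesPhysioEffect(
                    density_shift_frac=shift, fv_fm_shift=-0.1 * abs(shift)
                )
                for sp, shift in zip(tree.tips, (-0.2, -0.6, -0.4))
            },
        )
        write_table(physio, outdir / "physiology.tsv", index=False,
                    provenance=prov)
        state.update({"tree": tree, "expr": expr, "meta": meta,
                      "tpm": tpm, "annotation": ann, "physio": physio})
        return

    if stage == "eve":
        tree = _load_tree(config, outdir, state)
        expr, meta = _load_expression(config, outdir, state)
        ctrl = meta[meta["condition"] == "control"]
        layout = SampleLayout.from_metadata(ctrl)
        res = eve.divergence_test(
            expr[list(ctrl["sample_id"])], tree, layout,
            p_threshold=config.p_threshold,
        )
        write_table(res, outdir / "eve_results.tsv", provenance=prov)
        state["eve"] = res
        return

    if stage == "eve_r":
        tree = _load_tree(config, outdir, state)
        expr, meta = _load_expression(config, outdir, state)
        res = variants.run_eve_r(
            expr, meta, tree, p_div=config.p_div, p_change=config.p_change
        )
        write_table(res, outdir / "eve_r_candidates.tsv", provenance=prov)
        return

    if stage == "everest":
        tree = _load_tree(config, outdir, state)
        expr, meta = _load_expression(config, outdir, state)
        res = variants.run_everest(
            expr, meta, tree, sign=config.everest_sign,
            pairing=config.everest_pairing, p_threshold=config.p_threshold,
        )
        write_table(
            res, outdir / "everest_results.tsv",
            provenance={**prov, "sign": config.everest_sign,
                        "pairing": config.everest_pairing},
        )
        return

    if stage == "qmf":
        tpm, ann = _load_tpm_annotation(config, outdir, state)
        kept = metabolism.filter_expressed(
            tpm, min_tpm=config.min_tpm, min_samples=config.min_samples
        )
        qmf = metabolism.compute_qmf(
            tpm, ann, statistic=config.qmf_statistic,
            denominator=config.qmf_denominator, kept=kept,
        )
        qprov = {**prov, "statistic": config.qmf_statistic,
                 "denominator": config.qmf_denominator}
        write_table(qmf.proportions, outdir / "qmf.tsv", index=False,
                    provenance=qprov)
        write_table(qmf.fold_change, outdir / "qmf_foldchange.tsv",
                    index=False, provenance=qprov)
        shares, member_shares = metabolism.capability_shares(ann, kept)
        write_table(shares, outdir / "capabilities.tsv", index=False,
                    provenance=prov)
        state["kept"] = kept
        return

    if stage == "redundancy":
        tpm, ann = _load_tpm_annotation(config, outdir, state)
        part = metabolism.classify_reactions(ann)
        tab = part.table.copy()
        if not tab.empty:
            tab["carriers"] = [";".join(c) for c in tab["carriers"]]
        write_table(tab, outdir / "reaction_partition.tsv", index=False,
                    provenance=prov)
        catexp = metabolism.category_expression(tpm, part, ann)
        write_table(catexp, outdir / "category_expression.tsv", index=False,
                    provenance=prov)
        return

    if stage == "physio":
        if config.physiology:
            physio = read_table(config.physiology)
        elif "physio" in state:
            physio = state["physio"]
        else:
            p = outdir / "physiology.tsv"
            if not p.exists():
                raise FileNotFoundError(
                    "no physiology input: set path or run simulate"
                )
            physio = read_table(p)
        traits = photophysiology.annotate_physiology(physio)
        write_table(traits, outdir / "physio_traits.tsv", index=False,
                    provenance=prov)
        return

    raise ValueError(f"unknown stage {stage!r}")
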