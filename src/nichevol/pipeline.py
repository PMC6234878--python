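"""End-to-end pipeline orchestration: configuration, stages, manifest.

A :class:`RunConfig` names the inputs (tree set, optional summary tree,
character table), the stages to run and their parameters, and a master seed.
:func:`run_pipeline` executes the enabled stages in dependency order
(traits → signal → asr/simmap → deadend → sse), writes one or more TSV/JSON
artifacts per stage into the output directory — every file carrying the
package version and master seed in a header comment — and finishes with a
checksum manifest.  A stage failure halts its dependents only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, consensus, deadend, mk, signal, simmap, sse, synth, traits, tree as treeio

log = logging.getLogger("nichevol")

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]

STAGES = ("signal", "asr", "simmap", "deadend", "sse")


@dataclass
class RunConfig:
    trees_path: str = ""
    mcc_path: str = ""  # summary tree; defaults to the first posterior tree
    characters_path: str = ""
    character: str = "ps"  # which character drives multi-state stages
    outdir: str = "nichevol_out"
    seed: int = 0
    stages: tuple = STAGES
    # stage parameters
    n_trees: int = 0  # 0 = all trees in the set
    n_perm: int = 199
    lambda_scenarios: tuple = signal.DEFAULT_LAMBDA_SCENARIOS
    n_anchors: int = 19
    n_maps_per_tree: int = 100
    rank_window: int = 5
    mk_restarts: int = 2
    sse_steps: int = 1000
    sse_trees: int = 10  # chains are short per tree; pooled across this many

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        for p in (self.trees_path, self.characters_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _write_tsv(df: pd.DataFrame, path: Path, seed):
    with open(path, "w") as fh:
        fh.write(f"# nichevol {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _default_anchors(base: treeio.PhyloTree, n_anchors: int):
    """Anchor the largest internal clades of the summary tree (root included)."""
    nodes = sorted(
        range(base.n_tips, base.n_nodes),
        key=lambda n: -len(base.clade_tips(n)),
    )
    anchors = []
    for rank, node in enumerate(nodes[:n_anchors]):
        anchors.append(treeio.NodeAnchor(f"node_{rank + 1}",
                                         base.clade_tips(node)))
    return anchors


def simulate_inputs(outdir, seed: int = 0, n_tips: int = 100,
                    n_trees: int = 100) -> dict:
    """Generate and write the synthetic demo inputs consumed by the pipeline."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    demo = synth.demo_dataset(seed=seed, n_tips=n_tips, n_trees=n_trees)
    treeio.write_tree_set(demo["trees"], out / "trees.nwk")
    treeio.write_tree_set([demo["base_tree"]], out / "mcc.nwk")
    traits.write_character_table(out / "characters.csv", ps=demo["ps"],
                                 gs=demo["gs"])
    demo["occurrences"].to_csv(out / "occurrences.csv")
    (out / "sim_config.json").write_text(demo["config"].to_json())
    return {
        "trees_path": str(out / "trees.nwk"),
        "mcc_path": str(out / "mcc.nwk"),
        "characters_path": str(out / "characters.csv"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    trees = treeio.read_tree_set(config.trees_path)
    if config.n_trees:
        trees = treeio.TreeSet(trees.trees[: config.n_trees],
                               provenance=trees.provenance)
    base = (treeio.read_tree(config.mcc_path) if config.mcc_path
            else trees[0])
    ps, gs = traits.read_character_table(config.characters_path)
    data = ps if config.character.lower() == "ps" else gs
    if data is None:
        raise ValueError(f"character {config.character!r} missing from table")
    status = {}
    written = []

    def stage(name):
        return name in config.stages and status.get(name) is not False

    if stage("signal"):
        try:
            lam_res = signal.lambda_signal_test(
                trees, data, scenarios=config.lambda_scenarios,
                n_perm=config.n_perm, seed=int(rng.integers(2**31)))
            dist_res = signal.tiptip_distance_test(
                trees, data, n_perm=config.n_perm,
                seed=int(rng.integers(2**31)))
            rows = [
                {"tree_index": r.tree_index, "label": r.label,
                 "statistic": r.statistic, "p": r.p, "n_perm": r.n_perm,
                 "untestable": r.untestable,
                 "n_tips_in_state": r.n_tips_in_state}
                for r in lam_res + dist_res
            ]
            _write_tsv(pd.DataFrame(rows), out / "signal.tsv", config.seed)
            written.append("signal.tsv")
            status["signal"] = True
        except Exception as e:  # pragma: no cover - defensive
            log.error("signal stage failed: %s", e)
            status["signal"] = False

    anchors = _default_anchors(base, config.n_anchors)
    if stage("asr"):
        try:
            grid = consensus.default_grid(data.k)
            report = consensus.run_ensemble(
                trees, data, grid, anchors, seed=int(rng.integers(2**31)),
                n_restarts=config.mk_restarts)
            _write_tsv(pd.DataFrame(report.to_rows()), out / "asr_votes.tsv",
                       config.seed)
            summary = [consensus.summarize_node(report, a.name)
                       for a in anchors]
            rows = [{"node": s["node"], "winner": s["winner"],
                     "margin": s["margin"], "tie": s["tie"],
                     "monophyly_fraction": s["monophyly_fraction"],
                     "votes": json.dumps(s["votes"])} for s in summary]
            _write_tsv(pd.DataFrame(rows), out / "asr_summary.tsv", config.seed)
            written += ["asr_votes.tsv", "asr_summary.tsv"]
            status["asr"] = True
        except Exception as e:
            log.error("asr stage failed: %s", e)
            status["asr"] = False

    if stage("simmap"):
        try:
            all_maps = []
            for ti, t in enumerate(trees):
                fit = mk.fit_mk(t, data, "ARD",
                                n_restarts=config.mk_restarts,
                                seed=int(rng.integers(2**31)))
                if not fit.converged:
                    continue
                all_maps += simmap.sample_maps(
                    t, data, fit.q_matrix, n_maps=config.n_maps_per_tree,
                    seed=int(rng.integers(2**31)), tree_index=ti)
            summary = simmap.count_transitions(all_maps)
            rows = []
            k = data.k
            for i in range(k):
                for j in range(k):
                    if i != j:
                        rows.append({
                            "from_state": data.states[i],
                            "to_state": data.states[j],
                            "cumulative": int(summary.cumulative[i, j]),
                            "mean_per_map": float(summary.mean[i, j]),
                        })
            _write_tsv(pd.DataFrame(rows), out / "transitions.tsv", config.seed)
            written.append("transitions.tsv")
            status["simmap"] = True
        except Exception as e:
            log.error("simmap stage failed: %s", e)
            status["simmap"] = False

    if stage("deadend"):
        try:
            table = deadend.rank_models(trees, data,
                                        seed=int(rng.integers(2**31)),
                                        n_restarts=1)
            _write_tsv(table.to_frame(), out / "deadend_ranks.tsv", config.seed)
            top = deadend.top_models(table, window=config.rank_window)
            _write_tsv(pd.DataFrame(top, columns=["model", "trees_in_window"]),
                       out / "deadend_top.tsv", config.seed)
            written += ["deadend_ranks.tsv", "deadend_top.tsv"]
            status["deadend"] = True
        except Exception as e:
            log.error("deadend stage failed: %s", e)
            status["deadend"] = False

    if stage("sse"):
        try:
            samples = []
            for ti, t in enumerate(trees.trees[: config.sse_trees]):
                samples.append(sse.musse_mcmc(
                    t, data, n_steps=config.sse_steps,
                    seed=int(rng.integers(2**31)), tree_index=ti))
            dens = sse.diversification_density(samples, states=data.states)
            rows = [{"state": s, "mean_r": d["mean"], "median_r": d["median"],
                     "q025": d["q025"], "q975": d["q975"]}
                    for s, d in dens.items()]
            _write_tsv(pd.DataFrame(rows), out / "sse_density.tsv", config.seed)
            pairs = []
            names = list(dens)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    U, p = sse.compare_rates(dens[names[i]]["draws"],
                                             dens[names[j]]["draws"])
                    pairs.append({"state_i": names[i], "state_j": names[j],
                                  "U": U, "p": p})
            _write_tsv(pd.DataFrame(pairs), out / "sse_pairs.tsv", config.seed)
            written += ["sse_density.tsv", "sse_pairs.tsv"]
            status["sse"] = True
        except Exception as e:
            log.error("sse stage failed: %s", e)
            status["sse"] = False

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": status,
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
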