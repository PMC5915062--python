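"""End-to-end orchestration from one YAML config.

Stages run in order diff → select → network → cluster (plus prm and
transcriptome when configured), each writing TSV results into the output
directory; a ``manifest.json`` records version, seeds, parameters and the
row count of every output.  Config validation happens before any compute,
and a failing stage removes the partial outputs it produced.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, differential, enrichment, io, selection
from .model import ContrastSpec, SelectionParams
from .simulate import SimulationConfig, simulate_study, simulate_gene_sets


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _validate(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("config must set a seed")
    has_inputs = "inputs" in config
    has_sim = "simulate" in config
    if has_inputs == has_sim:
        raise ConfigError("config must set exactly one of 'inputs' or 'simulate'")
    if has_inputs:
        inp = config["inputs"]
        for key in ("matrix", "annotations"):
            if key not in inp:
                raise ConfigError(f"inputs must name a {key} file")
            if not Path(inp[key]).exists():
                raise ConfigError(f"input file not found: {inp[key]}")
    net = config.get("network")
    if net is not None and not has_sim:
        gmt = net.get("gmt")
        if not gmt:
            raise ConfigError("network stage enabled but no gmt path given")
        if not Path(gmt).exists():
            raise ConfigError(f"gmt file not found: {gmt}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the configured pipeline; returns the manifest dict."""
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    _validate(config)

    out_dir = Path(out_dir)
    fresh = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        io.write_table(df, path, index=index)
        written.append(path)
        manifest["outputs"][name] = int(len(df))

    seed = int(config["seed"])
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {},
        "outputs": {},
    }

    try:
        # ------------------------------------------------------------ inputs
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            sim_config = SimulationConfig(**sim_kwargs)
            matrix, annotations, truth = simulate_study(sim_config)
            manifest["parameters"]["simulate"] = {
                k: v for k, v in vars(sim_config).items()
            }
            io.write_count_matrix(matrix, out_dir / "matrix.tsv")
            written.append(out_dir / "matrix.tsv")
            io.write_annotations(annotations, out_dir / "annotations.tsv")
            written.append(out_dir / "annotations.tsv")
            emit(pd.DataFrame({"protein_id": list(truth.classes),
                               "class": list(truth.classes.values())}),
                 "truth.tsv")
        else:
            matrix = io.read_count_matrix(config["inputs"]["matrix"])
            annotations = io.read_annotations(config["inputs"]["annotations"])
            truth = None

        # -------------------------------------------------------------- diff
        ccfg = config.get("contrast", {})
        contrast = ContrastSpec(
            group_a=ccfg.get("group_a", "early_cancer"),
            group_b=ccfg.get("group_b", "healthy_epithelium"),
            pseudocount=float(ccfg.get("pseudocount", 0.125)),
            test_method=ccfg.get("test", "welch_log"),
        )
        manifest["parameters"]["contrast"] = vars(contrast)
        try:
            volcano = differential.volcano_table(matrix, annotations, contrast)
        except Exception as exc:  # noqa: BLE001
            raise StageError("diff", str(exc)) from exc
        emit(volcano, "volcano.tsv")

        # ------------------------------------------------------------ select
        scfg = config.get("selection", {}) or {}
        params = SelectionParams(
            target_group=contrast.group_a,
            min_present_target=int(scfg.get("min_present_target", 7)),
            p_max=float(scfg.get("p_max", 0.05)),
            alpha=float(scfg.get("alpha", 0.05)),
            q=float(scfg.get("q", 0.05)),
        )
        manifest["parameters"]["selection"] = vars(params)
        p = volcano.set_index("protein_id")["p_value"]
        fc = volcano.set_index("protein_id")["log2_fc"]
        try:
            sel = selection.selection_table(matrix, annotations, params, p, fc)
        except Exception as exc:  # noqa: BLE001
            raise StageError("select", str(exc)) from exc
        manifest["parameters"]["bonferroni_threshold"] = sel.attrs[
            "bonferroni_threshold"]
        emit(sel, "selection.tsv")

        # ----------------------------------------------------------- network
        ncfg = config.get("network")
        if ncfg is not None:
            try:
                if "simulate" in config:
                    planted = (truth.proteins_of_class("fc_up")[:14]
                               if truth else [])
                    collection = simulate_gene_sets(
                        int(ncfg.get("n_sets", 10)),
                        int(ncfg.get("set_size", 35)),
                        matrix.protein_ids,
                        planted_members=planted,
                        seed=seed + 1,
                    )
                else:
                    collection = io.read_gmt(ncfg["gmt"])
                    collection.background = matrix.protein_ids
                mode = ncfg.get("selection", "bh")
                input_list = list(sel.loc[sel[mode], "protein_id"])
                input_list = [g for g in input_list
                              if g in set(collection.background)]
                scores = enrichment.score_networks(input_list, collection)
                null = enrichment.permutation_threshold(
                    collection, collection.background, max(len(input_list), 1),
                    repeats=int(ncfg.get("repeats", 10)), seed=seed + 2,
                )
                sig = enrichment.significant_networks(scores, null)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("network", str(exc)) from exc
            emit(pd.DataFrame(sig), "networks.tsv")
            emit(pd.DataFrame({"repeat": range(1, null.repeats + 1),
                               "max_score": null.max_scores}), "null.tsv")
            manifest["parameters"]["network_threshold"] = null.threshold

        # ----------------------------------------------------------- cluster
        clcfg = config.get("cluster", {"enabled": True}) or {}
        if clcfg.get("enabled", True):
            try:
                mode = clcfg.get("selection", "bh")
                chosen = list(sel.loc[sel[mode], "protein_id"])
                if len(chosen) >= 2:
                    values = np.log2(differential.replace_zeros(
                        matrix.counts.loc[chosen], contrast.pseudocount))
                    result = clustering.cluster_matrix(values)
                    emit(pd.DataFrame(
                        result["row_merges"],
                        columns=["cluster_i", "cluster_j", "height", "size"]),
                        "cluster_rows.tsv")
                    emit(result["ordered"], "clustered_matrix.tsv", index=True)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("cluster", str(exc)) from exc

        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written.append(manifest_path)
    except Exception:
        # remove partial outputs so a failed run leaves nothing half-written
        if fresh:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for path in written:
                path.unlink(missing_ok=True)
        raise
    return manifest
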