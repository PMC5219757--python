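"""End-to-end pipeline driver: simulate/build/fit/analyze with a manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .io import write_matrix_tsv, write_regions_bed
from .module_analysis import (
    call_main_drivers,
    call_module_usage,
    call_participation,
    group_modules,
    module_labels,
    multi_module_census,
    pca_modules,
    region_module_matrix,
)
from .regions import BindingCall, build_cobinding_regions, build_region_tf_matrix
from .synthetic import SyntheticConfig, generate
from .topic_model import corpus_from_matrix, extract_outputs, fit_hdp_multistart

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    calls: list[BindingCall] | None = None,
    synthetic_config: SyntheticConfig | None = None,
) -> Path:
    """Run simulate (optional) -> build-regions -> fit -> analyze.

    Either ``calls`` or ``synthetic_config`` must be given.  All outputs
    are plain TSV/BED; a manifest records parameters and output files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "expand_bp": config.expand_bp,
            "min_sites": config.min_sites,
            "eta": config.eta,
            "max_iter": config.max_iter,
            "seeds": list(config.seeds),
            "z_cut": config.z_cut,
            "group_cutoff": config.group_cutoff,
            "usage_z_axis": config.usage_z_axis,
        },
        "outputs": [],
    }

    def _write(name: str, writer, *args) -> None:
        path = out_dir / name
        writer(path, *args)
        manifest["outputs"].append(name)

    if calls is None:
        if synthetic_config is None:
            raise RuntimeError("pipeline stage 'input' failed: no calls and no synthetic config")
        dataset = _stage("simulate")(generate)(synthetic_config)
        calls = dataset.calls
        manifest["parameters"]["synthetic_seed"] = synthetic_config.seed

    regions = _stage("build-regions")(build_cobinding_regions)(
        calls, expand_bp=config.expand_bp, min_sites=config.min_sites
    )
    factors = sorted({c.factor for c in calls})
    matrix = _stage("build-regions")(build_region_tf_matrix)(regions, factors)
    _write("regions.bed", write_regions_bed, regions)
    _write("region_tf_matrix.tsv", write_matrix_tsv, matrix.to_frame())

    corpus = corpus_from_matrix(matrix)
    state = _stage("fit")(fit_hdp_multistart)(
        corpus, seeds=config.seeds, eta=config.eta, max_iter=config.max_iter
    )
    mtm, assignments = extract_outputs(state, corpus)
    _write("module_tf_matrix.tsv", write_matrix_tsv, mtm.to_frame())
    _write(
        "assignments.tsv",
        lambda p, df: df.to_csv(p, sep="\t", index=False),
        assignments,
    )
    trace = pd.DataFrame({f"seed_{s}": t for s, t in state.multistart_traces.items()})
    _write("loglik_trace.tsv", write_matrix_tsv, trace)
    manifest["selected_seed"] = state.seed
    manifest["n_modules"] = mtm.n_modules

    analyze = _stage("analyze")
    participation = analyze(call_participation)(mtm, z_cut=config.z_cut)
    drivers = analyze(call_main_drivers)(mtm, z_cut=config.z_cut)
    labels = module_labels(mtm, z_cut=config.z_cut)
    rmm = analyze(region_module_matrix)(assignments, n_modules=mtm.n_modules)
    usage = analyze(call_module_usage)(
        rmm, min_sites=config.min_sites, z_cut=config.z_cut, usage_z_axis=config.usage_z_axis
    )
    census = multi_module_census(usage)
    groups = analyze(group_modules)(mtm, cutoff=config.group_cutoff)
    pca = analyze(pca_modules)(mtm)

    _write(
        "participation.tsv",
        write_matrix_tsv,
        pd.DataFrame(participation, index=labels, columns=mtm.factors),
    )
    _write(
        "main_drivers.tsv",
        lambda p, rows: pd.DataFrame(rows, columns=["module", "label", "drivers"]).to_csv(
            p, sep="\t", index=False
        ),
        [(k, labels[k], "+".join(d)) for k, d in enumerate(drivers)],
    )
    _write("region_module_matrix.tsv", write_matrix_tsv, rmm)
    _write("module_usage.tsv", write_matrix_tsv, usage)
    _write(
        "multi_module_census.tsv",
        lambda p, c: pd.DataFrame(
            sorted(c.items()), columns=["n_modules_used", "n_regions"]
        ).to_csv(p, sep="\t", index=False),
        census,
    )
    _write(
        "module_groups.tsv",
        lambda p, g: pd.DataFrame(
            sorted(g.group_of.items()), columns=["module", "group"]
        ).to_csv(p, sep="\t", index=False),
        groups,
    )
    _write(
        "pca_variance.tsv",
        lambda p, v: pd.DataFrame(
            {"pc": range(1, len(v) + 1), "variance_fraction": v}
        ).to_csv(p, sep="\t", index=False),
        pca.explained_variance_ratio,
    )

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    for name in manifest["outputs"]:
        path = out_dir / name
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"declared output missing or empty: {name}")
    return out_dir
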