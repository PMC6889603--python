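"""End-to-end orchestration: classification table -> gold standard.

Thin glue over the taxonomy/classification/recipe/simulate/goldstandard
modules so the CLI, the test-suite and scripts can run the whole
construction with one call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import classification as cls
from . import goldstandard as gs
from . import recipe as rcp
from . import simulate as sim
from . import taxonomy as tax
from ._io import atomic_write, open_text


@dataclass
class PipelineResult:
    partition: cls.ReadPartition
    recipe: rcp.Recipe
    stats: rcp.RecipeStats
    profile: sim.ErrorProfile
    manifest: gs.TruthManifest
    summary: gs.CompositionSummary
    gs_r1_path: Path
    gs_r2_path: Path
    manifest_path: Path
    summary_path: Path


def run_gold_standard(
    r1_path: str | Path,
    r2_path: str | Path,
    classification_path: str | Path,
    nodes_path: str | Path,
    names_path: str | Path,
    catalog_path: str | Path,
    out_dir: str | Path,
    seed: int,
    fragment_mean: float | None = None,
    fragment_sd: float | None = None,
    bacteria_root: int = tax.BACTERIA_TAXID,
) -> PipelineResult:
    """Run classification rollup, recipe building, simulation and splicing."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open_text(nodes_path) as nodes, open_text(names_path) as names:
        tree = tax.load_taxonomy(nodes, names)
    with open_text(classification_path) as stream:
        hits = cls.parse_centrifuge(stream)
    records = cls.collapse_multihits(hits, tree)
    partition = cls.partition_reads(records, tree, bacteria_root)

    with open_text(catalog_path) as stream:
        catalog = rcp.load_catalog(stream)
    with open_text(r1_path) as h1, open_text(r2_path) as h2:
        profile = sim.learn_error_profile(h1, h2, fragment_mean, fragment_sd)
    recipe = rcp.build_recipe(
        partition, catalog, tree, read_length=profile.read_length_r1, reads_per_fragment=2
    )
    stats = rcp.recipe_stats(recipe, catalog)

    sim_r1 = out_dir / "simulated_R1.fastq"
    sim_r2 = out_dir / "simulated_R2.fastq"
    truth_path = out_dir / "simulated_truth.tsv"
    with atomic_write(sim_r1) as o1, atomic_write(sim_r2) as o2, atomic_write(truth_path) as ot:
        sim.execute_recipe(recipe, catalog, profile, seed, o1, o2, ot)

    gs_r1 = out_dir / "goldstandard_R1.fastq"
    gs_r2 = out_dir / "goldstandard_R2.fastq"
    manifest_path = out_dir / "manifest.tsv"
    summary_path = out_dir / "composition.json"
    with open_text(r1_path) as h1, open_text(r2_path) as h2, \
            open(sim_r1) as s1, open(sim_r2) as s2, \
            atomic_write(gs_r1) as o1, atomic_write(gs_r2) as o2, \
            atomic_write(manifest_path) as om:
        manifest, summary = gs.build_gold_standard(
            h1, h2, partition, s1, s2, o1, o2, recipe=recipe, manifest_out=om
        )
    with atomic_write(summary_path) as handle:
        json.dump(gs.summary_to_dict(summary), handle, indent=2, sort_keys=True)

    return PipelineResult(
        partition=partition,
        recipe=recipe,
        stats=stats,
        profile=profile,
        manifest=manifest,
        summary=summary,
        gs_r1_path=gs_r1,
        gs_r2_path=gs_r2,
        manifest_path=manifest_path,
        summary_path=summary_path,
    )
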