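"""End-to-end orchestration: ingest -> clump per perspective -> score ->
compare -> permute -> report.

Both analysis perspectives are always run: among-ancestry (all samples as the
LD reference, ancestry groups compared) and within-ancestry (each group its
own LD reference and score cohort, populations compared).  The permutation
stage is applied, by default, to every within-ancestry population pair of the
(group, tissue) combinations whose Kruskal–Wallis p passed Bonferroni
correction; ``permute_all`` extends it to every combination.  A JSON manifest
records versions, seed, parameters and input checksums; identical config +
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .clump import ClumpParams, clump_all, clumps_to_frame
from .permutation import permutations_to_frame, permute_null
from .scoring import ScoreMatrix, compute_scores, summarize_scores
from .simulate import SimConfig, simulate_dataset, write_fixture
from .stats import ComparisonReport, run_comparisons

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    vcf: str | None = None
    weights: str | None = None
    panel: str | None = None
    chrom: str = "18"
    region_start: int = 29_155_000
    region_end: int = 29_195_000
    simulate: SimConfig | None = None
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    n_permutations: int = 100_000
    alpha: float = 0.05
    permute_all: bool = False
    seed: int = 0
    out_dir: str = "popscore_out"

    def __post_init__(self) -> None:
        has_files = any(x is not None for x in (self.vcf, self.weights, self.panel))
        if self.simulate is not None and has_files:
            raise ValueError("provide either real input paths or simulate, not both")
        if self.simulate is None and not (self.vcf and self.weights and self.panel):
            raise ValueError("vcf, weights and panel paths are all required without simulate")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "popscore_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "clump_params": asdict(config.clump_params),
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "permute_all": config.permute_all,
        "inputs": {},
        "counts": {},
    }

    with _stage("ingest"):
        if config.simulate is not None:
            sim = simulate_dataset(config.simulate)
            paths = write_fixture(sim.region, sim.panel, sim.weights, out / "inputs")
            region, panel, weights = sim.region, sim.panel, sim.weights
            manifest["mode"] = "simulate"
        else:
            paths = {
                "vcf": Path(config.vcf),
                "weights": Path(config.weights),
                "panel": Path(config.panel),
            }
            region = pio.read_region_vcf(
                paths["vcf"], config.chrom, config.region_start, config.region_end
            )
            weights = pio.read_weight_table(paths["weights"])
            panel = pio.read_panel(paths["panel"])
            manifest["mode"] = "files"
        manifest["inputs"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()}
        weights = pio.align_weights_to_genotypes(region, weights)
        manifest["counts"]["n_samples"] = region.n_samples
        manifest["counts"]["n_variants"] = region.n_variants
        manifest["counts"]["n_tissues"] = len(weights.tissues)
        manifest["counts"]["n_weight_rows"] = len(weights)
        logger.info(
            "loaded %d samples x %d variants, %d tissues",
            region.n_samples, region.n_variants, len(weights.tissues),
        )

    with _stage("clump"):
        clumps_among = clump_all(region, weights, panel, config.clump_params, "among")
        clumps_within = clump_all(region, weights, panel, config.clump_params, "within")
        pio.write_tsv(clumps_to_frame(clumps_among), out / "clumps_among.tsv")
        pio.write_tsv(clumps_to_frame(clumps_within), out / "clumps_within.tsv")
        manifest["counts"]["index_variants_among"] = {
            c.tissue: len(c.index_variants) for c in clumps_among
        }

    with _stage("score"):
        scores_among = compute_scores(
            region, weights, clumps_among, panel.samples, perspective="among"
        )
        pio.write_tsv(scores_among.to_long_frame(panel), out / "scores_among.tsv")
        pio.write_tsv(
            summarize_scores(scores_among, panel, "ancestry"),
            out / "score_summary_among.tsv",
        )
        scores_within: list[ScoreMatrix] = []
        for group in panel.groups:
            group_clumps = [c for c in clumps_within if c.ld_subset == group]
            sm = compute_scores(
                region,
                weights,
                group_clumps,
                panel.samples_in_group(group),
                perspective="within",
                group=group,
            )
            scores_within.append(sm)
        within_long = pd.concat(
            [sm.to_long_frame(panel) for sm in scores_within], ignore_index=True
        )
        pio.write_tsv(within_long, out / "scores_within.tsv")

    with _stage("compare"):
        report_among = run_comparisons(scores_among, panel, "among")
        report_within = run_comparisons(scores_within, panel, "within")
        pio.write_tsv(report_among.kw, out / "kw_among.tsv")
        pio.write_tsv(report_among.dunn, out / "dunn_among.tsv")
        pio.write_tsv(report_within.kw, out / "kw_within.tsv")
        pio.write_tsv(report_within.dunn, out / "dunn_within.tsv")
        n_sig = int((report_within.kw["p_bonferroni"] <= config.alpha).sum())
        manifest["counts"]["bonferroni_significant_among"] = int(
            (report_among.kw["p_bonferroni"] <= config.alpha).sum()
        )
        manifest["counts"]["bonferroni_significant_within"] = n_sig

    with _stage("permute"):
        if config.permute_all:
            targets = report_within.kw[["group", "tissue"]]
        else:
            targets = report_within.kw.loc[
                report_within.kw["p_bonferroni"] <= config.alpha, ["group", "tissue"]
            ]
        results = []
        seed_seq = np.random.SeedSequence(config.seed)
        sm_by_group = {sm.group: sm for sm in scores_within}
        for row in targets.itertuples(index=False):
            group, tissue = row.group, row.tissue
            pairs = list(combinations(panel.populations(group), 2))
            child = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            results += permute_null(
                sm_by_group[group], panel, tissue, group, pairs,
                n_perm=config.n_permutations, seed=child,
            )
        perm_df = permutations_to_frame(results)
        pio.write_tsv(perm_df, out / "permutation_results.tsv")
        manifest["counts"]["permuted_combinations"] = int(len(targets))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %s", manifest_path)
    return manifest
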