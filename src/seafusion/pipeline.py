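"""Full-analysis orchestration.

Runs simulate -> preprocess -> MFA -> BE-PLS-DA (global and single-source,
per site and time point) -> microbiome statistics from one configuration,
with all stage seeds derived from a single master seed
(``SeedSequence(seed, spawn_key=(stage,))``) and a summary table in the
layout of the study's model-comparison table: omics sources with original
and selected variable counts, latent-variable count, and calibration and
cross-validation accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .design import (MICROBIOME_SITES, TIMES, class_vector, generate_design,
                     subset, validate_design)
from .mfa import mfa_fit
from .microbiome import diversity_report, run_comparisons
from .preprocess import OmicsBlock, fuse, pair_center, preprocess_blocks
from .selection import BEConfig, BEPLSDAModel, be_plsda, single_source_be
from .simulate import (SITE_BLOCK_SIZES, SyntheticSpec, generate_multiomics,
                       generate_otu_counts, spawn_rng)

log = logging.getLogger(__name__)

_STAGE_OMICS = 1
_STAGE_OTU = 2
_STAGE_MICROBIOME = 3


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One run's inputs and per-stage parameters."""

    seed: int = 0
    out: str | None = None
    # synthetic-mode parameters; design/blocks paths override them
    site_block_sizes: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in SITE_BLOCK_SIZES.items()})
    n_days_per_time: int = 6
    n_planted: int = 20
    effect_size: float = 3.0
    day_effect_sd: float = 1.0
    noise_sd: float = 1.0
    # real-data inputs (TSV paths); when set, synthetic mode is off
    design_path: str | None = None
    block_paths: dict = field(default_factory=dict)  # site -> {block: path}
    otu_path: str | None = None
    # stage parameters
    mfa_dims: int = 5
    class_active: bool = True
    max_lv: int = 5
    drop_fraction: float = 0.1
    drop_floor: int = 50
    n_taxa: int = 58
    dispersion: float = 0.1
    n_perm: int = 199
    rarefy_depth: int = 10_000
    run_microbiome: bool = True
    run_single_source: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def be_config(self) -> BEConfig:
        return BEConfig(max_lv=self.max_lv, drop_fraction=self.drop_fraction,
                        drop_floor=self.drop_floor)


@dataclass
class RunSummary:
    models: pd.DataFrame  # Table-3-style rows
    mfa_variance: pd.DataFrame  # site x dimension variance explained
    microbiome_hits: pd.DataFrame | None  # FDR<0.05 counts per contrast


def _load_or_simulate_site(config: RunConfig, design_site: pd.DataFrame,
                           site: str):
    if config.design_path is not None:
        blocks = {name: io.read_block(path, name)
                  for name, path in config.block_paths[site].items()}
        return blocks, None
    sizes = config.site_block_sizes[site]
    spec = SyntheticSpec(
        n_days_per_time=config.n_days_per_time, block_sizes=sizes,
        n_planted=config.n_planted, effect_size=config.effect_size,
        day_effect_sd=config.day_effect_sd, noise_sd=config.noise_sd,
        seed=config.seed, distinct_time_effects=True)
    rng = spawn_rng(config.seed,
                    _STAGE_OMICS * 100 + sorted(SITE_BLOCK_SIZES).index(site)
                    if site in SITE_BLOCK_SIZES else _STAGE_OMICS)
    return generate_multiomics(design_site, spec, rng=rng)


def _model_row(site: str, time: str, sources: str, result: BEPLSDAModel,
               original: dict[str, int]) -> dict:
    sel = result.selected_counts()
    return {
        "site": site,
        "time": time,
        "sources": sources,
        "original_variables": " + ".join(f"{b} ({n})"
                                         for b, n in original.items()),
        "selected_variables": " + ".join(
            f"{b} ({int(sel.get(b, 0))})" for b in original),
        "n_selected": len(result.selected_features),
        "n_lv": result.model.n_lv,
        "acc_cal_pct": result.accuracy_cal,
        "acc_cv_pct": result.accuracy_cv,
    }


def run_all(config: RunConfig) -> RunSummary:
    """Execute every stage in dependency order; deterministic given seed."""
    if config.design_path is not None:
        design = io.read_design(config.design_path)
        sites = tuple(config.block_paths)
    else:
        sites = tuple(config.site_block_sizes)
        design = generate_design(config.n_days_per_time, sites=sites)
    validate_design(design)
    out_dir = Path(config.out) if config.out else None
    prov = {"seed": config.seed,
            "config": io.config_hash(asdict(config))}
    if out_dir:
        io.write_design(design, out_dir / "design.tsv", provenance=prov)

    rows = []
    mfa_var = {}
    for site in sites:
        design_site = subset(design, site=site)
        try:
            blocks, _truth = _load_or_simulate_site(config, design_site, site)
        except Exception as err:
            raise PipelineError(f"stage simulate/load failed for site "
                                f"{site!r}: {err}") from err

        # MFA over the full site set (both time points, four classes)
        try:
            scaled, _ = preprocess_blocks(blocks, design_site)
            classes = (design_site.set_index("sample_id")
                       .loc[next(iter(scaled.values())).index]
                       .pipe(lambda d: d["time"] + "_" + d["group"]))
            mfa_res = mfa_fit(scaled, classes=list(classes),
                              n_dims=config.mfa_dims,
                              class_active=config.class_active)
            mfa_var[site] = mfa_res.variance_explained
            if out_dir:
                io.write_table(mfa_res.scores, out_dir / f"mfa_{site}_scores.tsv",
                               index_label="sample_id", provenance=prov)
                io.write_table(mfa_res.block_contributions,
                               out_dir / f"mfa_{site}_block_contributions.tsv",
                               index_label="block", provenance=prov)
        except Exception as err:
            raise PipelineError(f"stage mfa failed for site {site!r}: "
                                f"{err}") from err

        for time in TIMES:
            design_ts = subset(design_site, time=time)
            sub_blocks = {
                name: OmicsBlock(name=name, data=b.data.loc[
                    design_ts["sample_id"].to_numpy()])
                for name, b in blocks.items()}
            centered = {name: pair_center(b, design_ts)
                        for name, b in sub_blocks.items()}
            y = class_vector(design_ts)
            original = {name: b.data.shape[1]
                        for name, b in centered.items()}
            try:
                fused = fuse(centered, design_ts)
                global_model = be_plsda(fused, y, config.be_config())
            except Exception as err:
                raise PipelineError(
                    f"stage beplsda failed for {site}/{time}: {err}") from err
            rows.append(_model_row(site, time, "+".join(original),
                                   global_model, original))
            if config.run_single_source and len(centered) > 1:
                for name, block in centered.items():
                    single = single_source_be(block, design_ts, y,
                                              config.be_config())
                    rows.append(_model_row(site, time, name, single,
                                           {name: original[name]}))

    models = pd.DataFrame(rows)
    mfa_variance = pd.DataFrame(mfa_var).T

    hits = None
    if config.run_microbiome:
        try:
            micro_sites = tuple(s for s in sites if s in MICROBIOME_SITES)
            if micro_sites:
                micro_design = design[design["site"].isin(micro_sites)]
                micro_design = micro_design.reset_index(drop=True)
                if config.otu_path is not None:
                    otu = io.read_otu(config.otu_path)
                else:
                    otu, _ = generate_otu_counts(
                        micro_design, n_taxa=config.n_taxa,
                        dispersion=config.dispersion,
                        seed=spawn_rng(config.seed, _STAGE_OTU))
                results = run_comparisons(otu, micro_design)
                hit_rows = []
                for (name, site), res in results.items():
                    fdr = res.table.get("fdr_p")
                    n_hit = int((fdr < 0.05).sum()) if fdr is not None else 0
                    hit_rows.append({"contrast": name, "site": site or "all",
                                     "n_taxa": len(res.table),
                                     "fdr_hits": n_hit})
                hits = pd.DataFrame(hit_rows)
                if out_dir:
                    io.write_otu(otu, out_dir / "otu_table.tsv",
                                 provenance=prov)
                    io.write_table(hits, out_dir / "microbiome_hits.tsv",
                                   provenance=prov)
        except Exception as err:
            raise PipelineError(f"stage microbiome failed: {err}") from err

    if out_dir:
        io.write_table(models, out_dir / "summary_models.tsv",
                       provenance=prov)
        io.write_table(mfa_variance, out_dir / "summary_mfa_variance.tsv",
                       index_label="site", provenance=prov)
    return RunSummary(models=models, mfa_variance=mfa_variance,
                      microbiome_hits=hits)


def validate_inputs(config: RunConfig) -> list[str]:
    """Check design pairing, block/sample alignment, and count integrality.

    Returns a list of human-readable problems (empty when clean).
    """
    problems: list[str] = []
    if config.design_path is None:
        try:
            design = generate_design(config.n_days_per_time,
                                     sites=tuple(config.site_block_sizes))
        except Exception as err:
            return [f"synthetic design invalid: {err}"]
    else:
        try:
            design = io.read_design(config.design_path)
        except Exception as err:
            return [f"cannot read design: {err}"]
    try:
        validate_design(design)
    except Exception as err:
        problems.append(f"design: {err}")
    for site, paths in (config.block_paths or {}).items():
        for name, path in paths.items():
            try:
                block = io.read_block(path, name)
            except Exception as err:
                problems.append(f"block {site}/{name}: {err}")
                continue
            missing = set(block.sample_ids) - set(design["sample_id"])
            if missing:
                problems.append(f"block {site}/{name}: samples not in "
                                f"design: {sorted(missing)[:5]}")
    if config.otu_path is not None:
        try:
            otu = io.read_otu(config.otu_path)
            if (otu.counts.to_numpy() % 1 != 0).any():
                problems.append("otu table: non-integer counts")
        except Exception as err:
            problems.append(f"otu table: {err}")
    return problems
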