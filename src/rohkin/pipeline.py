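"""End-to-end pipeline: synth -> QC -> ROH -> inbreeding -> origin -> association.

A single YAML-configurable run with deterministic seeding.  The global seed
is fanned out to fixed per-stage child seeds (via ``numpy`` SeedSequence
spawn keys) so any stage can be rerun in isolation; stage outputs are pure
functions of (inputs, config, seed).  Each stage writes versioned TSV/JSON
outputs into the run directory and the run ends with a machine-readable
``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import fit_gbc_model, forest_table, stratified_or
from .genotype_io import apply_variant_filters, read_plink, write_cohort, write_plink
from .inbreeding import profiles_table
from .origin import classify_cohort, fit_outbred_baseline
from .pedigree_sim import GenomeMap, simulate_mating, simulation_envelope
from .roh_caller import ROHParams, call_roh, write_roh
from .synthetic_cohort import COEFFICIENT_SETS, CohortConfig, generate_cohort_genotypes

logger = logging.getLogger(__name__)

_STAGES = ("synth", "qc", "roh", "inbreeding", "origin", "assoc")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Unknown keys in the YAML are rejected up front, before any stage runs.
    """

    seed: int = 0
    out_dir: str = "rohkin_run"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # synth
    n_samples: int = 60
    coefficient_set: str = "table2"
    genome: str = "scaled"
    snp_spacing_bp: int = 5000
    # qc
    maf_min: float = 0.01
    hwe_p_min: float | None = 0.001
    # roh
    roh: ROHParams = field(default_factory=ROHParams)
    # inbreeding
    froh_min_mb: float = 1.5
    genome_gb: float | None = None  # None -> use the simulated map length
    # origin
    baseline_n: int = 100
    envelope_n: int = 200
    fis_tolerance: float = 0.01
    # assoc
    interactions: list[str] = field(default_factory=list)
    stratify: list[str] = field(default_factory=lambda: ["sex", "age60", "prs_median"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "roh" in raw and isinstance(raw["roh"], dict):
            raw = {**raw, "roh": ROHParams(**raw["roh"])}
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)} (valid: {_STAGES})")
        return cfg


def _child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure raises with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                                for k, v in dataclasses.asdict(config).items()}}
    genome = GenomeMap.scaled() if config.genome == "scaled" else GenomeMap.human22()
    genome_gb = config.genome_gb if config.genome_gb is not None else genome.total_bp / 1e9

    state: dict = {}
    for stage in config.stages:
        logger.info("stage %s starting", stage)
        try:
            _run_stage(stage, config, genome, genome_gb, out, state, summary)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done", stage)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def _run_stage(stage: str, config: RunConfig, genome: GenomeMap, genome_gb: float,
               out: Path, state: dict, summary: dict) -> None:
    if stage == "synth":
        ccfg = CohortConfig(
            n=config.n_samples, genome=genome,
            coefficients=dict(COEFFICIENT_SETS[config.coefficient_set]),
            snp_spacing_bp=config.snp_spacing_bp,
        )
        cohort, params, g, truth = generate_cohort_genotypes(
            ccfg, seed=_child_seed(config.seed, "synth")
        )
        write_plink(g, out / "synth.bed", out / "synth.bim", out / "synth.fam")
        write_cohort(cohort, out / "cohort.tsv")
        truth.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
        (out / "truth_params.json").write_text(
            json.dumps({k: v for k, v in params.items() if k != "group_labels"},
                       indent=2, default=str)
        )
        pd.DataFrame({"sample_id": cohort["sample_id"],
                      "group": params["group_labels"]}).to_csv(
            out / "groups.tsv", sep="\t", index=False)
        state["genotypes"], state["cohort"] = g, cohort
        summary["synth"] = {"n_samples": g.n_samples, "n_variants": g.n_variants,
                            "prevalence": float(cohort["outcome"].mean())}
    elif stage == "qc":
        g = state.get("genotypes") or read_plink(
            out / "synth.bed", out / "synth.bim", out / "synth.fam")
        gq = apply_variant_filters(g, config.maf_min, config.hwe_p_min)
        write_plink(gq, out / "qc.bed", out / "qc.bim", out / "qc.fam")
        state["qc"] = gq
        summary["qc"] = {"n_variants_in": g.n_variants, "n_variants_out": gq.n_variants}
    elif stage == "roh":
        gq = state.get("qc") or read_plink(out / "qc.bed", out / "qc.bim", out / "qc.fam")
        segments = call_roh(gq, config.roh)
        write_roh(segments, out / "roh.tsv")
        state["segments"], state["qc"] = segments, gq
        summary["roh"] = {"n_segments": len(segments)}
    elif stage == "inbreeding":
        gq = state.get("qc") or read_plink(out / "qc.bed", out / "qc.bim", out / "qc.fam")
        segments = state.get("segments")
        if segments is None:
            from .roh_caller import read_roh

            segments = read_roh(out / "roh.tsv")
        profiles = profiles_table(gq, segments, config.froh_min_mb, genome_gb)
        profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
        state["profiles"] = profiles
        summary["inbreeding"] = {
            "median_f_roh": float(profiles["f_roh"].median()),
            "mean_f_is": float(profiles["f_is"].mean()),
        }
    elif stage == "origin":
        profiles = state.get("profiles")
        if profiles is None:
            profiles = pd.read_csv(out / "profiles.tsv", sep="\t")
        rng_seed = _child_seed(config.seed, "origin")
        baseline_pts = _outbred_panel(genome, config.baseline_n, rng_seed)
        baseline = fit_outbred_baseline(baseline_pts)
        offs = {
            mt: simulate_mating(mt, genome, n_offspring=config.envelope_n,
                                seed=rng_seed + i)
            for i, mt in enumerate(
                ("second_cousin", "first_cousin", "avuncular", "incest"))
        }
        envelopes = simulation_envelope(offs)
        calls = classify_cohort(profiles, baseline, envelopes, config.fis_tolerance)
        calls.to_csv(out / "origin.tsv", sep="\t", index=False)
        summary["origin"] = {
            "baseline_slope": baseline.slope,
            "region_counts": calls["fis_froh_region"].value_counts().to_dict(),
        }
    elif stage == "assoc":
        cohort = state.get("cohort")
        if cohort is None:
            from .genotype_io import read_cohort

            cohort = read_cohort(out / "cohort.tsv")
        profiles = state.get("profiles")
        if profiles is not None:
            # use the *called* F_ROH, closing the loop caller -> association
            called = profiles.set_index("sample_id")["f_roh"]
            cohort = cohort.assign(
                f_roh=cohort["sample_id"].map(called).fillna(0.0))
        full = fit_gbc_model(cohort, interactions=config.interactions or None)
        results = [full]
        for strat in config.stratify:
            results.extend(stratified_or(cohort, strat).values())
        table = forest_table(results)
        table.to_csv(out / "association.tsv", sep="\t", index=False)
        summary["assoc"] = {
            "froh_or_per_pct": full.term("froh_pct")["or"],
            "converged": full.converged,
            "n": full.n,
        }
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ValueError(f"unknown stage {stage}")


def _outbred_panel(genome: GenomeMap, n: int, seed: int) -> np.ndarray:
    """(NROH, SROH) points for a drift-only outbred reference panel.

    Uses the tract-level drift sampler with a moderate founder pool and no
    consanguinity, mimicking an admixed, relatively outbred population.
    """
    from .synthetic_cohort import GroupConfig as _GC

    rng = np.random.default_rng(seed)
    grp = _GC(1.0, 6, 1.86)
    lam = genome.total_mb * grp.autozygous_fraction * np.exp(
        -1.5 / grp.mean_tract_mb) / grp.mean_tract_mb
    counts = rng.poisson(lam, n)
    sroh = np.array([
        1.5 * c + rng.exponential(grp.mean_tract_mb, c).sum() for c in counts
    ])
    return np.column_stack([counts, sroh])
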