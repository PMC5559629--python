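"""End-to-end orchestration: QC -> GRM -> heritability screen (+ permutation
FDR) -> 16S clade test -> trait association, under one config with a master
seed and a machine-readable run manifest.

Per-stage seeds derive deterministically from the master seed as the first
four bytes of SHA-256("<master>:<stage>") masked to 31 bits, so stage-level
reruns reproduce pipeline-level results regardless of execution order.
Stages whose recorded outputs still exist with matching digests are skipped
unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from .abundance import AbundanceTable
from .errors import ConfigError, RumheritError
from .greml import eigen_prepare
from .grm import allele_frequencies, compute_grm, read_grm, write_grm
from .phylo import AlignmentScoring, SequenceSet, similarity_null_test, taxon_enrichment
from .plink import apply_qc, read_plink_text, write_plink_text
from .screen import (
    permutation_fdr,
    presence_filter,
    screen_heritable,
    trait_heritability,
)
from .simulate import (
    HerdDesign,
    PlantedMicrobiome,
    default_trait_spec,
    simulate_abundances,
    simulate_genotypes,
    simulate_sequences,
    simulate_traits,
)

log = logging.getLogger("rumherit")

STAGES = ("simulate", "qc", "grm", "screen", "phylo", "associate")


@dataclass
class RunConfig:
    """Pipeline configuration; either input paths or a simulate block."""

    out_dir: str = "rumherit_run"
    seed: int = 0
    ped: str | None = None
    map: str | None = None
    otu_table: str | None = None
    fasta: str | None = None
    traits: str | None = None
    simulate: dict | None = None  # HerdDesign/PlantedMicrobiome overrides
    mind: float = 0.05
    geno: float = 0.05
    maf: float = 0.05
    min_present: int = 12
    h2_min: float = 0.7
    alpha: float = 0.05
    n_perm_fdr: int = 100
    n_perm_corr: int = 1000
    n_draws_phylo: int = 100
    diagonal_mode: str = "plain"
    scoring: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.simulate is None and (self.ped is None or self.otu_table is None):
            raise ConfigError("either input paths or a simulate block is required")
        for name in ("mind", "geno", "maf", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1)")
        if not (0.0 <= self.h2_min <= 1.0):
            raise ConfigError("h2_min outside [0, 1]")
        for name in ("n_perm_fdr", "n_perm_corr", "n_draws_phylo"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be at least 1")


def derive_seed(master: int, stage: str) -> int:
    """Stable 31-bit per-stage seed from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = (
            json.loads(path.read_text()) if path.exists() else {"stages": {}}
        )

    def stage_done(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec:
            return False
        return all(
            Path(p).exists() and _digest(Path(p)) == d
            for p, d in rec["outputs"].items()
        )

    def record(self, stage: str, outputs: list[Path], seed: int | None, metrics: dict):
        self.data["stages"][stage] = {
            "outputs": {str(p): _digest(p) for p in outputs},
            "seed": seed,
            "metrics": metrics,
        }
        self.flush()

    def flush(self):
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages; returns the manifest dict.

    Any stage error aborts with the stage name attached after persisting
    the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["config"] = asdict(config)
    manifest.data["seed_derivation"] = "sha256('<master>:<stage>')[:4] & 0x7fffffff"
    manifest.flush()

    state: dict = {}
    for stage in STAGES:
        if not force and manifest.stage_done(stage):
            log.info("stage=%s status=skipped (outputs up to date)", stage)
            _reload_stage(stage, config, out, state)
            continue
        try:
            _run_stage(stage, config, out, state, manifest)
        except RumheritError as exc:
            manifest.flush()
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
    return manifest.data


def _sim_specs(config: RunConfig):
    block = dict(config.simulate or {})
    herd_keys = set(HerdDesign.__dataclass_fields__)
    micro_keys = set(PlantedMicrobiome.__dataclass_fields__)
    herd = HerdDesign(
        **{k: v for k, v in block.items() if k in herd_keys},
    )
    micro = PlantedMicrobiome(
        **{k: v for k, v in block.items() if k in micro_keys and k != "seed"},
    )
    return herd, micro


def _run_stage(stage, config: RunConfig, out: Path, state: dict, manifest: _Manifest):
    seed = derive_seed(config.seed, stage)
    metrics: dict = {}
    outputs: list[Path] = []

    if stage == "simulate":
        if config.simulate is None:
            manifest.record(stage, [], None, {"skipped": "inputs supplied"})
            _load_inputs(config, state)
            return
        herd, micro = _sim_specs(config)
        herd = HerdDesign(**{**asdict_shallow(herd), "seed": seed})
        micro_kwargs = {
            f: getattr(micro, f) for f in PlantedMicrobiome.__dataclass_fields__
        }
        micro_kwargs["seed"] = seed + 1
        micro = PlantedMicrobiome(**micro_kwargs)
        g, _pedigree = simulate_genotypes(herd)
        # additive polygenic model: the genetic covariance of a phenotype
        # driven by iid SNP effects is the realized GRM, not the pedigree
        kernel = compute_grm(g, allele_frequencies(g))
        extra = tuple(herd.animal_ids()[herd.n_genotyped:])
        table = simulate_abundances(kernel, micro, ungenotyped_ids=extra)
        seqs = simulate_sequences(micro)
        table = AbundanceTable(table.data, seqs.taxonomy.loc[table.data.index])
        tspec = default_trait_spec(micro.planted_ids(), seed=seed + 2)
        traits = simulate_traits(table, tspec)
        truth = pd.DataFrame(
            {
                "otu_id": micro.otu_ids(),
                "true_h2": [
                    micro.true_h2 if o in set(micro.planted_ids()) else 0.0
                    for o in micro.otu_ids()
                ],
                "clade": [o in set(micro.planted_ids()) for o in micro.otu_ids()],
            }
        )
        ped_p, map_p = out / "sim.ped", out / "sim.map"
        write_plink_text(g, ped_p, map_p)
        table.to_tsv(out / "sim_otu_table.tsv")
        seqs.write_fasta(out / "sim_16s.fasta")
        traits.rename_axis("animal").to_csv(out / "sim_traits.tsv", sep="\t")
        truth.to_csv(out / "sim_truth.tsv", sep="\t", index=False)
        outputs = [ped_p, map_p, out / "sim_otu_table.tsv", out / "sim_16s.fasta",
                   out / "sim_traits.tsv", out / "sim_truth.tsv"]
        metrics = {"n_genotyped": g.n_animals, "n_snps": g.n_snps,
                   "n_otus": len(table.otu_ids)}
        state.update(genotypes=g, table=table, seqs=seqs, traits=traits,
                     planted=set(micro.planted_ids()))

    elif stage == "qc":
        g, report = apply_qc(state["genotypes"], config.mind, config.geno, config.maf)
        report.to_tsv(out / "qc_report.tsv")
        qc_ped, qc_map = out / "qc.ped", out / "qc.map"
        write_plink_text(g, qc_ped, qc_map)
        outputs = [out / "qc_report.tsv", qc_ped, qc_map]
        metrics = {
            "individuals_removed": report.individuals_removed,
            "snps_removed_missing": report.snps_removed_missing,
            "snps_removed_maf": report.snps_removed_maf,
            "snps_passing": report.snps_passing,
        }
        state["qc_genotypes"] = g

    elif stage == "grm":
        g = state["qc_genotypes"]
        a = compute_grm(g, allele_frequencies(g), diagonal_mode=config.diagonal_mode)
        write_grm(a, out / "grm")
        outputs = [out / "grm.grm.id", Path(f"{out / 'grm'}.grm.gz")]
        metrics = {"n_animals": a.n_animals,
                   "mean_diagonal": float(np.mean(np.diag(a.values)))}
        state["grm"] = a

    elif stage == "screen":
        a = state["grm"]
        table = presence_filter(state["table"], a.animal_ids, config.min_present)
        metrics["otus_after_presence_filter"] = len(table.otu_ids)
        log.info("stage=screen otus_after_presence_filter=%d", len(table.otu_ids))
        eig = eigen_prepare(a)
        result = screen_heritable(
            table, eig, h2_min=config.h2_min, alpha=config.alpha,
            genotyped_ids=list(a.animal_ids),
        )
        fdr = permutation_fdr(
            table, eig, n_perm=config.n_perm_fdr, seed=seed,
            h2_min=config.h2_min, alpha=config.alpha,
            genotyped_ids=list(a.animal_ids),
        )
        result.results.to_csv(out / "screen_per_day.tsv", sep="\t", index=False)
        pd.Series(sorted(result.consensus_ids), name="otu_id").to_csv(
            out / "heritable_otus.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"permutation": np.arange(1, fdr.n_perm + 1), "count": fdr.permuted_counts}
        ).to_csv(out / "fdr_null_counts.tsv", sep="\t", index=False)
        if state.get("traits") is not None:
            th = trait_heritability(state["traits"], a)
            th.to_csv(out / "trait_heritability.tsv", sep="\t", index=False)
            outputs.append(out / "trait_heritability.tsv")
        outputs += [out / "screen_per_day.tsv", out / "heritable_otus.tsv",
                    out / "fdr_null_counts.tsv"]
        metrics.update(
            consensus_count=len(result.consensus_ids),
            fdr_fraction_below=fdr.fraction_below,
        )
        log.info(
            "stage=screen consensus_count=%d fdr_fraction_below=%.3f",
            len(result.consensus_ids), fdr.fraction_below,
        )
        state.update(filtered_table=table, heritable=result.consensus_ids)

    elif stage == "phylo":
        seqs: SequenceSet = state["seqs"]
        eligible = list(state["filtered_table"].otu_ids)
        heritable = sorted(state["heritable"])
        scoring = AlignmentScoring(**config.scoring)
        if len(heritable) >= 2:
            res = similarity_null_test(
                seqs, heritable, eligible, n_draws=config.n_draws_phylo,
                seed=seed, scoring=scoring,
            )
            pd.DataFrame({"null_mean_similarity": res.null_means}).to_csv(
                out / "phylo_null_means.tsv", sep="\t", index=False
            )
            metrics.update(
                observed_mean_similarity=res.observed, phylo_p=res.p_value,
                scoring=asdict_shallow(scoring),
            )
            enr = taxon_enrichment(
                state["filtered_table"].taxonomy, heritable, rank="order"
            )
            enr.rename_axis("taxon").to_csv(out / "order_enrichment.tsv", sep="\t")
            outputs = [out / "phylo_null_means.tsv", out / "order_enrichment.tsv"]
        else:
            metrics["skipped"] = "fewer than two heritable OTUs"
        log.info("stage=phylo metrics=%s", metrics)

    elif stage == "associate":
        traits = state.get("traits")
        if traits is None:
            manifest.record(stage, [], seed, {"skipped": "no trait table"})
            return
        heritable = sorted(state["heritable"])
        table = state["filtered_table"]
        abund = assoc.animal_abundance(table)
        profile = assoc.spearman_profile(abund, traits)
        profile.to_csv(out / "correlation_profile.tsv", sep="\t", index=False)
        outputs = [out / "correlation_profile.tsv"]
        if len(heritable) >= 2:
            null = assoc.mean_correlation_null(
                abund.loc[heritable], traits, n_perm=config.n_perm_corr, seed=seed
            )
            compare = assoc.mean_abs_corr_compare(profile, heritable)
            ors = assoc.correlation_odds_ratio(profile, heritable, alpha=config.alpha)
            summary = null.summary.join(
                compare.set_index("index")[["t_statistic", "p_value"]]
                .rename(columns={"p_value": "t_test_p"}),
                how="left",
            ).join(
                pd.DataFrame([vars(e) for e in ors]).set_index("index"), how="left"
            )
            summary.rename_axis("index").to_csv(out / "index_summary.tsv", sep="\t")
            outputs.append(out / "index_summary.tsv")
            metrics["indices_tested"] = int(len(summary))
        else:
            metrics["skipped"] = "fewer than two heritable OTUs"
        log.info("stage=associate metrics=%s", metrics)

    manifest.record(stage, outputs, seed, metrics)


def asdict_shallow(obj) -> dict:
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}


def _load_inputs(config: RunConfig, state: dict) -> None:
    state["genotypes"] = read_plink_text(config.ped, config.map)
    state["table"] = AbundanceTable.read_tsv(config.otu_table)
    if config.fasta:
        state["seqs"] = SequenceSet.read_fasta(
            config.fasta, state["table"].taxonomy
        )
    if config.traits:
        state["traits"] = pd.read_csv(config.traits, sep="\t", index_col=0)


def _reload_stage(stage, config: RunConfig, out: Path, state: dict) -> None:
    """Rebuild in-memory state for a skipped stage from its output files."""
    if stage == "simulate":
        if config.simulate is None:
            _load_inputs(config, state)
        else:
            state["genotypes"] = read_plink_text(out / "sim.ped", out / "sim.map")
            state["table"] = AbundanceTable.read_tsv(out / "sim_otu_table.tsv")
            state["seqs"] = SequenceSet.read_fasta(
                out / "sim_16s.fasta", state["table"].taxonomy
            )
            state["traits"] = pd.read_csv(out / "sim_traits.tsv", sep="\t", index_col=0)
    elif stage == "qc":
        state["qc_genotypes"] = read_plink_text(out / "qc.ped", out / "qc.map")
    elif stage == "grm":
        state["grm"] = read_grm(out / "grm")
    elif stage == "screen":
        a = state["grm"]
        state["filtered_table"] = presence_filter(
            state["table"], a.animal_ids, config.min_present
        )
        heritable = pd.read_csv(out / "heritable_otus.tsv", sep="\t")
        state["heritable"] = set(heritable["otu_id"].astype(str)) if len(heritable) else set()
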