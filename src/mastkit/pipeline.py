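"""End-to-end orchestration: simulate -> call -> cluster -> randomize -> evolve.

A run is driven by a flat key/value config file (YAML syntax, unknown keys
rejected).  Every stage's randomness is seeded deterministically from the
global seed and the stage name, so a config fully determines every output
byte.  Stages are skipped on re-run when their parameters and inputs are
unchanged (checksum stamps), and the run report records everything needed
to re-execute the identical run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import (
    MCLParams,
    build_cooccurrence_graph,
    bee_similarity_matrix,
    cluster_stats,
    mcl_cluster,
    within_vs_between_snps,
)
from .evolution_sim import run_evolution_experiment
from .randomization import (
    interspecies_association_test,
    location_shuffle_test,
    reassortment_null,
    saturation_curve,
)
from .strain_caller import CallerParams, call_from_fastq_dir, rescue_cryptic
from .synthetic_data import (
    ReadSimParams,
    make_truth,
    read_references,
    simulate_reads,
)


@dataclass
class RunConfig:
    """Validated flat configuration for a pipeline run."""

    out_dir: str = "mastkit_run"
    seed: int = 0
    # synthetic input generation (ignored when reads_dir is given)
    n_bees: int = 12
    locations: str = "Texas:6,Tennessee:3,Utah:2,Florida:1"
    n_clusters: int = 5
    strains_per_cluster: int = 4
    within_cluster_snps: int = 1
    two_cluster_fraction: float = 0.1
    location_bias: float = 0.0
    coverage_mean: float = 2000.0
    coverage_dispersion: float = 8.0
    error_rate: float = 0.001
    # external inputs (optional)
    reads_dir: str | None = None
    references_fasta: str | None = None
    frame_offsets: str | None = None
    metadata_tsv: str | None = None
    # calling
    min_mean_phred: float = 30.0
    freq_threshold: float = 0.01
    # clustering
    inflation: float = 2.0
    # randomization
    n_reps: int = 1000
    n_combinations: int = 100
    # evolution simulation
    run_evolution: bool = True
    evolution_mode: str = "pcr"

    def __post_init__(self) -> None:
        CallerParams(self.min_mean_phred, self.freq_threshold)  # validates
        MCLParams(inflation=self.inflation)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.evolution_mode not in ("pcr", "selection", "both"):
            raise ValueError("evolution_mode must be pcr, selection or both")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def location_sizes(self) -> dict[str, int]:
        out = {}
        for part in self.locations.split(","):
            name, _, size = part.strip().partition(":")
            out[name] = int(size)
        return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum_paths(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class _Stamps:
    """Checksum stamps for skip-unchanged stage re-execution."""

    def __init__(self, out_dir: Path):
        self.dir = out_dir / ".stamps"
        self.dir.mkdir(parents=True, exist_ok=True)

    def key(self, stage: str, payload: dict) -> str:
        return hashlib.sha256(
            json.dumps({"stage": stage, **payload}, sort_keys=True).encode()
        ).hexdigest()

    def is_current(self, stage: str, key: str, outputs: list[Path]) -> bool:
        stamp = self.dir / f"{stage}.json"
        if not stamp.exists() or not all(p.exists() for p in outputs):
            return False
        return json.loads(stamp.read_text()).get("key") == key

    def write(self, stage: str, key: str) -> None:
        (self.dir / f"{stage}.json").write_text(json.dumps({"key": key}))


@dataclass
class RunReport:
    """Everything needed to re-execute and audit a run."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    stages: dict[str, dict] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def summarize_strain_diversity(table) -> pd.DataFrame:
    """Per marker: total strains, mean strains per bee (+/- sd), mean pairwise SNPs."""
    if table.counts.empty:
        raise ValueError("empty strain table")
    rows = []
    for marker in table.markers:
        strains = table.strains(marker)
        samples = table.marker_samples(marker)
        pres = table.presence(marker)[samples] if strains and samples else None
        per_bee = pres.sum(axis=0) if pres is not None else pd.Series(dtype=float)
        from .strain_caller import snp_distance

        dists = [
            snp_distance(strains[i], strains[j])
            for i in range(len(strains))
            for j in range(i + 1, len(strains))
        ]
        rows.append(
            {
                "marker": marker,
                "total_strains": len(strains),
                "mean_strains_per_bee": float(per_bee.mean()) if len(per_bee) else 0.0,
                "sd_strains_per_bee": float(per_bee.std(ddof=0)) if len(per_bee) else 0.0,
                "mean_pairwise_snps": float(np.mean(dists)) if dists else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamps = _Stamps(out)
    cfg_dict = dataclasses.asdict(config)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("simulate", "call", "cluster", "randomize", "evolve")
    }
    report = RunReport(config=cfg_dict, version=__version__, stage_seeds=seeds)

    # -- stage: inputs (simulate or locate) -------------------------------
    if config.reads_dir is None:
        sim_dir = out / "inputs"
        sim_key = stamps.key("simulate", {"cfg": cfg_dict, "seed": seeds["simulate"]})
        sim_outputs = [sim_dir / "references.fasta", sim_dir / "metadata.tsv"]
        if not stamps.is_current("simulate", sim_key, sim_outputs):
            truth = make_truth(
                n_bees=config.n_bees,
                locations=config.location_sizes(),
                n_clusters=config.n_clusters,
                strains_per_cluster=config.strains_per_cluster,
                within_cluster_snps=config.within_cluster_snps,
                two_cluster_fraction=config.two_cluster_fraction,
                location_bias=config.location_bias,
                seed=seeds["simulate"],
            )
            sim = simulate_reads(
                truth,
                ReadSimParams(
                    coverage_mean=config.coverage_mean,
                    coverage_dispersion=config.coverage_dispersion,
                    error_rate=config.error_rate,
                    seed=seeds["simulate"],
                ),
                out_dir=sim_dir,
            )
            stamps.write("simulate", sim_key)
        reads_dir = sim_dir / "reads"
        references_fasta = sim_dir / "references.fasta"
        frame_offsets = sim_dir / "frame_offsets.tsv"
        metadata_tsv = sim_dir / "metadata.tsv"
        report.stages["simulate"] = {"out": str(sim_dir), "synthetic": True}
    else:
        reads_dir = Path(config.reads_dir)
        if config.references_fasta is None or config.metadata_tsv is None:
            raise ValueError("reads_dir requires references_fasta and metadata_tsv")
        references_fasta = Path(config.references_fasta)
        frame_offsets = Path(config.frame_offsets) if config.frame_offsets else None
        metadata_tsv = Path(config.metadata_tsv)
        for p in [reads_dir, references_fasta, metadata_tsv]:
            if not p.exists():
                raise FileNotFoundError(f"missing input: {p}")
        report.stages["simulate"] = {"synthetic": False}

    report.input_checksums["references"] = _checksum_paths([references_fasta])
    report.input_checksums["metadata"] = _checksum_paths([metadata_tsv])

    references = read_references(references_fasta, frame_offsets)
    metadata = pd.read_csv(metadata_tsv, sep="\t")
    caller_params = CallerParams(config.min_mean_phred, config.freq_threshold)

    # -- stage: call ------------------------------------------------------
    table_dir = out / "strain_table"
    table, raw_pools, accounting = call_from_fastq_dir(
        reads_dir, references, metadata, caller_params
    )
    table.save(table_dir)
    accounting.to_csv(table_dir / "read_accounting.tsv", sep="\t", index=False)
    diversity = summarize_strain_diversity(table)
    diversity.to_csv(table_dir / "strain_diversity.tsv", sep="\t")
    if table.registry:
        rescue = rescue_cryptic(table, raw_pools)
        rescue.to_csv(table_dir / "cryptic_rescue.tsv", sep="\t")
    report.stages["call"] = {
        "n_strains": len(table.registry),
        "n_samples": len(table.samples),
        "markers": table.markers,
    }

    # -- stage: cluster ---------------------------------------------------
    cluster_dir = out / "clusters"
    cluster_dir.mkdir(exist_ok=True)
    mcl_params = MCLParams(inflation=config.inflation)
    cluster_summary = {}
    for marker in table.markers:
        if len(table.strains(marker)) < 2:
            warnings.warn(f"{marker}: <2 strains, skipping clustering")
            continue
        graph = build_cooccurrence_graph(table, marker)
        graph.to_frame().to_csv(cluster_dir / f"{marker}_scores.tsv", sep="\t")
        bee_similarity_matrix(table, marker).to_csv(
            cluster_dir / f"{marker}_bee_similarity.tsv", sep="\t"
        )
        clusters = mcl_cluster(graph, mcl_params)
        pd.DataFrame(
            [(cid, sid) for cid, members in clusters.partition.items() for sid in members],
            columns=["cluster_id", "strain_id"],
        ).to_csv(cluster_dir / f"{marker}_clusters.tsv", sep="\t", index=False)
        stats_ = cluster_stats(clusters, table, marker)
        wb = within_vs_between_snps(clusters, table.registry)
        cluster_summary[marker] = {
            "n_clusters": len(clusters.partition),
            "sizes": stats_.sizes,
            "converged": clusters.converged,
            "within_vs_between_p": wb.pvalue if wb.applicable else None,
        }
    report.stages["cluster"] = cluster_summary

    # -- stage: randomize -------------------------------------------------
    rand_dir = out / "randomization"
    rand_dir.mkdir(exist_ok=True)
    rand_summary = {}
    n_markers = len(table.markers)
    for i, marker in enumerate(table.markers):
        if not table.strains(marker):
            continue
        loc = location_shuffle_test(
            table, metadata, marker, n_reps=config.n_reps,
            seed=stage_seed(seeds["randomize"], f"loc:{marker}"), n_tests=n_markers,
        )
        rea = reassortment_null(
            table, marker, n_reps=config.n_reps,
            seed=stage_seed(seeds["randomize"], f"rea:{marker}"), n_tests=n_markers,
        )
        sat = saturation_curve(
            table, marker, n_combinations=config.n_combinations,
            seed=stage_seed(seeds["randomize"], f"sat:{marker}"),
        )
        sat.to_frame().to_csv(rand_dir / f"{marker}_saturation.tsv", sep="\t", index=False)
        (rand_dir / f"{marker}_tests.json").write_text(
            json.dumps(
                {"location": loc.to_dict(), "reassortment": rea.to_dict()},
                indent=2, sort_keys=True,
            )
        )
        rand_summary[marker] = {
            "location_p": loc.p_bonferroni,
            "reassortment_p": rea.p_bonferroni if rea.applicable else None,
        }
    report.stages["randomize"] = rand_summary

    # -- stage: evolve ----------------------------------------------------
    if config.run_evolution:
        evo_dir = out / "evolution"
        evo_dir.mkdir(exist_ok=True)
        modes = ["pcr", "selection"] if config.evolution_mode == "both" else [config.evolution_mode]
        evo_summary = {}
        for mode in modes:
            from .evolution_sim import (
                DEFAULT_CODON_WEIGHTS,
                DEFAULT_MEAN_SNPS,
                DEFAULT_STRAINS_PER_BEE,
            )

            experiment = run_evolution_experiment(
                mode=mode, references=references,
                strains_per_bee={m: DEFAULT_STRAINS_PER_BEE.get(m, 6) for m in references},
                mean_snps={m: DEFAULT_MEAN_SNPS.get(m, 8.0) for m in references},
                codon_weights={m: DEFAULT_CODON_WEIGHTS.get(m, (0.15, 0.07, 0.78)) for m in references},
                seed=stage_seed(seeds["evolve"], mode),
            )
            evo_summary[mode] = experiment.summary()
            (evo_dir / f"{mode}_summary.json").write_text(
                json.dumps(experiment.summary(), indent=2, sort_keys=True)
            )
        report.stages["evolve"] = evo_summary

    report.save(out / "run_report.json")
    return report
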