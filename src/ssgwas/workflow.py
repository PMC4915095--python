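"""Replicate orchestration: simulate one population, analyze it with
WssGBLUP (SI/SII, weights w1-w3) and Bayes C (pi = 0.99 / 0.999), score
QTL detection, and aggregate replicates into a summary table.

Three problem scales are bundled:

``full``
    the nominal study design (2,333 cM, 335,000 selected markers,
    1,000 QTLs, 90,000 selection animals) - documented configuration;
``desk``
    a reduced design for workstation runs;
``mini``
    a further-reduced design used by the test-suite; drift per
    generation (1/2N) and the ratio of HLD to LLD bottleneck lengths
    mirror the full design.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_sim as gs
from . import io as sio
from .bayesc import BayesCConfig, run_bayesc
from .mixed_model import GwasData, run_wssgblup
from .qtl_eval import (EvalStats, aggregate_replicates, evaluate_cell,
                       hwe_variance_shares, qtl_variance_shares)
from .relmat import build_Ainv, extract_A22, observed_freqs

logger = logging.getLogger("ssgwas")

__all__ = ["ScaleParams", "ExperimentConfig", "SCALES", "simulate_replicate",
           "analyze_replicate", "run_experiment", "cell_rng", "cell_seed"]


@dataclass
class ScaleParams:
    """All size/schedule knobs of one problem scale."""

    n_chromosomes: int
    total_length: float
    n_sim_markers: int          # loci carried through the historical phase
    n_sim_qtl: int
    n_markers: int              # panel retained for analysis
    n_qtl: int
    maf_min: float
    hist_constant_size: int
    hist_n_constant: int
    hist_final_size: int
    hist_decline_hld: int
    hist_decline_lld: int
    exp_generations: int
    offspring_per_dam: int
    sel_generations: int
    n_sires: int
    n_dams: int
    replacement_rate: float
    n_genotyped: int
    genotyped_last_k: int
    blend: float
    bc_chain: int
    bc_burnin: int
    bc_thin: int


SCALES: dict[str, ScaleParams] = {
    "full": ScaleParams(
        n_chromosomes=29, total_length=2333.0,
        n_sim_markers=735_293, n_sim_qtl=7_000,
        n_markers=335_000, n_qtl=1_000, maf_min=0.02,
        hist_constant_size=1000, hist_n_constant=1000, hist_final_size=200,
        hist_decline_hld=2020, hist_decline_lld=1020,
        exp_generations=6, offspring_per_dam=5,
        sel_generations=15, n_sires=240, n_dams=6000, replacement_rate=0.2,
        n_genotyped=2000, genotyped_last_k=3, blend=0.05,
        bc_chain=550_000, bc_burnin=50_000, bc_thin=50,
    ),
    "desk": ScaleParams(
        n_chromosomes=29, total_length=600.0,
        n_sim_markers=15_000, n_sim_qtl=900,
        n_markers=6_000, n_qtl=300, maf_min=0.02,
        hist_constant_size=400, hist_n_constant=400, hist_final_size=100,
        hist_decline_hld=804, hist_decline_lld=404,
        exp_generations=6, offspring_per_dam=5,
        sel_generations=5, n_sires=96, n_dams=2400, replacement_rate=0.2,
        n_genotyped=800, genotyped_last_k=3, blend=0.05,
        bc_chain=55_000, bc_burnin=5_000, bc_thin=5,
    ),
    "mini": ScaleParams(
        n_chromosomes=10, total_length=200.0,
        n_sim_markers=9_000, n_sim_qtl=300,
        n_markers=2_000, n_qtl=100, maf_min=0.02,
        hist_constant_size=200, hist_n_constant=200, hist_final_size=80,
        hist_decline_hld=400, hist_decline_lld=200,
        exp_generations=4, offspring_per_dam=5,
        sel_generations=5, n_sires=24, n_dams=600, replacement_rate=0.2,
        n_genotyped=300, genotyped_last_k=3, blend=0.05,
        bc_chain=6_000, bc_burnin=1_000, bc_thin=5,
    ),
}


@dataclass
class ExperimentConfig:
    """Reproducible description of one experiment."""

    ld_level: str = "hld"
    n_replicates: int = 10
    scale: str = "mini"
    base_seed: int = 1
    h2: float = 0.14
    var_p: float = 1.0
    gamma_shape: float = 0.4
    mutation_rate: float = 1e-4
    pi_values: tuple = (0.99, 0.999)
    n_weight_iterations: int = 3
    params: ScaleParams | None = None

    def __post_init__(self) -> None:
        if self.ld_level not in ("hld", "lld"):
            raise ValueError("ld_level must be 'hld' or 'lld'")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.params is None:
            self.params = SCALES[self.scale]
        elif isinstance(self.params, dict):
            self.params = ScaleParams(**self.params)

    @property
    def trait(self) -> gs.TraitSpec:
        return gs.TraitSpec(h2=self.h2, var_p=self.var_p,
                            gamma_shape=self.gamma_shape)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["pi_values"] = list(self.pi_values)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "pi_values" in d:
            d["pi_values"] = tuple(d["pi_values"])
        return cls(**d)


# stable sub-stream labels: scenarios must share the simulated data
_STREAMS = ["genome", "historical", "panel", "effects", "expansion",
            "selection", "genotyping", "bayesc0", "bayesc1", "ld"]


def cell_seed(base_seed: int, replicate: int, stream: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, replicate, _STREAMS.index(stream)])


def cell_rng(base_seed: int, replicate: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(cell_seed(base_seed, replicate, stream))


def true_qtl_drift_stats(ld_level: str, n_replicates: int = 10,
                         base_seed: int = 1, n_loci: int = 7000,
                         n_qtl: int = 1000,
                         mutation_rate: float = 1e-4,
                         gamma_shape: float = 0.4,
                         schedule: gs.PopSchedule | None = None) -> pd.DataFrame:
    """True-QTL statistics of the demographic design from marginal drift.

    For each replicate: drift every QTL locus's allele frequencies
    through the historical schedule, sample ``n_qtl`` segregating loci,
    draw signed gamma allele effects, and compute each QTL's share of
    genetic variance under Hardy-Weinberg / linkage equilibrium.
    Returns one row per replicate with ``topQTL`` (count of shares
    >= 1%), ``pvar_topQTL`` and ``pvar_1stQTL``.
    """
    if schedule is None:
        schedule = gs.PopSchedule.historical(ld=ld_level)
    sizes = gs.historical_size_path(schedule)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([base_seed, rep, 997]))
        k = rng.integers(2, 5, size=n_loci)
        p = gs.simulate_locus_drift(rng, sizes, k, mutation_rate)
        seg = (p > 0).sum(axis=1) >= 2
        if seg.sum() < n_qtl:
            raise RuntimeError(
                f"only {seg.sum()} segregating QTLs after drift, need {n_qtl}")
        idx = rng.choice(np.nonzero(seg)[0], size=n_qtl, replace=False)
        pf = p[idx]
        eff = rng.gamma(gamma_shape, 1.0, size=pf.shape)
        eff *= np.where(rng.random(pf.shape) < 0.5, -1.0, 1.0)
        eff[pf == 0] = 0.0
        shares = hwe_variance_shares(pf, eff)
        top = shares >= 1.0
        rows.append({"replicate": rep, "topQTL": int(top.sum()),
                     "pvar_topQTL": float(shares[top].sum()),
                     "pvar_1stQTL": float(shares.max())})
    return pd.DataFrame(rows)



@dataclass
class ReplicateData:
    """One simulated dataset plus everything the analyses need."""

    genome: gs.GenomeSpec
    pop: gs.Population
    effects: gs.QTLEffectTable
    gwas: GwasData
    qtl_shares: np.ndarray
    qtl_chrom: np.ndarray
    qtl_pos: np.ndarray


def simulate_replicate(config: ExperimentConfig, replicate: int) -> ReplicateData:
    """Simulate one replicate's population and prepare analysis inputs."""
    p = config.params
    trait = config.trait
    t0 = time.time()

    genome = gs.GenomeSpec.random(
        cell_rng(config.base_seed, replicate, "genome"),
        n_chromosomes=p.n_chromosomes, total_length=p.total_length,
        n_markers=p.n_sim_markers, n_qtl=p.n_sim_qtl,
        mutation_rate=config.mutation_rate)

    hist_sched = gs.PopSchedule.historical(
        constant_size=p.hist_constant_size, n_constant=p.hist_n_constant,
        final_size=p.hist_final_size, ld=config.ld_level,
        n_decline=(p.hist_decline_hld if config.ld_level == "hld"
                   else p.hist_decline_lld))
    hist = gs.simulate_historical(
        genome, hist_sched, cell_rng(config.base_seed, replicate, "historical"))
    logger.info("replicate %d: historical phase done (%.1fs)",
                replicate, time.time() - t0)

    genome, hist = gs.select_segregating_loci(
        hist, genome, p.maf_min, p.n_markers, p.n_qtl,
        cell_rng(config.base_seed, replicate, "panel"))
    effects = gs.assign_qtl_effects(
        genome, trait, hist, cell_rng(config.base_seed, replicate, "effects"))

    pop = gs.simulate_expansion(
        hist, genome, gs.PopSchedule.expansion(p.exp_generations,
                                               p.offspring_per_dam),
        cell_rng(config.base_seed, replicate, "expansion"))
    pop = gs.simulate_selection(
        pop, trait, genome, effects,
        gs.PopSchedule.selection(p.sel_generations, p.n_sires, p.n_dams,
                                 p.replacement_rate),
        cell_rng(config.base_seed, replicate, "selection"))
    pop = gs.genotype_females(
        pop, p.n_genotyped, p.genotyped_last_k,
        cell_rng(config.base_seed, replicate, "genotyping"))
    logger.info("replicate %d: population complete, %d animals (%.1fs)",
                replicate, pop.n_animals, time.time() - t0)

    # analysis inputs shared by every cell
    rec_rows = np.nonzero(~np.isnan(pop.phenotype))[0]
    geno_idx = np.nonzero(pop.genotyped)[0]
    Ainv = build_Ainv(pop.sire, pop.dam)
    A22 = extract_A22(Ainv, geno_idx)
    dosages = gs.marker_dosages(pop, genome)
    gwas = GwasData(
        y=pop.phenotype[rec_rows], rec_animal=rec_rows,
        X=np.ones((len(rec_rows), 1)), Ainv=Ainv, A22=A22,
        geno_idx=geno_idx, dosages=dosages, lam=trait.lam, blend=p.blend)

    # truth: variance shares over the phenotyped cohort
    qvals = gs.qtl_genetic_values(pop, genome, effects)[rec_rows]
    shares = qtl_variance_shares(qvals, tbv=pop.tbv[rec_rows])
    qi = genome.qtl_index
    return ReplicateData(genome=genome, pop=pop, effects=effects, gwas=gwas,
                         qtl_shares=shares, qtl_chrom=genome.chrom[qi],
                         qtl_pos=genome.pos_cm[qi])


def analyze_replicate(config: ExperimentConfig, replicate: int,
                      data: ReplicateData,
                      cells: list[str] | None = None) -> dict[str, EvalStats]:
    """Run the analysis cells on one simulated dataset and score them."""
    p = config.params
    genome = data.genome
    mk = genome.marker_index
    stats: dict[str, EvalStats] = {}

    def score(name: str, u: np.ndarray) -> None:
        stats[name] = evaluate_cell(
            u, data.gwas.dosages, genome.chrom[mk], genome.pos_cm[mk],
            genome.chrom_lengths, data.qtl_shares, data.qtl_chrom,
            data.qtl_pos)

    want = cells or (["BayesC_pi%g" % v for v in config.pi_values] +
                     [f"{s}w{w}" for s in ("SI", "SII")
                      for w in range(1, config.n_weight_iterations + 1)])

    for i, pi in enumerate(config.pi_values):
        name = "BayesC_pi%g" % pi
        if name not in want:
            continue
        cfg = BayesCConfig(pi_excluded=pi, chain_length=p.bc_chain,
                           burn_in=p.bc_burnin, thin=p.bc_thin,
                           var_a=config.trait.var_a, var_e=config.trait.var_e)
        geno_phe = data.gwas.y[np.isin(data.gwas.rec_animal,
                                       data.gwas.geno_idx)]
        seed = int(cell_seed(config.base_seed, replicate,
                             f"bayesc{i}").generate_state(1)[0] & 0x7FFFFFFF)
        post = run_bayesc(geno_phe, data.gwas.dosages, cfg, seed)
        score(name, post.effect_mean)

    for scen in ("SI", "SII"):
        if not any(c.startswith(f"{scen}w") for c in want):
            continue
        iters = run_wssgblup(data.gwas, scenario=scen,
                             n_iterations=config.n_weight_iterations)
        for it in iters:
            name = f"{scen}w{it['iteration']}"
            if name in want:
                score(name, it["u_hat"])
    return stats


def run_experiment(config: ExperimentConfig, out_dir=None,
                   write_artifacts: bool = True) -> pd.DataFrame:
    """Run every replicate and aggregate the summary table.

    A failed cell marks the replicate incomplete; aggregation then
    excludes it with a warning.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    all_stats: list[dict[str, EvalStats]] = []
    for rep in range(config.n_replicates):
        t0 = time.time()
        try:
            data = simulate_replicate(config, rep)
            stats = analyze_replicate(config, rep, data)
        except Exception:
            logger.exception("replicate %d failed; excluded from aggregation",
                             rep)
            continue
        all_stats.append(stats)
        if out is not None and write_artifacts:
            rdir = out / f"replicate_{rep:02d}"
            rdir.mkdir(exist_ok=True)
            sio.write_pedigree_csv(rdir / "pedigree.csv", data.pop)
            sio.write_phenotypes_csv(rdir / "phenotypes.csv", data.pop)
            sio.write_plink(rdir / "genotypes", data.pop, data.genome)
            sio.write_qtl_truth(rdir / "qtl_truth.tsv", data.genome,
                                data.effects, data.qtl_shares)
            rows = [{"cell": k, **dataclasses.asdict(v)}
                    for k, v in stats.items()]
            pd.DataFrame(rows).to_csv(rdir / "cell_stats.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        logger.info("replicate %d finished in %.1fs", rep, time.time() - t0)

    if not all_stats:
        raise RuntimeError("all replicates failed")
    if len(all_stats) < config.n_replicates:
        logger.warning("aggregating %d of %d replicates",
                       len(all_stats), config.n_replicates)
    table = aggregate_replicates(all_stats)
    if out is not None:
        table.to_csv(out / "summary.tsv", sep="\t", index=False,
                     float_format="%.6g")
    return table
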