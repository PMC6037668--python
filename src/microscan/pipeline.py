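"""End-to-end pipeline: simulate -> prep -> select -> scan -> cluster -> overlap -> report.

Each stage reads the previous stage's TSV outputs from the run directory
and writes its own, so stages can be re-run individually.  A manifest
records the seed, a hash of the configuration and package versions; all
outputs are deterministic functions of (config, seed) -- no timestamps
are written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import microscan
from microscan import io as mio
from microscan.clustering import (
    arcsine_viz,
    multiscale_bootstrap,
    sparsify,
    to_newick,
)
from microscan.markers import greedy_select_markers, spearman_matrix, threshold_graph, verify_coverage
from microscan.overlap import build_overlap_table
from microscan.phenotypes import phi_matrix, prevalence_filter
from microscan.scan import run_scan_variants
from microscan.synthetic import PlantedEffect, SimConfig, read_fixture, simulate_cohort, write_fixture

STAGES = ("simulate", "prep", "select", "scan", "cluster", "overlap", "report")

__all__ = ["RunConfig", "STAGES", "run_pipeline", "make_report", "default_reference_config"]


@dataclass
class RunConfig:
    """Pipeline settings; thresholds default to the reference analysis values."""

    seed: int
    simulate: dict | None = None          # SimConfig fields (seed injected)
    phenotypes_path: str | None = None    # real-data path inputs
    traits_path: str | None = None
    covariates_path: str | None = None
    prevalence_threshold: float = 0.01
    reference_n: int | None = None        # wider-cohort size; defaults to n samples
    edge_threshold: float = 0.8
    alpha: float = 0.05                   # nominal significance
    fdr_alpha: float = 0.05
    min_assoc: int = 10                   # overlap eligibility set size
    n_boot: int = 1000
    scales: list[float] | None = None
    engine: str = "lmm"
    fdr_scope: str = "global"
    variants: tuple[str, ...] = ("full", "no_bmi", "no_age", "neither")
    medication_prefix: str = "med_"
    cluster_variant: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_threshold < 1.0:
            raise ValueError("prevalence_threshold must be in (0,1)")
        if not 0.0 < self.edge_threshold < 1.0:
            raise ValueError("edge_threshold must be in (0,1)")
        for name in ("alpha", "fdr_alpha"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        if self.min_assoc < 0:
            raise ValueError("min_assoc must be nonnegative")
        if self.simulate is None and not (
            self.phenotypes_path and self.traits_path and self.covariates_path
        ):
            raise ValueError("either 'simulate' or the three input table paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        out = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        if self.simulate is not None:
            sim = dict(self.simulate)
            if "planted_effects" in sim:
                sim["planted_effects"] = [
                    list(e) if not isinstance(e, PlantedEffect)
                    else [e.phenotype, e.trait, e.log_odds_per_sd]
                    for e in sim["planted_effects"]
                ]
            out["simulate"] = sim
        return out

    def sim_config(self) -> SimConfig:
        if self.simulate is None:
            raise ValueError("config has no 'simulate' section")
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        effects = kwargs.get("planted_effects", [])
        kwargs["planted_effects"] = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(e[0], e[1], float(e[2]))
            for e in effects
        ]
        kwargs["phenotype_specs"] = [tuple(x) for x in kwargs.get("phenotype_specs", [])]
        kwargs["phi_targets"] = [tuple(x) for x in kwargs.get("phi_targets", [])]
        return SimConfig(**kwargs)


def _stage_seed(seed: int, stage: str) -> int:
    offset = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(100 + offset,))
    return int(ss.generate_state(1)[0] % (2**31))


def default_reference_config(seed: int) -> RunConfig:
    """The reference synthetic analysis: n=1000 twins cohort, 68 traits, 20 phenotypes.

    Twelve diseases and eight medications at realistic prevalences; one
    strongly co-prescribed disease-medication pair (the metformin/T2D
    pattern), one comorbidity block, shared and disjoint planted effects.
    """
    diseases = [
        ("disease_t2d", 0.08), ("disease_hypertension", 0.30),
        ("disease_hypercholesterolaemia", 0.35), ("disease_osteoarthritis", 0.30),
        ("disease_anxiety", 0.25), ("disease_asthma", 0.12),
        ("disease_constipation", 0.10), ("disease_ibs", 0.10),
        ("disease_food_allergy", 0.06), ("disease_recurrent_uti", 0.07),
        ("disease_ibd", 0.02), ("disease_gout", 0.03),
    ]
    medications = [
        ("med_metformin", 0.05), ("med_statins", 0.20), ("med_ppi", 0.15),
        ("med_ssri", 0.10), ("med_paracetamol", 0.25), ("med_opioids", 0.08),
        ("med_antibiotics", 0.10), ("med_calcium", 0.15),
    ]
    # feasibility: a phi of 0.45 between two rare phenotypes already implies
    # a latent correlation near 0.85, so co-targets on shared phenotypes stay low
    phi_targets = [
        ("disease_t2d", "med_metformin", 0.45),
        ("disease_hypertension", "disease_hypercholesterolaemia", 0.30),
        ("disease_t2d", "disease_hypertension", 0.15),
        ("disease_anxiety", "med_ssri", 0.35),
        ("disease_hypercholesterolaemia", "med_statins", 0.40),
    ]
    planted = [
        PlantedEffect("disease_t2d", "block01_t1", -0.8),
        PlantedEffect("disease_t2d", "block02_t1", 0.6),
        PlantedEffect("med_metformin", "block01_t1", -0.7),
        PlantedEffect("med_metformin", "block02_t1", 0.5),
        PlantedEffect("disease_constipation", "block03_t2", 0.7),
        PlantedEffect("disease_ibs", "block04_t1", -0.6),
        PlantedEffect("disease_ibd", "block05_t1", -0.9),
        PlantedEffect("med_ppi", "block06_t1", 0.7),
        PlantedEffect("med_antibiotics", "block07_t1", -0.7),
        PlantedEffect("disease_recurrent_uti", "block07_t1", -0.5),
    ]
    # clean-signal rho 0.9 with mild technical noise keeps observed within-block
    # Spearman above the 0.8 edge threshold, so the 68 traits collapse to ~17 markers
    sim = dict(
        n_individuals=1000,
        n_twin_pairs=300,
        phenotype_specs=diseases + medications,
        phi_targets=phi_targets,
        n_trait_blocks=17,
        traits_per_block=4,
        within_block_rho=0.9,
        batch_effect_sd=0.1,
        depth_effect_sd=0.05,
        planted_effects=planted,
    )
    # eligibility set-size scaled to the ~17 markers this cohort scans:
    # the default of 10 is proportioned to a 68-marker scan (10/68 ~ 2/17)
    return RunConfig(seed=seed, simulate=sim, n_boot=500, min_assoc=2)


@dataclass
class _Log:
    lines: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: Path) -> None:
        path.write_text("".join(line + "\n" for line in self.lines))


def _load_fixture_tables(run_dir: Path, config: RunConfig):
    fixture_dir = run_dir / "fixture"
    if (fixture_dir / "phenotypes.tsv").exists():
        fx = read_fixture(fixture_dir)
        return fx.phenotypes, fx.traits, fx.covariates
    paths = [config.phenotypes_path, config.traits_path, config.covariates_path]
    if not all(paths):
        raise FileNotFoundError(
            "no simulated fixture found and no input table paths configured"
        )
    return tuple(mio.read_matrix(p) for p in paths)


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: tuple[str, ...] | None = None
) -> Path:
    """Execute the requested stages (all by default) into ``out_dir``."""
    stages = STAGES if stages is None else tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # fail early on missing real-data inputs
    for p in (config.phenotypes_path, config.traits_path, config.covariates_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input table does not exist: {p}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _Log()
    ran: list[str] = []

    try:
        if "simulate" in stages and config.simulate is not None:
            fixture = simulate_cohort(config.sim_config())
            fdir = out_dir / "fixture"
            fdir.mkdir(exist_ok=True)
            write_fixture(fixture, fdir)
            log.add(f"simulate: n={len(fixture.phenotypes)} samples, "
                    f"{fixture.traits.shape[1]} traits, "
                    f"{fixture.phenotypes.shape[1]} phenotypes, "
                    f"{len(fixture.truth)} planted effects")
            ran.append("simulate")

        phenotypes, traits, covariates = _load_fixture_tables(out_dir, config)

        if "prep" in stages:
            ref_n = config.reference_n or len(phenotypes)
            filtered = prevalence_filter(phenotypes, ref_n, config.prevalence_threshold)
            pm = phi_matrix(filtered)
            pdir = out_dir / "prep"
            mio.write_matrix(filtered, pdir / "phenotypes_filtered.tsv", "sample_id")
            mio.write_matrix(pm.phi, pdir / "phi.tsv", "phenotype")
            mio.write_matrix(pm.p, pdir / "phi_p.tsv", "phenotype")
            mio.write_matrix(pm.n, pdir / "phi_n.tsv", "phenotype")
            (pdir / "dropped_phenotypes.txt").write_text(
                "".join(x + "\n" for x in filtered.attrs["dropped_phenotypes"])
            )
            log.add(f"prep: retained {filtered.shape[1]} phenotypes, dropped "
                    f"{len(filtered.attrs['dropped_phenotypes'])}")
            ran.append("prep")

        if "select" in stages:
            corr = spearman_matrix(traits)
            graph = threshold_graph(corr, config.edge_threshold)
            selection = greedy_select_markers(graph, seed=_stage_seed(config.seed, "select"))
            report = verify_coverage(selection, graph)
            if not report.ok:
                raise RuntimeError(f"marker selection violated coverage: {report.violations}")
            mdir = out_dir / "markers"
            mdir.mkdir(exist_ok=True)
            mio.write_matrix(corr, mdir / "spearman.tsv", "trait")
            edges = pd.DataFrame(
                [(a, b, d["weight"]) for a, b, d in graph.edges(data=True)],
                columns=["trait_a", "trait_b", "rho"],
            ).sort_values(["trait_a", "trait_b"], ignore_index=True)
            mio.write_frame(edges, mdir / "edges.tsv")
            mio.write_frame(
                pd.DataFrame(
                    [(r["iteration"], r["marker"], r["degree"], r["n_tied"])
                     for r in selection.selection_log],
                    columns=["iteration", "marker", "degree_at_selection", "n_tied"],
                ),
                mdir / "markers.tsv",
            )
            mio.write_frame(
                pd.DataFrame(
                    [(t, ";".join(ms)) for t, ms in sorted(selection.covered_by.items())],
                    columns=["discarded_trait", "covering_markers"],
                ),
                mdir / "coverage.tsv",
            )
            log.add(f"select: {len(selection.markers)} markers from {traits.shape[1]} traits "
                    f"({graph.number_of_edges()} edges at >|{config.edge_threshold}|)")
            ran.append("select")

        if "scan" in stages:
            markers_path = out_dir / "markers" / "markers.tsv"
            if not markers_path.exists():
                raise FileNotFoundError("scan requires the select stage output (markers/markers.tsv)")
            marker_names = mio.read_frame(markers_path)["marker"].tolist()
            pheno_path = out_dir / "prep" / "phenotypes_filtered.tsv"
            pheno = mio.read_matrix(pheno_path) if pheno_path.exists() else phenotypes
            scan = run_scan_variants(
                pheno, traits[marker_names], covariates,
                engine=config.engine, scope=config.fdr_scope, variants=config.variants,
            )
            sdir = out_dir / "scan"
            for variant, res in scan.results.items():
                mio.write_frame(res, sdir / f"results_{variant}.tsv")
            mio.write_matrix(scan.beta_correlations, sdir / "beta_correlations.tsv", "variant")
            n_sig = int((scan.results[config.cluster_variant]["q"] < config.fdr_alpha).sum())
            log.add(f"scan: {len(marker_names)} markers x {pheno.shape[1]} phenotypes "
                    f"x {len(config.variants)} variants; {n_sig} FDR-significant "
                    f"({config.cluster_variant} variant)")
            ran.append("scan")

        if "cluster" in stages:
            res_path = out_dir / "scan" / f"results_{config.cluster_variant}.tsv"
            if not res_path.exists():
                raise FileNotFoundError("cluster requires the scan stage output")
            results = mio.read_frame(res_path)
            disease_cols = [
                c for c in results["phenotype"].unique()
                if not str(c).startswith(config.medication_prefix)
            ]
            subset = results[results["phenotype"].isin(disease_cols)]
            matrix = sparsify(subset, alpha=config.alpha)
            tree = multiscale_bootstrap(
                matrix, axis="rows", n_boot=config.n_boot,
                scales=tuple(config.scales) if config.scales else None,
                seed=_stage_seed(config.seed, "cluster"),
            )
            cdir = out_dir / "cluster"
            cdir.mkdir(exist_ok=True)
            mio.write_matrix(matrix, cdir / "beta_matrix.tsv", "trait")
            mio.write_matrix(arcsine_viz(matrix), cdir / "heatmap_arcsine.tsv", "trait")
            (cdir / "trait_dendrogram.newick").write_text(to_newick(tree) + "\n")
            support = tree.support.copy()
            support["members"] = support["members"].map(lambda t: ";".join(t))
            mio.write_matrix(support, cdir / "trait_clusters.tsv", "cluster_id")
            pheno_dend = multiscale_bootstrap(
                matrix, axis="columns", n_boot=config.n_boot,
                scales=tuple(config.scales) if config.scales else None,
                seed=_stage_seed(config.seed, "cluster") + 1,
            )
            (cdir / "phenotype_dendrogram.newick").write_text(to_newick(pheno_dend) + "\n")
            n_sig = int(tree.support["significant"].sum())
            log.add(f"cluster: {matrix.shape[0]} traits x {matrix.shape[1]} phenotypes; "
                    f"{n_sig} significant trait clusters (AU > 0.95)")
            ran.append("cluster")

        if "overlap" in stages:
            res_path = out_dir / "scan" / f"results_{config.cluster_variant}.tsv"
            if not res_path.exists():
                raise FileNotFoundError("overlap requires the scan stage output")
            results = mio.read_frame(res_path)
            pheno_path = out_dir / "prep" / "phenotypes_filtered.tsv"
            pheno = mio.read_matrix(pheno_path) if pheno_path.exists() else phenotypes
            med_cols = [c for c in pheno.columns if str(c).startswith(config.medication_prefix)]
            dis_cols = [c for c in pheno.columns if c not in med_cols]
            if med_cols and dis_cols:
                table = build_overlap_table(
                    results[results["phenotype"].isin(dis_cols)],
                    results[results["phenotype"].isin(med_cols)],
                    pheno[dis_cols], pheno[med_cols],
                    alpha=config.alpha, fdr_alpha=config.fdr_alpha,
                    min_assoc=config.min_assoc,
                )
                odir = out_dir / "overlap"
                mio.write_frame(table, odir / "overlap.tsv")
                mio.write_frame(
                    table.loc[table["eligible"], ["disease", "medication", "phi", "jaccard"]],
                    odir / "phi_vs_jaccard.tsv",
                )
                log.add(f"overlap: {len(table)} pairs, {int(table['eligible'].sum())} eligible")
            else:
                log.add("overlap: skipped (no disease/medication split under prefix "
                        f"{config.medication_prefix!r})")
            ran.append("overlap")

        if "report" in stages:
            make_report(out_dir, alpha=config.alpha, fdr_alpha=config.fdr_alpha,
                        variant=config.cluster_variant)
            log.add("report: association counts and cases-vs-associations written")
            ran.append("report")
    except Exception as exc:
        log.add(f"ABORTED at stage after {ran}: {exc}")
        log.write(out_dir / "log.txt")
        raise

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "microscan",
        "version": microscan.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages_run": ran,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.write(out_dir / "log.txt")
    return out_dir


def make_report(
    run_dir: str | Path,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    variant: str = "full",
) -> Path:
    """Summaries of a completed run: per-phenotype association counts by direction.

    Every scanned phenotype appears, including those with zero
    associations; the direction split (positive/negative beta) sums to the
    total count.
    """
    run_dir = Path(run_dir)
    res_path = run_dir / "scan" / f"results_{variant}.tsv"
    missing = [s for s, p in (("scan", res_path),) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")
    results = mio.read_frame(res_path)
    ok = results[results["status"] == "ok"]
    rows = []
    for pheno in sorted(results["phenotype"].unique()):
        sub = ok[ok["phenotype"] == pheno]
        nom = sub[sub["p"] < alpha]
        sig = sub[sub["q"] < fdr_alpha]
        n_cases = int(results.loc[results["phenotype"] == pheno, "n_cases"].max())
        rows.append(
            {
                "phenotype": pheno,
                "n_cases": n_cases,
                "nominal_total": len(nom),
                "nominal_positive": int((nom["beta"] > 0).sum()),
                "nominal_negative": int((nom["beta"] < 0).sum()),
                "fdr_total": len(sig),
                "fdr_positive": int((sig["beta"] > 0).sum()),
                "fdr_negative": int((sig["beta"] < 0).sum()),
            }
        )
    counts = pd.DataFrame(rows)
    rdir = run_dir / "report"
    mio.write_frame(counts, rdir / "association_counts.tsv")
    mio.write_frame(
        counts[["phenotype", "n_cases", "nominal_total"]],
        rdir / "cases_vs_associations.tsv",
    )
    return rdir
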