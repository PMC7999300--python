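"""End-to-end orchestration: simulate a cohort, analyze it, write a report.

The default cohort mirrors a four-tumour design: sacrifice at 2, 10, 20 and
25 weeks, Tp53 inactivation only in the two late tumours, two organoids from
the 20-week tumour, and seven organoids plus primary/metastatic bulk
biopsies from the 25-week one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clonality, cna, genesize, phylo, rates, signatures
from .genome import (
    GenomeConfig,
    GenomeModel,
    build_genome,
    read_fasta,
    read_genes_bed,
    read_timing_bed,
    triplet_census,
    write_fasta,
    write_genes_bed,
    write_timing_bed,
)
from .sim import CloneTree, SimConfig, sample_bulk, sample_organoid, simulate_lineage
from .variants import (
    PresenceThresholds,
    read_calls_tsv,
    vaf_summary,
    write_calls_tsv,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class MouseSpec:
    name: str
    duration_weeks: float
    tp53_week: float | None
    n_organoids: int
    n_primary_biopsies: int = 0
    n_metastases: int = 0
    purity: float = 0.6


@dataclass
class RunConfig:
    """One config drives both simulation and analysis; every stochastic
    stage derives its own stream from ``seed``."""

    seed: int = 0
    depth_mean: float = 100.0
    bin_width: int = 50_000
    mice: list[MouseSpec] = field(
        default_factory=lambda: [
            MouseSpec("mI", 2.0, None, 6),
            MouseSpec("mII", 10.0, None, 7),
            MouseSpec("mIII", 20.0, 5.0, 2),
            MouseSpec("mIV", 25.0, 5.0, 7, n_primary_biopsies=2, n_metastases=4),
        ]
    )
    presence: PresenceThresholds = field(default_factory=PresenceThresholds)
    sns_rate_per_week: float = 0.8
    cna_rate_per_week_tp53null: float = 0.10
    segmentation_min_bins: int = 5
    segmentation_t_threshold: float = 5.0
    permutation_reps: int = 100_000
    size_threshold_bp: int = 150_000

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mice" in raw:
            raw["mice"] = [MouseSpec(**m) for m in raw["mice"]]
        if "presence" in raw:
            raw["presence"] = PresenceThresholds(**raw["presence"])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)


def _diploid_bins(
    genome: GenomeModel, depth_mean: float, bin_width: int, rng: np.random.Generator
) -> cna.DepthBins:
    rows = []
    for chrom, seq in genome.chromosomes.items():
        pos, n = 0, len(seq)
        while pos < n:
            end = min(pos + bin_width, n)
            lam = depth_mean * (end - pos) / bin_width
            rows.append((chrom, pos, end, int(rng.poisson(lam))))
            pos = end
    return cna.DepthBins.from_rows(rows)


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic dataset plus truth files; deterministic
    for a fixed config.  Partial output is removed on failure."""
    out = Path(outdir)
    if any(m.n_organoids < 1 for m in config.mice):
        raise ValueError("every mouse needs at least one organoid")
    try:
        out.mkdir(parents=True, exist_ok=True)
        _run_simulate(config, out)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def _run_simulate(config: RunConfig, out: Path) -> None:
    genome = build_genome(GenomeConfig(), seed=config.seed)
    write_fasta(genome, str(out / "genome.fa"))
    write_genes_bed(genome.genes, str(out / "genes.bed"))
    write_timing_bed(genome.timing_domains, str(out / "timing.bed"))
    (out / "config.json").write_text(config.to_json())

    manifest: dict = {"mice": [], "samples": []}
    for m_idx, mouse in enumerate(config.mice):
        mouse_rng = np.random.default_rng([config.seed, m_idx])
        n_leaves = mouse.n_organoids + mouse.n_metastases
        branchings = sorted(
            mouse_rng.uniform(0.2 * mouse.duration_weeks, 0.9 * mouse.duration_weeks,
                              size=max(0, n_leaves - 1)).tolist()
        )
        sim_config = SimConfig(
            sns_rate_per_week=config.sns_rate_per_week,
            cna_rate_per_week_tp53null=config.cna_rate_per_week_tp53null,
            driver_schedule={"apc": 0.0, "kras": 0.0, "tp53": mouse.tp53_week},
            branching_times=branchings,
            duration_weeks=mouse.duration_weeks,
            seed=int(mouse_rng.integers(2**31)),
        )
        tree = simulate_lineage(genome, sim_config)
        leaves = tree.leaves()
        if len(leaves) < n_leaves:
            raise RuntimeError(f"{mouse.name}: not enough leaves simulated")
        (out / f"{mouse.name}.truth.json").write_text(tree.to_json())
        (out / f"{mouse.name}.truth.nwk").write_text(tree.to_newick() + "\n")

        mouse_entry = {"name": mouse.name, "duration_weeks": mouse.duration_weeks,
                       "tp53_week": mouse.tp53_week, "normal": f"{mouse.name}_liver"}
        manifest["mice"].append(mouse_entry)

        def emit(sample_id: str, role: str, calls, bins, node_id: str | None) -> None:
            write_vcf(calls, str(out / f"{sample_id}.vcf"), sample_id=sample_id)
            write_calls_tsv(calls, str(out / f"{sample_id}.calls.tsv"))
            bins.to_tsv(str(out / f"{sample_id}.bins.tsv"))
            manifest["samples"].append(
                {"sample_id": sample_id, "mouse": mouse.name, "role": role,
                 "node_id": node_id,
                 "tp53_null": bool(tree.nodes[node_id].tp53_mut) if node_id else False}
            )

        for i in range(mouse.n_organoids):
            node_id = leaves[i]
            sample_id = f"{mouse.name}_O{i + 1}"
            calls, bins = sample_organoid(
                tree, node_id, genome, depth_mean=config.depth_mean,
                seed=int(mouse_rng.integers(2**31)), sample_id=sample_id,
                bin_width=config.bin_width,
            )
            emit(sample_id, "organoid", calls, bins, node_id)
        for i in range(mouse.n_metastases):
            node_id = leaves[mouse.n_organoids + i]
            sample_id = f"{mouse.name}_MT{i + 1}"
            calls, bins = sample_bulk(
                tree, [(node_id, 1.0)], genome, purity=0.7,
                depth_mean=config.depth_mean, seed=int(mouse_rng.integers(2**31)),
                sample_id=sample_id, bin_width=config.bin_width,
            )
            emit(sample_id, "metastasis", calls, bins, node_id)
        for i in range(mouse.n_primary_biopsies):
            fractions = mouse_rng.dirichlet(np.ones(mouse.n_organoids))
            mixture = [(leaves[j], float(f)) for j, f in enumerate(fractions)]
            sample_id = f"{mouse.name}_PT{i + 1}"
            calls, bins = sample_bulk(
                tree, mixture, genome, purity=mouse.purity,
                depth_mean=config.depth_mean, seed=int(mouse_rng.integers(2**31)),
                sample_id=sample_id, bin_width=config.bin_width,
            )
            emit(sample_id, "primary_biopsy", calls, bins, None)
        # matched normal + panel of normals (all diploid)
        for tissue in ("liver", "kidney", "spleen"):
            sample_id = f"{mouse.name}_{tissue}"
            bins = _diploid_bins(
                genome, config.depth_mean, config.bin_width,
                np.random.default_rng(int(mouse_rng.integers(2**31))),
            )
            bins.to_tsv(str(out / f"{sample_id}.bins.tsv"))
            manifest["samples"].append(
                {"sample_id": sample_id, "mouse": mouse.name, "role": "normal",
                 "node_id": None, "tp53_null": False}
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------


def run_analyze(dataset: str | Path, outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Analyze a simulated (or equivalently formatted) dataset directory and
    write report.json plus per-stage tables; returns the report dict."""
    dataset = Path(dataset)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig.from_json((dataset / "config.json").read_text())

    genome = GenomeModel(
        chromosomes=read_fasta(str(dataset / "genome.fa")),
        genes=read_genes_bed(str(dataset / "genes.bed")),
        timing_domains=read_timing_bed(str(dataset / "timing.bed")),
    )
    manifest = json.loads((dataset / "manifest.json").read_text())
    samples = manifest["samples"]
    report: dict = {"mice": {}}

    calls_by_sample = {}
    for s in samples:
        if s["role"] == "normal":
            continue
        calls_by_sample[s["sample_id"]] = read_calls_tsv(
            str(dataset / f"{s['sample_id']}.calls.tsv")
        )

    # --- per-role VAF summary -------------------------------------------
    by_role: dict[str, list] = {}
    for s in samples:
        if s["role"] == "normal":
            continue
        by_role.setdefault(s["role"], []).extend(calls_by_sample[s["sample_id"]])
    vafs = vaf_summary(by_role)
    vafs.to_csv(out / "vaf_summary.tsv", sep="\t", index=False)
    report["vaf_summary"] = vafs.to_dict(orient="records")

    # --- spectra over organoid variants ---------------------------------
    organoid_variants = {}
    for s in samples:
        if s["role"] == "organoid":
            for c in calls_by_sample[s["sample_id"]]:
                organoid_variants[c.variant.key] = c.variant
    spec = signatures.spectrum96(list(organoid_variants.values()), genome)
    census = triplet_census(genome, genome.territory_intervals("coding"))
    spec_norm = signatures.normalize_spectrum(spec, census)
    fit = signatures.fit_signatures(spec_norm)
    spec.to_tsv(str(out / "spectrum_raw.tsv"))
    spec_norm.to_tsv(str(out / "spectrum_normalized.tsv"))
    report["signature_weights"] = fit.weights
    report["signature_residual"] = fit.residual_norm

    # --- gene-size enrichment -------------------------------------------
    assignments = []
    for v in organoid_variants.values():
        gene = next(
            (g for g in genome.genes if g.chrom == v.chrom and g.start <= v.pos < g.end),
            None,
        )
        if gene is not None:
            assignments.append(gene.gene_id)
    if assignments:
        perm = genesize.permutation_test(
            assignments, genome.genes,
            size_threshold_bp=config.size_threshold_bp,
            n_reps=config.permutation_reps, seed=config.seed,
        )
        report["gene_size_test"] = dataclasses.asdict(perm)
        ratios = genesize.obs_exp_ratios(assignments, genome.genes)
        ratios.to_csv(out / "gene_size_ratios.tsv", sep="\t", index=False)

    # --- per-mouse sharing, phylogeny, CNA ------------------------------
    tp53_cna_rows = []
    regression_points = []
    burden_groups: dict[str, list[float]] = {}
    for mouse in manifest["mice"]:
        name = mouse["name"]
        mouse_samples = [s for s in samples if s["mouse"] == name and s["role"] != "normal"]
        organoids = [s for s in mouse_samples if s["role"] == "organoid"]
        mreport: dict = {}

        for s in organoids:
            n_sns = len(calls_by_sample[s["sample_id"]])
            regression_points.append((mouse["duration_weeks"], float(n_sns)))
            burden_groups.setdefault(name, []).append(float(n_sns))

        if len(organoids) >= 2:
            tables = {s["sample_id"]: calls_by_sample[s["sample_id"]] for s in mouse_samples}
            roles = {s["sample_id"]: s["role"] for s in mouse_samples}
            matrix = clonality.build_presence_matrix(tables, roles, config.presence)
            classes = clonality.classify_sharing(matrix)
            mreport["sharing"] = clonality.sharing_counts(classes)
            mreport["seeding_events"] = clonality.count_seeding_events(matrix)
            matrix.to_tsv(str(out / f"{name}.matrix.tsv"), str(out / f"{name}.matrix.json"))

            char_sets = phylo.matrix_character_sets(matrix)
            groups = phylo.group_characters(char_sets)
            accepted, conflicts = phylo.check_compatibility(groups)
            tree = phylo.build_tree(
                accepted,
                [s["sample_id"] for s in mouse_samples if s["role"] in ("organoid", "metastasis")],
            )
            (out / f"{name}.tree.nwk").write_text(phylo.write_newick(tree) + "\n")
            (out / f"{name}.conflicts.tsv").write_text(phylo.conflict_report(conflicts))
            mreport["root_out_degree"] = tree.root_out_degree
            mreport["n_conflicting_groups"] = len(conflicts)

        # CNA calling per organoid against the matched normal
        normal_bins = cna.DepthBins.from_tsv(str(dataset / f"{mouse['normal']}.bins.tsv"))
        panel = []
        for tissue in ("kidney", "spleen"):
            path = dataset / f"{name}_{tissue}.bins.tsv"
            if path.exists():
                pbins = cna.DepthBins.from_tsv(str(path))
                pratios = cna.log2_ratios(pbins, normal_bins)
                panel.append(cna.segment(
                    pratios, min_bins=config.segmentation_min_bins,
                    t_threshold=config.segmentation_t_threshold,
                ))
        mouse_segments = {}
        for s in organoids:
            bins = cna.DepthBins.from_tsv(str(dataset / f"{s['sample_id']}.bins.tsv"))
            ratios = cna.log2_ratios(bins, normal_bins)
            segs = cna.segment(
                ratios, min_bins=config.segmentation_min_bins,
                t_threshold=config.segmentation_t_threshold,
            )
            segs = cna.filter_panel(segs, panel)
            cna.write_segments_bed(segs, str(out / f"{s['sample_id']}.segments.bed"))
            mouse_segments[s["sample_id"]] = segs
            has_large = any(x.large_scale for x in segs)
            tp53_cna_rows.append((bool(s["tp53_null"]), has_large))
        mreport["n_large_scale_cna"] = {
            sid: sum(1 for x in segs if x.large_scale) for sid, segs in mouse_segments.items()
        }
        report["mice"][name] = mreport

    # --- cohort-level statistics ----------------------------------------
    assoc = cna.associate_cna_genotype(tp53_cna_rows)
    report["tp53_cna_association"] = {
        "table": assoc.table, "p_value": assoc.p_value, "odds_ratio": assoc.odds_ratio,
    }
    if len({w for w, _ in regression_points}) >= 2:
        reg = rates.fit_rate_regression(regression_points)
        report["rate_regression"] = dataclasses.asdict(reg)
    if len(burden_groups) >= 2 and all(len(v) >= 2 for v in burden_groups.values()):
        burden = rates.compare_burden(burden_groups)
        burden.to_csv(out / "burden_comparison.tsv", sep="\t", index=False)
        report["burden_comparison"] = burden.to_dict(orient="records")
    strata = rates.timing_strata(list(organoid_variants.values()), genome)
    strata.to_csv(out / "timing_strata.tsv", sep="\t", index=False)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
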