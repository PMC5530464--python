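"""Self-contained toy genomes, regulatory networks and tumor cohorts with
implanted ground truth.

The generator emulates the statistical structure of a whole-genome tumor
cohort at desk scale: a small multi-chromosome genome with genes, promoter
windows, distal enhancers and open-chromatin peaks; a TF network with a
heavy-tailed out-degree distribution and designated hubs; and a cohort with
uniform background SNVs (Beta-distributed impact scores), log-normal-length
background SVs at the per-sample rate seen in prostate whole genomes
(~30 events), array-style methylation beta values, and log-scale expression
responding additively to deletions, promoter hyper-methylation and upstream
hub dosage. Drivers (SNV hotspots, recurrent SVs over a designated element,
methylation shifts) are implanted at a configured penetrance and recorded in
a ground-truth manifest.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import genome_io, network_build
from .elements import Element, ElementCatalog, write_elements
from .genome_io import (
    ChromosomeMap,
    GeneModel,
    GenomicInterval,
    InputError,
    SVSet,
    VariantSet,
)
from .network_build import BindingCall, RegulatoryElement

Mechanism = Literal["hotspot-SNV", "recurrent-SV", "hyper-meth", "hypo-meth"]


@dataclass
class DriverSpec:
    mechanism: Mechanism
    penetrance: float
    effect_size: float = 0.5
    # target gene id; None lets the generator pick (the top designated hub
    # for recurrent-SV, an arbitrary non-TF gene otherwise)
    target: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.penetrance <= 1:
            raise InputError(f"penetrance {self.penetrance} outside (0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 17
    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 300
    tf_fraction: float = 0.2
    n_enhancers: int = 200
    n_tumor_samples: int = 100
    n_normal_samples: int = 30
    # per bp per sample; matches prostate WGS cohorts (~2.4e-6)
    background_snv_rate: float = 2.0e-6
    # events per sample; prostate WGS cohorts carry ~30-100
    sv_per_sample_mean: float = 30.0
    sv_length_log_mean: float = math.log(30_000)
    sv_length_log_sigma: float = 1.0
    expression_noise_sigma: float = 0.25
    beta_noise_sigma: float = 0.05
    hub_degree_max: int = 150
    hub_degree_gamma: float = 1.0
    implanted_drivers: list[DriverSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background_snv_rate < 0 or self.sv_per_sample_mean < 0:
            raise InputError("rates must be >= 0")


@dataclass
class Genome:
    chrom_map: ChromosomeMap
    genes: list[GeneModel]
    promoters: list[RegulatoryElement]
    enhancers: list[RegulatoryElement]
    dhs: list[GenomicInterval]

    def catalog(self) -> ElementCatalog:
        """Testable-element catalog: CDS = gene span, plus promoters and
        enhancers attributed to their linked gene."""
        elements = []
        for g in self.genes:
            elements.append(Element(f"cds_{g.gene_id}", g.interval, "CDS", g.gene_id))
        for p in self.promoters:
            elements.append(Element(p.element_id, p.interval, "promoter", p.linked_genes[0][0]))
        for e in self.enhancers:
            gene = e.linked_genes[0][0] if e.linked_genes else ""
            elements.append(Element(e.element_id, e.interval, "enhancer", gene))
        return ElementCatalog(elements)


@dataclass
class NetworkTruth:
    binding_calls: list[BindingCall]
    network: network_build.RegulatoryNetwork
    designated_hubs: set[str]
    tf_target_genes: dict[str, set[str]]


@dataclass
class GroundTruthManifest:
    drivers: list[dict]
    hubs: list[str]
    n_true_edges: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Cohort:
    variants: VariantSet
    svs: SVSet
    beta: pd.DataFrame
    probe_locations: dict[str, GenomicInterval]
    expression: pd.DataFrame  # genes x (tumor + normal) samples, log2 scale
    labels: pd.Series
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def make_genome(config: SimulationConfig) -> Genome:
    """Lay out genes, promoters, distal enhancers and DHS peaks.

    Each gene gets an exclusive slot so promoter windows and the >= 1 kb
    enhancer-gene buffer are satisfiable by construction; enhancers are
    placed in the intergenic half of the slot.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_map = ChromosomeMap(
        {c: config.chrom_length for c in chroms},
        {c: config.chrom_length // 2 for c in chroms},
    )
    per_chrom = int(math.ceil(config.n_genes / config.n_chromosomes))
    slot = config.chrom_length // (per_chrom + 1)
    min_needed = 2500 + 25_000 + 4_000
    if slot < min_needed:
        raise InputError(
            f"infeasible packing: slot {slot} bp < {min_needed}; "
            "increase chrom_length or reduce n_genes"
        )
    n_tfs = int(round(config.n_genes * config.tf_fraction))
    genes: list[GeneModel] = []
    enhancer_slots: list[tuple[str, int, int]] = []
    gi = 0
    for chrom in chroms:
        for k in range(per_chrom):
            if gi >= config.n_genes:
                break
            slot_start = (k + 1) * slot
            span = int(rng.integers(2_000, 20_001))
            strand = "+" if rng.random() < 0.5 else "-"
            start = slot_start + 3_000  # room for the upstream promoter window
            gene_id = f"G{gi:04d}"
            genes.append(
                GeneModel(
                    gene_id,
                    gene_id,
                    GenomicInterval(chrom, start, start + span, strand),
                    is_tf=gi < n_tfs,
                )
            )
            # intergenic region of the slot, clear of the gene +/- buffers
            enhancer_slots.append((chrom, start + span + 4_000, slot_start + slot - 2_000))
            gi += 1

    enh_candidates: list[GenomicInterval] = []
    slots_idx = rng.permutation(len(enhancer_slots))[: config.n_enhancers]
    for si in sorted(slots_idx):
        chrom, lo, hi = enhancer_slots[si]
        length = int(rng.integers(500, 1_501))
        start = int(rng.integers(lo, hi - length))
        enh_candidates.append(GenomicInterval(chrom, start, start + length))

    promoters = network_build.define_promoters(
        genes, chrom_lengths=chrom_map.lengths
    )
    enhancers = network_build.classify_enhancers(enh_candidates, genes)
    if len(enhancers) != len(enh_candidates):
        raise InputError("enhancer placement violated the gene-distance rule")
    # link each enhancer to the gene owning its slot (nearest TSS)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for enh in enhancers:
        nearest = min(
            genes_by_chrom[enh.interval.chrom],
            key=lambda g: abs(g.tss - enh.interval.start),
        )
        enh.linked_genes = [(nearest.gene_id, "synthetic-link")]

    # DHS peaks over every element (all elements active) plus background noise peaks
    dhs: list[GenomicInterval] = []
    for el in [*promoters, *enhancers]:
        mid = (el.interval.start + el.interval.end) // 2
        half = int(rng.integers(75, 151))
        dhs.append(GenomicInterval(el.interval.chrom, max(0, mid - half), mid + half))
    for _ in range(config.n_genes // 2):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_length - 300))
        dhs.append(GenomicInterval(chrom, start, start + 300))
    return Genome(chrom_map, genes, promoters, enhancers, dhs)


# ---------------------------------------------------------------------------
# Network truth
# ---------------------------------------------------------------------------


def make_network_truth(config: SimulationConfig, genome: Genome) -> NetworkTruth:
    """Assign TFs strictly decreasing target counts (power-law-like), emit
    binding calls with true-edge probabilities >= 0.7 and sub-threshold
    decoys, and designate the top-25% hubs by construction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tfs = sorted(g.gene_id for g in genome.genes if g.is_tf)
    gene_ids = [g.gene_id for g in genome.genes]
    promoter_of = {p.linked_genes[0][0]: p.element_id for p in genome.promoters}

    # strictly decreasing distinct-target counts so the top-25% cut is unambiguous
    n_tf = len(tfs)
    raw = [
        max(1, int(round(config.hub_degree_max * (k + 1) ** (-config.hub_degree_gamma))))
        for k in range(n_tf)
    ]
    degrees = []
    prev = None
    for d in raw:
        d = min(d, len(gene_ids))
        if prev is not None:
            d = min(d, prev - 1)
        d = max(d, 1)
        degrees.append(d)
        prev = d

    order = rng.permutation(n_tf)  # which TF gets which rank
    calls: list[BindingCall] = []
    tf_targets: dict[str, set[str]] = {}
    for rank, tf_idx in enumerate(order):
        tf = tfs[tf_idx]
        targets = rng.choice(gene_ids, size=degrees[rank], replace=False)
        tf_targets[tf] = set(map(str, targets))
        for gene in sorted(tf_targets[tf]):
            calls.append(
                BindingCall(tf, promoter_of[gene], float(0.75 + 0.24 * rng.random()))
            )
        # sub-threshold decoy calls that filter_binding must drop
        for gene in map(str, rng.choice(gene_ids, size=2, replace=False)):
            calls.append(
                BindingCall(tf, promoter_of[gene], float(0.3 + 0.39 * rng.random()))
            )

    kept = network_build.filter_binding(calls)
    net = network_build.assemble_network(kept, genome.promoters + genome.enhancers)
    designated = set(
        sorted(tf_targets, key=lambda t: (-len(tf_targets[t]), t))[
            : math.floor(0.25 * n_tf)
        ]
    )
    network_build.select_hubs(net)
    return NetworkTruth(
        binding_calls=calls,
        network=net,
        designated_hubs=designated,
        tf_target_genes=tf_targets,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _resolve_driver_targets(
    config: SimulationConfig, genome: Genome, truth: NetworkTruth | None
) -> list[tuple[DriverSpec, str]]:
    resolved = []
    non_tf = [g.gene_id for g in genome.genes if not g.is_tf]
    hub_order = (
        sorted(truth.designated_hubs, key=lambda t: -len(truth.tf_target_genes[t]))
        if truth
        else []
    )
    pick_plain = iter(non_tf)
    pick_hub = iter(hub_order)
    for spec in config.implanted_drivers:
        if spec.target is not None:
            resolved.append((spec, spec.target))
        elif spec.mechanism == "recurrent-SV" and hub_order:
            resolved.append((spec, next(pick_hub)))
        else:
            resolved.append((spec, next(pick_plain)))
    return resolved


def simulate_cohort(
    config: SimulationConfig,
    genome: Genome,
    truth: NetworkTruth | None = None,
) -> Cohort:
    """Generate SNVs, SVs, methylation and expression for the cohort, with
    every implanted driver recorded in the manifest."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    chroms = list(genome.chrom_map.lengths)
    chrom_len = np.array([genome.chrom_map.lengths[c] for c in chroms])
    tumor = [f"T{i:03d}" for i in range(config.n_tumor_samples)]
    normal = [f"N{i:03d}" for i in range(config.n_normal_samples)]
    gene_by_id = {g.gene_id: g for g in genome.genes}
    promoter_by_gene = {p.linked_genes[0][0]: p for p in genome.promoters}
    drivers = _resolve_driver_targets(config, genome, truth)
    manifest_drivers = []

    # --- background SNVs -------------------------------------------------
    genome_len = int(chrom_len.sum())
    rows = []
    for s in tumor:
        n = rng.poisson(config.background_snv_rate * genome_len)
        offs = rng.integers(0, genome_len, size=n)
        ci = np.searchsorted(np.cumsum(chrom_len), offs, side="right")
        pos = offs - (np.cumsum(chrom_len) - chrom_len)[ci]
        ref_idx = rng.integers(0, 4, size=n)
        ref = _BASES[ref_idx]
        alt = _BASES[(ref_idx + rng.integers(1, 4, size=n)) % 4]
        fs = rng.beta(2, 5, size=n)
        for j in range(n):
            rows.append((s, chroms[ci[j]], int(pos[j]), ref[j], alt[j], float(fs[j])))
    # --- hotspot drivers --------------------------------------------------
    for spec, target in drivers:
        if spec.mechanism != "hotspot-SNV":
            continue
        gene = gene_by_id[target]
        hotspot = int((gene.interval.start + gene.interval.end) // 2)
        n_aff = max(1, int(round(spec.penetrance * config.n_tumor_samples)))
        if n_aff < 2:
            import logging

            logging.getLogger(__name__).warning(
                "driver %s affects < 2 samples; undetectable by design", target
            )
        affected = sorted(rng.choice(tumor, size=n_aff, replace=False))
        for s in affected:
            rows.append((s, gene.interval.chrom, hotspot, "C", "T", float(rng.beta(8, 2))))
        manifest_drivers.append(
            {
                "mechanism": spec.mechanism,
                "target": target,
                "element": f"cds_{target}",
                "position": hotspot,
                "samples": affected,
            }
        )
    vdf = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "fs"])
    vdf = vdf.drop_duplicates(["sample", "chrom", "pos", "alt"])
    variants = VariantSet(vdf.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True))

    # --- SVs --------------------------------------------------------------
    sv_rows = []
    sv_types = np.array(["DEL", "DUP", "INV", "INS", "TRA"])
    sv_probs = np.array([0.45, 0.20, 0.15, 0.10, 0.10])
    deleted_by_gene: dict[str, set[str]] = {}
    for s in tumor:
        n = rng.poisson(config.sv_per_sample_mean)
        for _ in range(n):
            svtype = str(rng.choice(sv_types, p=sv_probs))
            ci = int(rng.integers(len(chroms)))
            chrom = chroms[ci]
            if svtype == "TRA":
                cj = int((ci + 1 + rng.integers(len(chroms) - 1)) % len(chroms))
                p1 = int(rng.integers(0, chrom_len[ci] - 1))
                p2 = int(rng.integers(0, chrom_len[cj] - 1))
                sv_rows.append((s, "TRA", chrom, p1, p1 + 1, chroms[cj], p2, p2 + 1))
            elif svtype == "INS":
                p1 = int(rng.integers(0, chrom_len[ci] - 1))
                sv_rows.append((s, "INS", chrom, p1, p1 + 1, chrom, p1, p1 + 1))
            else:
                length = int(
                    np.clip(
                        rng.lognormal(config.sv_length_log_mean, config.sv_length_log_sigma),
                        500,
                        chrom_len[ci] // 10,
                    )
                )
                p1 = int(rng.integers(0, chrom_len[ci] - length))
                sv_rows.append((s, svtype, chrom, p1, p1 + 1, chrom, p1 + length, p1 + length + 1))
    for spec, target in drivers:
        if spec.mechanism != "recurrent-SV":
            continue
        gene = gene_by_id[target]
        n_aff = max(1, int(round(spec.penetrance * config.n_tumor_samples)))
        affected = sorted(rng.choice(tumor, size=n_aff, replace=False))
        for s in affected:
            pad_left = int(rng.integers(1_000, 20_000))
            pad_right = int(rng.integers(1_000, 20_000))
            p1 = max(0, gene.interval.start - pad_left)
            p2 = min(genome.chrom_map.lengths[gene.interval.chrom] - 1, gene.interval.end + pad_right)
            sv_rows.append((s, "DEL", gene.interval.chrom, p1, p1 + 1, gene.interval.chrom, p2, p2 + 1))
            deleted_by_gene.setdefault(target, set()).add(s)
        manifest_drivers.append(
            {
                "mechanism": spec.mechanism,
                "target": target,
                "element": f"cds_{target}",
                "samples": affected,
            }
        )
    sdf = pd.DataFrame(
        sv_rows,
        columns=["sample", "svtype", "chrom1", "start1", "end1", "chrom2", "start2", "end2"],
    )
    intra = sdf["svtype"] != "TRA"
    sdf["length"] = np.where(
        intra, (sdf["start2"] - sdf["start1"]).abs(), np.nan
    )
    svs = SVSet(sdf[list(SVSet.COLUMNS)].sort_values(["sample", "chrom1", "start1"]).reset_index(drop=True))
    # background deletions also knock genes out for the expression model
    for r in svs.df[svs.df["svtype"] == "DEL"].itertuples(index=False):
        lo, hi = min(r.start1, r.start2), max(r.end1, r.end2)
        for g in genome.genes:
            if g.interval.chrom == r.chrom1 and g.interval.start < hi and lo < g.interval.end:
                deleted_by_gene.setdefault(g.gene_id, set()).add(r.sample)

    # --- methylation ------------------------------------------------------
    all_samples = tumor + normal
    probe_rows = []
    probe_locations: dict[str, GenomicInterval] = {}
    meth_affected: dict[str, tuple[str, set[str], float]] = {}  # probe -> (dir, samples, effect)
    driver_meth = {
        target: spec
        for spec, target in drivers
        if spec.mechanism in ("hyper-meth", "hypo-meth")
    }
    probes: list[tuple[str, GenomicInterval, float, str]] = []
    for p in genome.promoters:
        gene = p.linked_genes[0][0]
        mid = (p.interval.start + p.interval.end) // 2
        probes.append(
            (f"cg_prom_{gene}", GenomicInterval(p.interval.chrom, mid, mid + 1),
             float(0.05 + 0.2 * rng.random()), gene)
        )
    for i, e in enumerate(genome.enhancers):
        if i % 2:
            continue
        gene = e.linked_genes[0][0] if e.linked_genes else ""
        mid = (e.interval.start + e.interval.end) // 2
        probes.append(
            (f"cg_enh_{i}", GenomicInterval(e.interval.chrom, mid, mid + 1),
             float(0.3 + 0.3 * rng.random()), gene)
        )
    for probe_id, iv, base, gene in probes:
        probe_locations[probe_id] = iv
        beta_vals = np.clip(
            base + rng.normal(0, config.beta_noise_sigma, size=len(all_samples)), 0, 1
        )
        spec = driver_meth.get(gene) if probe_id.startswith("cg_prom_") else None
        if spec is not None:
            n_aff = max(1, int(round(spec.penetrance * config.n_tumor_samples)))
            aff_idx = rng.choice(config.n_tumor_samples, size=n_aff, replace=False)
            sign = 1.0 if spec.mechanism == "hyper-meth" else -1.0
            beta_vals[aff_idx] = np.clip(
                base + sign * spec.effect_size
                + rng.normal(0, config.beta_noise_sigma, size=n_aff),
                0,
                1,
            )
            aff_samples = {tumor[i] for i in aff_idx}
            meth_affected[probe_id] = (
                "hyper" if sign > 0 else "hypo", aff_samples, spec.effect_size
            )
            manifest_drivers.append(
                {
                    "mechanism": spec.mechanism,
                    "target": gene,
                    "element": probe_id,
                    "samples": sorted(aff_samples),
                }
            )
        probe_rows.append(pd.Series(beta_vals, index=all_samples, name=probe_id))
    beta = pd.DataFrame(probe_rows)

    # --- expression -------------------------------------------------------
    baseline = rng.normal(8.0, 2.0, size=len(genome.genes))
    expr = np.empty((len(genome.genes), len(all_samples)))
    sample_index = {s: j for j, s in enumerate(all_samples)}
    hub_hit_samples: dict[str, set[str]] = {}
    if truth is not None:
        for spec, target in drivers:
            if spec.mechanism == "recurrent-SV" and target in truth.tf_target_genes:
                hub_hit_samples[target] = deleted_by_gene.get(target, set())
    for i, g in enumerate(genome.genes):
        mu = np.full(len(all_samples), baseline[i])
        for s in deleted_by_gene.get(g.gene_id, ()):  # deletion halves dosage
            mu[sample_index[s]] -= 1.0
        probe_id = f"cg_prom_{g.gene_id}"
        if probe_id in meth_affected:
            direction, samples, effect = meth_affected[probe_id]
            shift = -2.0 * effect if direction == "hyper" else 2.0 * effect
            for s in samples:
                mu[sample_index[s]] += shift
        if truth is not None:
            for hub, hit_samples in hub_hit_samples.items():
                if g.gene_id in truth.tf_target_genes[hub]:
                    for s in hit_samples:
                        mu[sample_index[s]] -= 0.5
        expr[i] = mu + rng.normal(0, config.expression_noise_sigma, size=len(all_samples))
    expression = pd.DataFrame(expr, index=[g.gene_id for g in genome.genes], columns=all_samples)

    labels = pd.Series(
        ["tumor"] * len(tumor) + ["normal"] * len(normal), index=all_samples, name="label"
    )
    manifest = GroundTruthManifest(
        drivers=manifest_drivers,
        hubs=sorted(truth.designated_hubs) if truth else [],
        n_true_edges=truth.network.n_tf_gene_edges() if truth else 0,
    )
    return Cohort(
        variants=variants,
        svs=svs,
        beta=beta,
        probe_locations=probe_locations,
        expression=expression,
        labels=labels,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_cohort(
    out_dir: str | os.PathLike,
    config: SimulationConfig,
    genome: Genome,
    truth: NetworkTruth,
    cohort: Cohort,
) -> dict[str, str]:
    """Write every standard-format input the pipeline consumes; returns the
    path map. Deterministic: same config => byte-identical files."""
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {k: os.path.join(out, v) for k, v in {
        "genes": "genes.tsv",
        "tf_list": "tf_list.txt",
        "chrom_sizes": "chrom.sizes",
        "dhs": "dhs.bed",
        "enhancers": "enhancer_candidates.bed",
        "elements": "elements.bed",
        "binding": "binding_calls.tsv",
        "variants": "variants.tsv",
        "svs": "svs.bedpe",
        "beta": "beta.tsv",
        "probes": "probe_locations.tsv",
        "expression": "expression.tsv",
        "labels": "sample_labels.tsv",
        "manifest": "manifest.json",
    }.items()}
    genome_io.write_gene_models(paths["genes"], genome.genes)
    with open(paths["tf_list"], "w") as fh:
        for g in genome.genes:
            if g.is_tf:
                fh.write(g.gene_id + "\n")
    genome_io.write_chrom_sizes(paths["chrom_sizes"], genome.chrom_map)
    genome_io.write_bed(paths["dhs"], [(iv, ()) for iv in genome.dhs])
    genome_io.write_bed(
        paths["enhancers"], [(e.interval, (e.element_id,)) for e in genome.enhancers]
    )
    write_elements(paths["elements"], genome.catalog())
    pd.DataFrame(
        [
            {"tf": c.tf_id, "element": c.element_id, "probability": round(c.probability, 6)}
            for c in truth.binding_calls
        ]
    ).to_csv(paths["binding"], sep="\t", index=False)
    genome_io.write_variants_tsv(paths["variants"], cohort.variants)
    genome_io.write_sv_bedpe(paths["svs"], cohort.svs)
    cohort.beta.round(6).to_csv(paths["beta"], sep="\t", index_label="probe_id")
    pd.DataFrame(
        [
            {"probe_id": p, "chrom": iv.chrom, "pos": iv.start}
            for p, iv in cohort.probe_locations.items()
        ]
    ).to_csv(paths["probes"], sep="\t", index=False)
    cohort.expression.round(6).to_csv(paths["expression"], sep="\t", index_label="gene_id")
    cohort.labels.rename_axis("sample").reset_index().to_csv(
        paths["labels"], sep="\t", index=False
    )
    with open(paths["manifest"], "w") as fh:
        fh.write(cohort.manifest.to_json())
    return paths


def simulate_all(config: SimulationConfig) -> tuple[Genome, NetworkTruth, Cohort]:
    genome = make_genome(config)
    truth = make_network_truth(config, genome)
    cohort = simulate_cohort(config, genome, truth)
    return genome, truth, cohort
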