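"""Integration of SNV, SV and methylation hits onto the regulatory network,
the enrichment-test battery, and the regulatory-driver report.

The driver logic: a TF hub whose coding or regulatory elements carry
significant alterations is predicted to dysregulate its many targets.
Candidates are ranked by the strength of their best alteration (smallest
q-value) and, at ties, by out-degree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import InputError
from .network_build import RegulatoryNetwork
from .stats_core import (
    TwoByTwoTable,
    bh_adjust,
    conditional_mle_or,
    fisher_exact,
    hypergeom_log_sf,
    spearman,
    wilcoxon_rank_sum,
)

ALTERATION_KEYS = ("SNV", "SV", "hyper-meth", "hypo-meth")
REGION_KEYS = ("CDS", "promoter", "enhancer")
DEFAULT_DE_Q_MAX = 0.0001


@dataclass
class GeneAlterationRecord:
    gene_id: str
    # (alteration, region) -> best q-value among significant hits
    flags: dict[tuple[str, str], float] = field(default_factory=dict)
    is_tf: bool = False
    is_hub: bool = False
    diffexp: dict | None = None  # {direction, p, q}

    @property
    def best_q(self) -> float:
        return min(self.flags.values()) if self.flags else math.nan

    def altered_by(self, alteration: str) -> bool:
        return any(a == alteration for a, _ in self.flags)


@dataclass
class EnrichmentResult:
    table: TwoByTwoTable
    odds_ratio: float
    p_value: float
    method: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        t = self.table
        return {
            "table": [[t.a, t.b], [t.c, t.d]],
            "odds_ratio": self.odds_ratio,
            "p": self.p_value,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def _fisher_battery(table: TwoByTwoTable, method: str) -> EnrichmentResult:
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        return EnrichmentResult(table, math.nan, 1.0, method, degenerate=True)
    return EnrichmentResult(
        table,
        odds_ratio=conditional_mle_or(table),
        p_value=fisher_exact(table, "two"),
        method=method,
    )


def build_alteration_table(
    fsig_snv_hits: pd.DataFrame | None,
    fsig_sv_hits: pd.DataFrame | None,
    dm_links: Sequence[tuple[str, str, str, float]] | None,
    network: RegulatoryNetwork | None = None,
    tf_ids: set[str] | None = None,
) -> dict[str, GeneAlterationRecord]:
    """One record per gene with >= 1 significant alteration flag.

    ``fsig_snv_hits`` / ``fsig_sv_hits`` are the result frames of the two
    recurrence tests (only rows with significant=True contribute);
    ``dm_links`` rows are (gene_id, direction, region, q) from methylation
    probe-gene linking. TF and hub status comes from the network.
    """
    records: dict[str, GeneAlterationRecord] = {}

    def rec(gene: str) -> GeneAlterationRecord:
        if gene not in records:
            records[gene] = GeneAlterationRecord(gene_id=gene)
        return records[gene]

    for df, alteration in ((fsig_snv_hits, "SNV"), (fsig_sv_hits, "SV")):
        if df is None or not len(df):
            continue
        sig = df[df["significant"]]
        for _, row in sig.iterrows():
            gene = row["gene"]
            if not isinstance(gene, str) or not gene:
                continue
            key = (alteration, row["class"])
            r = rec(gene)
            r.flags[key] = min(r.flags.get(key, math.inf), float(row["q"]))

    for gene, direction, region, q in dm_links or ():
        key = (f"{direction}-meth", region)
        r = rec(gene)
        r.flags[key] = min(r.flags.get(key, math.inf), float(q))

    tf_ids = tf_ids or (set(network.tfs) if network is not None else set())
    hubs = network.hubs if network is not None else set()
    for r in records.values():
        r.is_tf = r.gene_id in tf_ids
        r.is_hub = r.gene_id in hubs
    return records


def hub_enrichment(
    group_a_tfs: set[str], group_b_tfs: set[str], hubs: set[str]
) -> EnrichmentResult:
    """Are group-A TFs enriched for hubs relative to group-B TFs?

    2x2 = [hub, non-hub] x [group A, group B]; two-sided Fisher by the
    point-probability rule, OR by conditional MLE.
    """
    a = len(group_a_tfs & hubs)
    b = len(group_a_tfs - hubs)
    c = len(group_b_tfs & hubs)
    d = len(group_b_tfs - hubs)
    return _fisher_battery(TwoByTwoTable(a, b, c, d), "fisher_hub_enrichment")


@dataclass
class OverlapResult:
    overlap: int
    expected: float
    log_p: float

    @property
    def p_value(self) -> float:
        return math.exp(self.log_p)

    def as_dict(self) -> dict:
        return {
            "overlap": self.overlap,
            "expected": self.expected,
            "p": self.p_value,
            "log10_p": self.log_p / math.log(10),
        }


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Upper-tail hypergeometric test of |A intersect B| against chance,
    with population = universe, successes = A, draws = B."""
    if not (set_a <= universe and set_b <= universe):
        raise InputError("sets must be subsets of the universe")
    x = len(set_a & set_b)
    N, K, n = len(universe), len(set_a), len(set_b)
    expected = K * n / N if N else 0.0
    return OverlapResult(x, expected, hypergeom_log_sf(x, N, K, n))


def signature_enrichment(
    signature_genes: set[str], target_genes: set[str], universe: set[str]
) -> EnrichmentResult:
    """Fisher test of a gene signature against a target set within a universe.

    2x2 = [in target set, not] x [in signature, not].
    """
    if not signature_genes <= universe:
        raise InputError("signature must be a subset of the universe")
    a = len(signature_genes & target_genes)
    b = len(signature_genes - target_genes)
    c = len(target_genes - signature_genes)
    d = len(universe - target_genes - signature_genes)
    return _fisher_battery(TwoByTwoTable(a, b, c, d), "fisher_signature_enrichment")


def differential_expression(
    expression: pd.DataFrame,
    labels: pd.Series,
    q_max: float = DEFAULT_DE_Q_MAX,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tumor vs normal per gene, BH-adjusted.

    Returns a frame indexed by gene with p, q, direction (up = higher in
    tumor, by median difference) and significant (q <= q_max). Constant
    genes get p = 1.
    """
    tumor = [s for s in expression.columns if labels.get(s) == "tumor"]
    normal = [s for s in expression.columns if labels.get(s) == "normal"]
    if len(tumor) < 3 or len(normal) < 3:
        raise InputError("differential expression needs >= 3 samples per group")
    t_mat = expression[tumor].to_numpy(dtype=float)
    n_mat = expression[normal].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(expression.index):
        x, y = t_mat[i], n_mat[i]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            _, p = wilcoxon_rank_sum(x, y, "two")
        direction = "up" if np.median(x) > np.median(y) else "down"
        rows.append((gene, p, direction))
    df = pd.DataFrame(rows, columns=["gene", "p", "direction"]).set_index("gene")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= q_max
    return df


def sample_overlap(
    deleted_samples: set[str], hypermeth_samples: set[str]
) -> dict[str, int]:
    """Venn partition of a cohort by deletion / hyper-methylation status."""
    both = deleted_samples & hypermeth_samples
    return {
        "n_del_only": len(deleted_samples - hypermeth_samples),
        "n_meth_only": len(hypermeth_samples - deleted_samples),
        "n_both": len(both),
        "n_union": len(deleted_samples | hypermeth_samples),
    }


def tf_methylation_correlation(
    tf_expression: pd.Series, beta_submatrix: pd.DataFrame
) -> dict[str, float]:
    """Spearman correlation between TF expression and the per-sample mean
    beta across a probe set (probes x samples). Requires >= 10 shared
    samples; constant vectors yield NaN with a flag."""
    shared = [s for s in tf_expression.index if s in beta_submatrix.columns]
    if len(shared) < 10:
        raise InputError("TF-methylation correlation needs >= 10 shared samples")
    mean_beta = beta_submatrix[shared].mean(axis=0, skipna=True)
    rho, p = spearman(tf_expression[shared].to_numpy(), mean_beta.to_numpy())
    return {"rho": rho, "p": p, "n": len(shared), "undefined": math.isnan(rho)}


@dataclass
class DriverReport:
    candidates: pd.DataFrame  # ranked TF-hub drivers
    evidence: pd.DataFrame  # per-gene alteration rows
    enrichments: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(
            {
                "candidates": self.candidates.to_dict(orient="records"),
                "n_altered_genes": int(len(self.evidence)),
                "enrichments": self.enrichments,
            },
            indent=2,
            default=float,
        )


def driver_report(
    records: Mapping[str, GeneAlterationRecord],
    enrichments: dict[str, dict] | None,
    network: RegulatoryNetwork,
) -> DriverReport:
    """Rank TF-hub driver candidates (hub AND >= 1 significant alteration).

    Ranking: best (smallest) alteration q first, then out-degree descending,
    then gene id. Non-hub altered genes stay in the evidence table.
    """
    evid_rows = []
    for gene in sorted(records):
        r = records[gene]
        row = {
            "gene": gene,
            "is_tf": r.is_tf,
            "is_hub": r.is_hub,
            "best_q": r.best_q,
            "out_degree": network.out_degree(gene),
        }
        for alt in ALTERATION_KEYS:
            regions = sorted(reg for a, reg in r.flags if a == alt)
            row[f"alt_{alt}"] = ";".join(regions)
        if r.diffexp:
            row["de_direction"] = r.diffexp.get("direction", "")
            row["de_q"] = r.diffexp.get("q", math.nan)
        evid_rows.append(row)
    evidence = pd.DataFrame(evid_rows)

    if len(evidence):
        cand = evidence[evidence["is_hub"]].copy()
        cand = cand.sort_values(
            by=["best_q", "out_degree", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)
        cand.insert(0, "rank", np.arange(1, len(cand) + 1))
    else:
        cand = pd.DataFrame(
            columns=["rank", "gene", "is_tf", "is_hub", "best_q", "out_degree"]
        )
    return DriverReport(
        candidates=cand, evidence=evidence, enrichments=enrichments or {}
    )
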