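"""Differential DNA methylation at promoter and enhancer probes, with
expression-based linking of probes to putative target genes.

The unit of analysis is the array probe with its beta value (methylated /
total intensity, in [0, 1]). Hypo-methylated probes are called by comparing
the 20% least-methylated tumor samples against the 20% least-methylated
normals with a one-tailed Welch t-test (tumor < normal); hyper-methylated
probes symmetrically on the most-methylated quintiles (tumor > normal). A
probe is reported when the BH-adjusted q is <= 0.01 and the group-mean
difference on the compared quintiles exceeds 0.3 in absolute value — the
signed 0.3 filter makes hyper and hypo calls mutually exclusive.

Each called probe is then linked to nearby genes by splitting tumor samples
into the 20% most- and least-methylated at that probe and comparing target
expression between the two groups with a one-sided Wilcoxon rank-sum test
in the repression direction (hyper -> lower expression when methylated).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, InputError
from .network_build import RegulatoryElement
from .stats_core import bh_adjust, welch_t_one_tailed, wilcoxon_rank_sum

log = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.2
DEFAULT_MIN_DELTA = 0.3
DEFAULT_Q_MAX = 0.01
DEFAULT_N_NEARBY = 10
DEFAULT_LINK_WINDOW = 1_000_000
DEFAULT_LINK_P_MAX = 0.01


@dataclass
class MethylationAssay:
    """Beta matrix (probes x samples) plus probe locations, classes, labels."""

    beta: pd.DataFrame
    locations: dict[str, GenomicInterval]
    classes: dict[str, str] = field(default_factory=dict)  # promoter|enhancer|other
    labels: pd.Series | None = None  # sample -> tumor|normal

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        if vals.size:
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise InputError("beta values outside [0, 1]")

    def tumor_samples(self) -> list[str]:
        self._need_labels()
        return [s for s in self.beta.columns if self.labels.get(s) == "tumor"]

    def normal_samples(self) -> list[str]:
        self._need_labels()
        return [s for s in self.beta.columns if self.labels.get(s) == "normal"]

    def _need_labels(self) -> None:
        if self.labels is None:
            raise InputError("assay has no sample labels attached")


@dataclass
class LinkedGene:
    gene_id: str
    p_value: float
    q_value: float


@dataclass
class DMProbe:
    probe_id: str
    klass: str
    direction: str  # hyper | hypo
    mu_tumor_extreme: float
    mu_normal_extreme: float
    delta: float  # mu_tumor - mu_normal on the compared quintiles
    p_value: float
    q_value: float
    linked_genes: list[LinkedGene] = field(default_factory=list)


def classify_probes(
    assay: MethylationAssay,
    promoter_elements: Sequence[RegulatoryElement],
    enhancer_elements: Sequence[RegulatoryElement],
) -> dict[str, str]:
    """Probe class by element overlap; promoter takes precedence over
    enhancer; probes in neither are 'other' and are never tested."""
    from .genome_io import IntervalIndex

    def build(elements):
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for el in elements:
            s, e = by_chrom.setdefault(el.interval.chrom, ([], []))
            s.append(el.interval.start)
            e.append(el.interval.end)
        return {c: IntervalIndex(s, e) for c, (s, e) in by_chrom.items()}

    prom_idx = build(promoter_elements)
    enh_idx = build(enhancer_elements)
    classes = {}
    for probe, iv in assay.locations.items():
        idx = prom_idx.get(iv.chrom)
        if idx is not None and idx.query(iv.start, iv.end).size:
            classes[probe] = "promoter"
            continue
        idx = enh_idx.get(iv.chrom)
        if idx is not None and idx.query(iv.start, iv.end).size:
            classes[probe] = "enhancer"
        else:
            classes[probe] = "other"
    assay.classes = classes
    n = pd.Series(classes).value_counts()
    log.info("probe classes: %s", n.to_dict())
    return classes


def _extreme_group(values: np.ndarray, quantile: float, side: str) -> np.ndarray:
    """The ceil(quantile * n) lowest or highest non-missing values."""
    values = values[~np.isnan(values)]
    k = math.ceil(quantile * values.size)
    values = np.sort(values)
    return values[:k] if side == "low" else values[-k:]


def differential_methylation(
    assay: MethylationAssay,
    quantile: float = DEFAULT_QUANTILE,
    min_delta: float = DEFAULT_MIN_DELTA,
    q_max: float = DEFAULT_Q_MAX,
) -> list[DMProbe]:
    """Extreme-quintile one-tailed t-tests per classified probe.

    BH is applied across all tested probes within each direction; a probe is
    reported when q <= q_max and |delta| > min_delta.
    """
    tumor = assay.tumor_samples()
    normal = assay.normal_samples()
    if len(tumor) < 5 or len(normal) < 5:
        raise InputError("need >= 5 tumor and >= 5 normal samples")
    probes = [p for p, k in assay.classes.items() if k in ("promoter", "enhancer")]
    tested: list[tuple[str, str, float, float, float, float]] = []
    for probe in probes:
        row = assay.beta.loc[probe]
        t_vals = row[tumor].to_numpy(dtype=float)
        n_vals = row[normal].to_numpy(dtype=float)
        if np.isnan(t_vals).all() or np.isnan(n_vals).all():
            log.info("probe %s all-missing in one group; skipped", probe)
            continue
        for direction, side, alt in (("hypo", "low", "less"), ("hyper", "high", "greater")):
            tg = _extreme_group(t_vals, quantile, side)
            ng = _extreme_group(n_vals, quantile, side)
            if tg.size < 2 or ng.size < 2:
                continue
            _, p = welch_t_one_tailed(tg, ng, alt)
            tested.append((probe, direction, float(tg.mean()), float(ng.mean()),
                           float(tg.mean() - ng.mean()), p))

    out: list[DMProbe] = []
    for direction in ("hypo", "hyper"):
        rows = [t for t in tested if t[1] == direction]
        if not rows:
            continue
        q = bh_adjust([r[5] for r in rows])
        for (probe, _, mu_t, mu_n, delta, p), qv in zip(rows, q):
            signed_ok = delta < -min_delta if direction == "hypo" else delta > min_delta
            if qv <= q_max and signed_ok:
                out.append(
                    DMProbe(
                        probe_id=probe,
                        klass=assay.classes[probe],
                        direction=direction,
                        mu_tumor_extreme=mu_t,
                        mu_normal_extreme=mu_n,
                        delta=delta,
                        p_value=p,
                        q_value=float(qv),
                    )
                )
    return out


def link_probe_to_genes(
    probe: DMProbe,
    assay: MethylationAssay,
    expression: pd.DataFrame,
    genes: Sequence[GeneModel],
    n_nearby: int = DEFAULT_N_NEARBY,
    p_max: float = DEFAULT_LINK_P_MAX,
    window: int = DEFAULT_LINK_WINDOW,
    quantile: float = DEFAULT_QUANTILE,
    use_q: bool = True,
) -> list[LinkedGene]:
    """Link a differentially methylated probe to putative target genes.

    Candidates are the n_nearby nearest TSSs within the window. Tumor samples
    are split into the 20% most- (M) and least- (U) methylated at the probe;
    expression is compared M vs U one-sided in the repression direction.
    BH within the candidate set when ``use_q``; raw-p thresholding otherwise.
    """
    loc = assay.locations[probe.probe_id]
    shared = [s for s in assay.tumor_samples() if s in expression.columns]
    if len(shared) < 5:
        raise InputError("probe-gene linking needs >= 5 shared tumor samples")
    beta = assay.beta.loc[probe.probe_id, shared].astype(float)
    beta = beta.dropna()
    k = math.ceil(quantile * beta.size)
    order = beta.sort_values()
    u_group = list(order.index[:k])
    m_group = list(order.index[-k:])

    cand = sorted(
        (
            g
            for g in genes
            if g.interval.chrom == loc.chrom and abs(g.tss - loc.start) <= window
        ),
        key=lambda g: (abs(g.tss - loc.start), g.gene_id),
    )[:n_nearby]
    results = []
    alternative = "less" if probe.direction == "hyper" else "greater"
    for g in cand:
        if g.gene_id not in expression.index:
            continue
        expr_m = expression.loc[g.gene_id, m_group].to_numpy(dtype=float)
        expr_u = expression.loc[g.gene_id, u_group].to_numpy(dtype=float)
        _, p = wilcoxon_rank_sum(expr_m, expr_u, alternative)
        results.append((g.gene_id, p))
    if not results:
        return []
    q = bh_adjust([p for _, p in results])
    linked = [
        LinkedGene(gid, p, float(qv))
        for (gid, p), qv in zip(results, q)
        if (qv if use_q else p) < p_max
    ]
    probe.linked_genes = linked
    return linked


def dm_probes_to_frame(probes: Sequence[DMProbe]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "class": p.klass,
                "direction": p.direction,
                "mu_tumor_extreme": p.mu_tumor_extreme,
                "mu_normal_extreme": p.mu_normal_extreme,
                "delta": p.delta,
                "p": p.p_value,
                "q": p.q_value,
                "linked_genes": ";".join(lg.gene_id for lg in p.linked_genes),
            }
            for p in probes
        ]
    )
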